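#!/usr/bin/env python
"""miRNA-mediated lncRNA-mRNA crosstalk network over the DEFGs.

Pairwise Pearson correlation on tumor samples (|r| >= 0.4, p < 0.05), the
simultaneous-co-expression triplet rule, and target-database validation
(>= 4 of 6 databases for miRNA-mRNA, >= 1 of 3 for miRNA-lncRNA).  Writes the
triplet table and the edge list (TSV + SIF).
"""

import json
from pathlib import Path

import pandas as pd

from omicross import crosstalk
from omicross.datatypes import ExpressionMatrix

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    annot = pd.read_csv(ROOT / "data" / "annotation.tsv", sep="\t", index_col="sample")
    tumors = annot.index[annot["group"] == "tumor"]
    defgs = json.loads((ROOT / "defgs.json").read_text())
    pools = {}
    for layer in ("mRNA", "miRNA", "lncRNA"):
        m = ExpressionMatrix.from_tsv(ROOT / "data" / f"expr_{layer}.tsv", layer)
        keep = [g for g in defgs[layer] if g in set(m.genes)]
        pools[layer] = m.subset_genes(keep).subset_samples(tumors)
    pairs = {}
    for key, (la, lb) in {"lnc_mrna": ("lncRNA", "mRNA"),
                          "mir_lnc": ("miRNA", "lncRNA"),
                          "mir_mrna": ("miRNA", "mRNA")}.items():
        ct = crosstalk.pairwise_correlation(pools[la], pools[lb])
        pairs[key] = crosstalk.filter_coexpressed(ct)
        print(f"{key}: {len(pairs[key])} co-expressed pairs "
              f"of {len(ct)} tested")
    net = crosstalk.infer_triplets(pairs["lnc_mrna"], pairs["mir_lnc"],
                                   pairs["mir_mrna"])
    evidence = pd.read_csv(ROOT / "data" / "evidence.tsv", sep="\t")
    net = crosstalk.validate_triplets(net, evidence)
    net.to_csv(ROOT / "triplets.tsv", sep="\t", index=False)
    edges = crosstalk.export_network(net, ROOT / "network_edges.tsv")

    truth = json.loads((ROOT / "data" / "truth.json").read_text())
    planted = {(t["mirna"], t["lncrna"], t["mrna"]) for t in truth["triplets"]}
    got = {(r.mirna, r.lncrna, r.mrna) for r in net[net["validated"]].itertuples()}
    print(f"{len(net)} triplets inferred, {len(got)} validated "
          f"({len(got & planted)} planted of {len(planted)}); "
          f"{len(edges)} network edges written")


if __name__ == "__main__":
    main()
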