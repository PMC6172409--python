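#!/usr/bin/env python
"""Generate the synthetic multi-omic study cohort.

Emits three expression layers (mRNA/miRNA/lncRNA) over 120 tumors and 20
normals with two planted subtypes, tumor-vs-normal DE genes, miRNA-mediated
triplets, subtype-linked survival and clinical covariates, plus the ground
truth and the target-database evidence table.  Everything downstream reads
from results/data/.
"""

import json
from pathlib import Path

from omicross.simulate import SimConfig, generate_dataset, generate_target_db

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 20240901


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(n_tumor=120, n_normal=20, k_true=2, seed=SEED)
    layers, annot, truth = generate_dataset(cfg)
    for layer, m in layers.items():
        m.to_tsv(OUT / f"expr_{layer}.tsv")
    annot.to_csv(OUT / "annotation.tsv", sep="\t")
    (OUT / "truth.json").write_text(
        json.dumps(truth.to_json_dict(), sort_keys=True, indent=1))
    ev = generate_target_db(truth, decoy_fraction=1.0, seed=SEED + 1)
    ev.to_csv(OUT / "evidence.tsv", sep="\t", index=False)
    print(f"cohort: {cfg.n_tumor} tumors / {cfg.n_normal} normals; "
          f"layers {[m.n_genes for m in layers.values()]} genes; "
          f"{len(truth.triplets)} planted triplets; "
          f"{len(truth.de_genes)} planted DE genes -> {OUT}")


if __name__ == "__main__":
    main()
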