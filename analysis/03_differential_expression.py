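#!/usr/bin/env python
"""Tumor-vs-normal differential expression per omics layer.

F test on log2(x+1), BH FDR < 0.05 and |log2FC| > 0.57 (strict); writes one
DE table per layer and reports recovery of the planted DE genes.
"""

import json
from pathlib import Path

import pandas as pd

from omicross import diffexpr
from omicross.datatypes import ExpressionMatrix

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    annot = pd.read_csv(ROOT / "data" / "annotation.tsv", sep="\t", index_col="sample")
    truth = json.loads((ROOT / "data" / "truth.json").read_text())
    planted = set(truth["de_genes"])
    for layer in ("mRNA", "miRNA", "lncRNA"):
        m = ExpressionMatrix.from_tsv(ROOT / "data" / f"expr_{layer}.tsv", layer)
        tab = diffexpr.de_table(m, annot["group"], numerator="tumor")
        tab.to_csv(ROOT / f"de_{layer}.tsv", sep="\t", index_label="gene")
        up, down = diffexpr.deg_lists(tab)
        called = set(up) | set(down)
        hits = len(called & planted)
        print(f"{layer}: {len(up)} up / {len(down)} down; "
              f"{hits} of the called DEGs are planted "
              f"(layer has {len(planted & set(m.genes))} planted)")


if __name__ == "__main__":
    main()
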