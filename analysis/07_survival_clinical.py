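#!/usr/bin/env python
"""Survival and clinical readouts for the discovered subtypes and network genes.

Kaplan-Meier / log-rank between subtypes with 5-year survival rates, Pearson
chi-square on the clinical covariates, and mean-split survival for the genes
of the validated crosstalk triplets.
"""

import json
from pathlib import Path

import pandas as pd

from omicross import survival
from omicross.datatypes import ExpressionMatrix, InputError

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    annot = pd.read_csv(ROOT / "data" / "annotation.tsv", sep="\t", index_col="sample")
    subtypes = pd.read_csv(ROOT / "subtypes.tsv", sep="\t", index_col="sample")["subtype"]
    t = annot.loc[subtypes.index, "time"]
    e = annot.loc[subtypes.index, "event"]

    chi2, p = survival.logrank_by_group(t, e, subtypes.map(lambda s: min(int(s), 2)))
    rows = []
    for s in sorted(subtypes.map(lambda v: min(int(v), 2)).unique()):
        mask = subtypes.map(lambda v: min(int(v), 2)) == s
        km = survival.km_curve(t[mask].to_numpy(), e[mask].to_numpy())
        rate = survival.survival_rate_at(km, survival.FIVE_YEARS_DAYS)
        rows.append({"subtype": s, "n": int(mask.sum()),
                     "five_year_rate": round(rate, 3)})
        km.table.to_csv(ROOT / f"km_subtype{s}.tsv", sep="\t", index=False)
    print(pd.DataFrame(rows).to_string(index=False))
    print(f"log-rank between subtypes: chi2 = {chi2:.2f}, p = {p:.3g}")

    for cov in ("stage", "grade"):
        table = pd.crosstab(subtypes.map(lambda v: min(int(v), 2)),
                            annot.loc[subtypes.index, cov])
        c2, df_, pv = survival.chisq_clinical(table)
        print(f"clinical {cov}: chi2 = {c2:.2f} (df {df_}), p = {pv:.3g}")

    net = pd.read_csv(ROOT / "triplets.tsv", sep="\t")
    members = sorted(set(net[net["validated"]][["mirna", "lncrna", "mrna"]]
                         .to_numpy().ravel()))
    out = []
    layer_of = {"mrna": "mRNA", "mir": "miRNA", "lnc": "lncRNA"}
    exprs = {layer: ExpressionMatrix.from_tsv(ROOT / "data" / f"expr_{layer}.tsv", layer)
             for layer in ("mRNA", "miRNA", "lncRNA")}
    for g in members:
        layer = layer_of[g.split(":")[0]]
        try:
            res = survival.gene_survival(exprs[layer].values.loc[g, subtypes.index], t, e)
        except InputError:
            continue
        out.append({"gene": g, **{k: round(v, 4) if isinstance(v, float) else v
                                  for k, v in res.items()}})
    gene_surv = pd.DataFrame(out)
    gene_surv.to_csv(ROOT / "gene_survival.tsv", sep="\t", index=False)
    if len(gene_surv):
        sig = gene_surv[gene_surv["p"] < 0.05]
        print(f"network genes with mean-split log-rank p < 0.05: "
              f"{len(sig)} of {len(gene_surv)}")


if __name__ == "__main__":
    main()
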