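# omicross

Multi-omic consensus subtype discovery and miRNA-mediated lncRNA–mRNA
crosstalk analysis for bulk tumor expression cohorts.

Given mRNA, miRNA and lncRNA expression matrices over shared samples, the
pipeline (i) consensus-clusters each layer (Monti subsampling, hierarchical
clustering on 1 − Pearson distance, reps = 50, K = 2..6), (ii) integrates the
layers by *cluster-of-clusters*: each sample becomes a binary membership
vector of length ∑Kᵢ and is re-clustered, (iii) picks the number of subtypes
K by a majority vote of four statistics — average silhouette width (ASW),
cophenetic correlation (CPCC), the relative change Δ(K) in the area under the
consensus CDF, and the proportion of ambiguous clustering
PAC = F(0.9) − F(0.1) — then (iv) characterizes the subtypes: tumor-vs-normal
differential expression (F test, BH FDR < 0.05, |log₂FC| > 0.57), gene-set
enrichment on the Signal2Noise ranking with the weighted running-sum
statistic and gene-set permutation, classifier evaluation (stratified 60/40
split, 10-fold CV, ROC/AUC) with feature-gene extraction, a miRNA-mediated
lncRNA–mRNA co-expression network over the differentially expressed feature
genes (|r| ≥ 0.4 and p < 0.05; a triplet is a co-expressed lncRNA–mRNA pair
both co-expressed with the same miRNA; validated when the miRNA–mRNA edge
appears in ≥ 4 of 6 target databases and the miRNA–lncRNA edge in ≥ 1 of 3),
and Kaplan–Meier / log-rank survival with 5-year rates and clinical
chi-square tests.

Because the original cohorts are controlled-access consortium data, the
package ships a first-class synthetic generator (`omicross.simulate`) that
plants known subtypes, DE genes, signed correlation triplets, prognostic
effects and clinical associations, and emits the ground truth so every stage
can be scored against what was planted.  See `docs/methods.md` for the model
and all conventions.

## Worked example

```python
from omicross import SimConfig, RunConfig, run_pipeline

cfg = RunConfig(sim=SimConfig(n_tumor=120, n_normal=20, k_true=2, seed=5),
                top_mad={"mRNA": 250, "miRNA": 60, "lncRNA": 250},
                seed=5, outdir="demo_run")
report = run_pipeline(cfg)
print(report["selected_k"], report["k_votes"])
print(report["subtype_ari"], report["five_year_rates"])
```

prints

```
2 {'asw': 2, 'cpcc': 2, 'pac': 2, 'delta': 2}
1.0 {'subtype1': 0.0, 'subtype2': 0.228212241653418}
```

— all four statistics vote for the planted K = 2, the recovered subtype
labels match the planted ones exactly (adjusted Rand index 1.0), and the two
subtypes separate strongly in survival (5-year rates ≈ 0% vs ≈ 23%; the
discovered label 1 happens to map onto the planted high-hazard subtype,
which carries a hazard ratio of 3).  `demo_run/` holds every stage's artifacts plus
`manifest.json` (parameters and SHA-256 of each artifact; rerunning with the
same seed reproduces it byte for byte) and `report.json`.

The same stages are available as numbered drivers over a shared cohort:

```sh
python analysis/01_simulate_cohort.py      # cohort + ground truth -> results/data/
python analysis/02_subtype_discovery.py    # CC per layer, CoC, K vote
python analysis/03_differential_expression.py
python analysis/04_enrichment.py           # GSEA + over-representation
python analysis/05_classification.py       # AUC / CV / feature genes / DEFGs
python analysis/06_crosstalk_network.py    # triplets + database validation
python analysis/07_survival_clinical.py    # K-M, log-rank, chi-square
```

and as a CLI (`omicross run-all --seed 5 --outdir demo_run`, plus per-stage
subcommands `simulate`, `preprocess`, `cluster`, `select-k`, `de`, `gsea`,
`survival`).

On the default cohort the drivers report: K = 2 selected unanimously with
ARI 1.0; all planted DE genes recovered per layer; the planted gene set at
NES ≈ 2.2, q ≈ 0 against random sets; AUC 1.0 per layer; and — the crosstalk
punchline — roughly twenty thousand raw co-expression triplets among the
DEFGs collapse to exactly the ten planted ones after target-database
validation.

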