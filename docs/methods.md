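# Methods

`omicross` re-creates, as a tested pipeline over synthetic data, a multi-omic
tumor-subtyping workflow: per-layer consensus clustering, cluster-of-clusters
integration with a four-statistic K vote, tumor-vs-normal differential
expression, subtype gene-set enrichment, a classifier-based feature-gene
protocol, miRNA-mediated lncRNA–mRNA crosstalk inference with target-database
validation, and survival/clinical readouts.  This note records the models,
the defaults and the judgment calls.

## Synthetic cohort model

Expression is log-normal: a gene's linear-scale value is
`2^(mu + effects + eps)` with `eps ~ N(0, noise_sd)` and per-gene baseline
`mu ~ U(1, 7)` (log2 FPKM/RPM-like).  All planted effects are exact log2
shifts:

- **Subtypes.** Tumors are split evenly into `k_true` subtypes; a fraction
  `subtype_frac` (default 0.10) of each layer's genes is raised by
  `subtype_shift` (default 3) in one randomly owned subtype.  Defaults put
  the separation at 3× the noise SD — a clearly clusterable regime.
- **DE genes.** A fraction `de_fraction` (default 0.10) of each layer's
  genes is shifted by ±`de_lfc` (default 1.5) in all tumors, half up, half
  down.
- **Triplets.** Each planted (miRNA, lncRNA, mRNA) triplet shares a
  unit-variance latent factor with signed member loadings
  (default signs −1/+1/+1: miRNA anti-correlated with both targets).  The
  loading is `lam = noise_sd * sqrt(|triplet_r|)` and the members' residual
  SD is `noise_sd * sqrt(1 − |triplet_r|)`, so each pairwise Pearson
  correlation is exactly ±`triplet_r` in expectation and triplet genes have
  the same total variance as every other gene.  The latent factor carries a
  subtype component (`triplet_subtype_assoc = 0.7` of its SD on the subtype
  axis): the crosstalk network downstream is built over
  subtype-discriminative feature genes, so a network that is discoverable at
  all must be subtype-linked.  Triplet members also receive the `de_lfc`
  tumor shift (a uniform tumor shift leaves within-tumor correlations
  untouched), which makes them DEGs, as the network genes are in the
  workflow being emulated.
- **Survival.** Event times are exponential with subtype-`g` hazard
  `base * hazard_ratio^(g−1)`; the baseline mean event time is
  `follow_up_max / 3` (default 3650/3 days).  Each sample is independently
  censored with probability `censor_rate` at a time uniform on
  (0, event time), so the expected censored fraction equals the configured
  rate exactly and `censor_rate = 0` yields all-event data.
- **Clinical covariates.** Two binary covariates whose adverse-level odds
  are multiplied by `clinical_odds^(subtype−1)` (default 3), for chi-square
  testing.

What the generator does **not** emulate: count-level noise (negative
binomial), library-size and batch artifacts, gene–gene correlation beyond
the planted structure, non-proportional hazards.  Green tests therefore
certify the pipeline's logic and calibration on idealized data, not its
behavior on real RNA-seq.

## Preprocessing

Per layer: drop the `floor(0.25 * n)` genes with the smallest linear-scale
arithmetic mean (ties keep earlier genes), then keep the genes with the
largest MAD of log2(x+1) (reference workflow: 3000 mRNA / 300 miRNA /
3000 lncRNA).  The MAD scale constant is omitted — it cannot change a top-N
ranking.  Clustering input is per-gene median-centered log2(x+1); centering
keeps absolute expression level from dominating the Pearson distance.

## Consensus clustering

Monti consensus: per rep (default 50), sample `ceil(0.8 n)` samples without
replacement, cluster by complete-linkage hierarchical clustering on the
1 − Pearson distance, and tally co-clustering over co-sampling; final labels
cut the dendrogram of 1 − M.  The full sample–sample distance matrix is
computed once and subset per rep — Pearson distance between two samples does
not depend on which other samples were drawn, so this is exactly equivalent
and much faster.  One master seed drives the subsample draws in rep order;
the same draws are reused across K so per-K results are comparable.  The
0.8 item fraction is the wrapped tool's default (the source protocol names
reps, linkage, algorithm, K range and distance but not the fraction).

Cutting a dendrogram at K can yield fewer than K clusters when merge heights
tie (e.g. a two-block consensus matrix cut at K = 5); labels are therefore
contiguous from 1 but not guaranteed to reach K.

## Cluster-of-clusters and K selection

Samples are encoded as binary membership vectors of length `sum(K_i)` over
the layers (one indicator block per layer) and consensus clustering is
re-run on the encoded rows with the same Pearson distance.  Each layer's
`K_i` is its PAC argmin (see below), restricted to eligible K, with exact
ties going to the larger K.

Four statistics score each candidate K of the CoC run: area under the
consensus-CDF `A(K)` and its relative change `delta(K)`
(`delta(2) = A(2)`); PAC = CDF(0.9) − CDF(0.1) (standard thresholds, the
cited method's defaults); average silhouette width of the final labels; and
the cophenetic correlation of each K's final dendrogram against 1 − M.
Each casts one vote — ASW and CPCC argmax, PAC argmin, delta the largest K
with `delta(K) >= 0.1` (a declared elbow rule replacing visual inspection) —
and the majority wins, the smallest voted K breaking ties.

Two eligibility rules keep the vote meaningful on degenerate tables: a K
whose final labeling cannot realize K clusters is ineligible, and so is a K
whose smallest cluster holds under 5% of samples (`min_cluster_frac`) — a
straggler split, not a subtype.  A metric tied exactly across eligible K
votes for the largest of them: a finer clustering that is *equally* clean is
evidence for more structure, while the majority tie still resolves
conservatively to the smallest K.  Without these rules, a clean three-subtype
cohort ties PAC/CPCC at their optima for K = 2 and 3 and the vote
systematically under-selects.

## Differential expression

One-way ANOVA F on log2(x+1) per gene (two groups: F = t² of the pooled
t-test; df 1, n−2), BH step-up FDR across genes, and
`lfc = log2((mean_t + 1)/(mean_n + 1))` on linear values (the pseudocount
guards zero means in FPKM-like data).  Calls are strict: up iff q < 0.05 and
lfc > 0.57, down mirrored.  Genes with zero spread score F = 0, p = 1.

## GSEA and over-representation

Genes are ranked by Signal2Noise `(mu1 − mu2)/(sd1 + sd2)` with the
canonical floors `sd >= 0.2 |mu|` (0.2 when mu = 0); ties break by gene ID.
The weighted running sum adds `|s|^w / N_R` at hits and subtracts
`1/(N − N_H)` at misses; ES is the signed maximal deviation.  Null ES per
set size comes from `n_perm` random same-size gene sets (gene-set
permutation, as in the emulated protocol — an anticonservative choice that
is the protocol's, not ours); NES divides ES by the mean |null ES| of
matching sign; nominal p is the same-sign null tail; FDR q is the usual
ratio of pooled-null to observed NES tail fractions, capped at 1.  Set-size
filter 15–500, configurable.  ES extrema occur only at hit positions, so
null ES is computed in O(set size) per permutation.  Over-representation is
a one-sided hypergeometric upper tail per GMT set with BH across sets.

## Classification protocol

The evaluation is generic over a backend contract (fit / per-sample
probability / nonnegative importance).  Stratified 60/40 split uses
largest-remainder per-class allocation; 10-fold stratified CV reports mean
accuracy at threshold 0.5; AUC is the trapezoidal ROC area (equal to
Mann–Whitney with ties at ½).  Two backends ship: a deterministic
centroid-logistic stub and gradient-boosted trees (defaults: max_depth 14,
2000 rounds, gamma 1, min_child_weight 1; tests and drivers use fewer rounds
as a problem-size choice).  Feature genes are those with importance > 0
(descending, ties by ID) — the retained-feature rule is a declared proxy, as
the emulated protocol does not state a cutoff.  On cleanly separable
synthetic cohorts boosted trees stop after a few representative splits and
their importance support collapses to a handful of genes; the analysis
drivers therefore report the tree backend's AUC/CV but rank feature genes
with the dense-support centroid backend.  DEFGs are feature genes ∩ DEGs,
partitioned by layer.

## Crosstalk network

Pairwise Pearson correlation on log2(x+1) over tumor samples (tumor-only by
default; the subtype analysis concerns tumors), two-sided p from
`t = r sqrt(n−2)/sqrt(1−r²)`.  Co-expression requires `|r| >= 0.4`
(inclusive) and `p < 0.05` (strict).  A triplet is any miRNA co-expressed
with both members of a co-expressed lncRNA–mRNA pair; no sign constraint is
applied (both signs occur in the emulated network).  Validation requires the
miRNA–mRNA edge in ≥ 4 of 6 database flag columns and the miRNA–lncRNA edge
in ≥ 1 of the 3 designated columns (miRWalk/miRanda/Targetscan analogues);
absent evidence rows count as zero support.  The synthetic evidence table
plants support above these thresholds for true edges and below them for
decoys, so validated = planted exactly in the recovery studies.

## Survival and clinical readouts

Mean split (ties to "high", per the emulated wording; configurable),
Kaplan–Meier product-limit with events before censorings at tied times,
two-group log-rank with hypergeometric variance, survival rate at a horizon
(default 1825 days = 5 years) as S at the last event time ≤ horizon, and
Pearson chi-square without continuity correction for clinical tables.  The
KM and log-rank implementations are cross-checked against lifelines in the
tests.

## Problem sizes and determinism

The analysis drivers and acceptance studies run a 120-tumor / 20-normal
cohort with 300/80/300 genes per layer, reps = 50, K ≤ 6 — a deliberate
desk-scale rendering of the emulated cohort (403 tumors, thousands of
genes).  All randomness flows from one master seed through named per-stage
substreams (`numpy.random.SeedSequence`); the pipeline manifest records
parameters and artifact SHA-256 digests and contains no timestamps, so one
seed reproduces it byte for byte.

## Known limitations

- The log-normal generator understates the heavy tails and mean–variance
  coupling of real RNA-seq; calibration results (e.g. BH null behavior)
  transfer only approximately.
- Gene-set permutation GSEA is anticonservative relative to phenotype
  permutation on correlated genes.
- The K vote's eligibility thresholds (5% minimum cluster size, 0.1 delta
  elbow) are declared conventions; cohorts with genuinely tiny subtypes
  need `min_cluster_frac` lowered.
- Validation evidence is synthetic plumbing shaped like a miRWalk2.0 export;
  no sequence-based target prediction is attempted.
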