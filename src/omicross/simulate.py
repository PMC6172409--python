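"""Synthetic multi-omic data generator with planted ground truth.

Emulates the statistical structure the downstream analysis assumes: three
co-measured omics layers (mRNA / miRNA / lncRNA) over shared tumor and normal
samples, with

* ``k_true`` planted tumor subtypes separated by a log2-scale mean shift on a
  fraction of each layer's genes,
* tumor-vs-normal differentially expressed genes of a stated log2 fold change,
* miRNA-mediated lncRNA-mRNA triplets generated from a shared per-triplet
  latent factor with signed loadings, giving controlled pairwise Pearson
  correlations,
* subtype-linked exponential survival with independent censoring, and
* categorical clinical covariates associated with subtype.

Expression is emitted on the linear (FPKM/RPM-like) scale: a gene's value is
``2 ** (mu + effects + eps)`` with ``eps ~ Normal(0, noise_sd)``, so every
planted effect is exact on the log2 scale.  The generator returns a
:class:`~omicross.datatypes.TruthSet` so recovery tests can score the pipeline
against what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, InputError, TruthSet, namespace_gene

#: the six target-database flag columns (miRWalk2.0-style evidence table)
DB_COLUMNS = ("db_mirwalk", "db_miranda", "db_mirdb", "db_mirnamap", "db_rna22", "db_targetscan")
#: the three columns that count for miRNA-lncRNA evidence
LNC_DB_COLUMNS = ("db_mirwalk", "db_miranda", "db_targetscan")


@dataclass
class SimConfig:
    """Study-condition parameters for one synthetic dataset.

    Defaults are a desk-scale rendering of a two-subtype bulk tumor cohort:
    120 tumors / 20 normals, a few hundred genes per layer, subtype shift of
    three log2 units on 10% of genes against noise_sd = 1 (so separation =
    3 x noise), DE genes at |log2FC| = 1.5, and triplets at |r| = 0.7.
    """

    n_tumor: int = 120
    n_normal: int = 20
    n_mrna: int = 300
    n_mirna: int = 80
    n_lncrna: int = 300
    k_true: int = 2
    subtype_shift: float = 3.0  # log2 mean separation between subtypes
    subtype_frac: float = 0.10  # fraction of each layer's genes carrying it
    de_fraction: float = 0.10
    de_lfc: float = 1.5
    n_triplets: int = 10
    triplet_r: float = 0.7
    # per-member latent loading signs (miRNA, lncRNA, mRNA); edge signs are
    # their pairwise products, e.g. (-1, +1, +1) -> miRNA negatively
    # correlated with both targets, lncRNA-mRNA positively (ceRNA-like)
    triplet_signs: tuple[int, int, int] = (-1, 1, 1)
    # fraction of the triplet latent factor's standard deviation carried by
    # the subtype axis: crosstalk modules are subtype-related structures, so
    # their members must be subtype-discriminative enough to surface among
    # the classifier's feature genes
    triplet_subtype_assoc: float = 0.7
    noise_sd: float = 1.0
    hazard_ratio: float = 3.0
    censor_rate: float = 0.2
    follow_up_max: float = 3650.0  # days; sets the event-time scale
    n_prognostic: int = 2
    clinical_odds: float = 3.0  # subtype-2 odds multiplier for covariate levels
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_tumor, self.n_normal, self.n_mrna, self.n_mirna,
                  self.n_lncrna, self.k_true, self.n_triplets)
        if any(c < 1 for c in counts[:6]) or self.n_triplets < 0:
            raise InputError("all counts must be >= 1 (n_triplets >= 0)")
        if not (0.0 <= self.de_fraction <= 1.0 and 0.0 <= self.censor_rate <= 1.0):
            raise InputError("de_fraction and censor_rate must lie in [0, 1]")
        if not abs(self.triplet_r) < 1.0:
            raise InputError("|triplet_r| must be < 1")
        if self.noise_sd <= 0:
            raise InputError("noise_sd must be > 0")
        if set(np.sign(self.triplet_signs)) - {-1, 1}:
            raise InputError("triplet_signs must be +/-1")

    @property
    def layer_sizes(self) -> dict[str, int]:
        return {"mRNA": self.n_mrna, "miRNA": self.n_mirna, "lncRNA": self.n_lncrna}


def _gene_names(layer: str, n: int) -> list[str]:
    stem = {"mRNA": "G", "miRNA": "miR-", "lncRNA": "LNC"}[layer]
    return [namespace_gene(layer, f"{stem}{i + 1:04d}") for i in range(n)]


def generate_dataset(
    config: SimConfig,
) -> tuple[dict[str, ExpressionMatrix], pd.DataFrame, TruthSet]:
    """Generate the three expression layers, sample annotations and truth.

    Returns ``(layers, annotation, truth)`` where ``layers`` maps layer name
    to :class:`ExpressionMatrix`, and ``annotation`` is indexed by sample with
    columns ``group`` (tumor/normal), ``subtype``, ``time``, ``event`` and two
    categorical clinical covariates.  Identical config (including seed) gives
    bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    tumors = [f"T{i + 1:04d}" for i in range(config.n_tumor)]
    normals = [f"N{i + 1:04d}" for i in range(config.n_normal)]
    samples = tumors + normals
    is_tumor = np.array([True] * config.n_tumor + [False] * config.n_normal)

    # balanced subtype assignment, shuffled
    base = np.repeat(np.arange(1, config.k_true + 1),
                     int(np.ceil(config.n_tumor / config.k_true)))[: config.n_tumor]
    subtype = rng.permutation(base)

    # triplet gene bookkeeping: members drawn from a reserved tail of each
    # layer so they never overlap subtype-informative or DE genes
    if config.n_triplets > min(config.layer_sizes.values()):
        raise InputError(
            f"n_triplets={config.n_triplets} exceeds the smallest layer "
            f"({min(config.layer_sizes.values())} genes)")

    # latent factor loading: pairwise r = lam^2 / (lam^2 + resid^2); the
    # variance is split (lam^2 + resid^2 = noise_sd^2) so triplet genes have
    # the same total spread as every other gene
    lam = config.noise_sd * np.sqrt(abs(config.triplet_r))
    triplet_resid_sd = config.noise_sd * np.sqrt(1.0 - abs(config.triplet_r))
    # latent factor: unit-variance mixture of the subtype axis and noise; the
    # pairwise correlation between members is lam^2/noise_sd^2 either way
    alpha = config.triplet_subtype_assoc
    contrast = np.where(np.r_[subtype, np.full(config.n_normal, 0)] == config.k_true,
                        1.0, -1.0)
    if config.n_tumor > 1:
        tumor_c = contrast[:config.n_tumor]
        sd_c = tumor_c.std()
        contrast[:config.n_tumor] = ((tumor_c - tumor_c.mean()) / sd_c
                                     if sd_c > 0 else 0.0)
    contrast[config.n_tumor:] = rng.standard_normal(config.n_normal)
    latent = (alpha * contrast[None, :]
              + np.sqrt(1.0 - alpha**2)
              * rng.standard_normal((config.n_triplets, len(samples))))

    layers: dict[str, ExpressionMatrix] = {}
    de_genes: dict[str, str] = {}
    triplet_members: dict[str, list[str]] = {}
    subtype_gene_effects: dict[str, np.ndarray] = {}

    sign_by_layer = dict(zip(("miRNA", "lncRNA", "mRNA"), config.triplet_signs))

    for layer, n_genes in config.layer_sizes.items():
        genes = _gene_names(layer, n_genes)
        n_sub = int(round(config.subtype_frac * n_genes))
        n_de = int(round(config.de_fraction * n_genes))
        if n_sub + n_de + config.n_triplets > n_genes:
            raise InputError(f"layer {layer}: subtype + DE + triplet genes exceed n_genes")

        mu = rng.uniform(1.0, 7.0, size=n_genes)  # baseline log2 abundance
        log2x = mu[:, None] + rng.normal(0.0, config.noise_sd, size=(n_genes, len(samples)))

        # subtype effect: first n_sub genes, each raised in one subtype
        sub_effect = np.zeros((n_genes, len(samples)))
        owner = rng.integers(1, config.k_true + 1, size=n_sub)
        for g in range(n_sub):
            hit = is_tumor & (np.r_[subtype, np.zeros(config.n_normal, int)] == owner[g])
            sub_effect[g, hit] = config.subtype_shift
        if config.subtype_shift != 0:
            log2x += sub_effect
        subtype_gene_effects[layer] = owner

        # DE effect: next n_de genes, half up half down in tumors
        for j in range(n_de):
            g = n_sub + j
            direction = "up" if j % 2 == 0 else "down"
            delta = config.de_lfc if direction == "up" else -config.de_lfc
            log2x[g, is_tumor] += delta
            de_genes[genes[g]] = direction

        # triplet members: reserved tail genes share the per-triplet latent
        # factor; they also carry the tumor-vs-normal DE effect (a uniform
        # tumor shift leaves within-tumor correlations untouched) so that the
        # downstream DEFG-restricted network stage can reach them, as the
        # crosstalk analysis operates on DEFGs
        sgn = sign_by_layer[layer]
        for t in range(config.n_triplets):
            g = n_genes - config.n_triplets + t
            log2x[g, :] = mu[g] + sgn * lam * latent[t] + \
                rng.normal(0.0, triplet_resid_sd, size=len(samples))
            if config.de_lfc != 0:
                log2x[g, is_tumor] += config.de_lfc
                de_genes[genes[g]] = "up"
            triplet_members.setdefault(layer, []).append(genes[g])

        layers[layer] = ExpressionMatrix(
            pd.DataFrame(np.power(2.0, log2x), index=genes, columns=samples), layer)

    triplets = []
    s_mir, s_lnc, s_mrna = config.triplet_signs
    for t in range(config.n_triplets):
        triplets.append({
            "mirna": triplet_members["miRNA"][t],
            "lncrna": triplet_members["lncRNA"][t],
            "mrna": triplet_members["mRNA"][t],
            "sign_mir_lnc": int(s_mir * s_lnc),
            "sign_mir_mrna": int(s_mir * s_mrna),
            "sign_lnc_mrna": int(s_lnc * s_mrna),
        })

    subtype_labels = pd.Series(subtype, index=tumors, name="subtype")

    # prognostic genes: subtype-informative mRNAs owned by the highest-hazard
    # subtype (hazard direction +1: high expression -> high hazard when
    # hazard_ratio > 1)
    prognostic: dict[str, float] = {}
    mrna_genes = list(layers["mRNA"].genes)
    owners = subtype_gene_effects["mRNA"]
    high_risk = config.k_true  # subtype k_true carries the largest hazard (see generate_survival)
    cands = [i for i in range(len(owners)) if owners[i] == high_risk]
    for i in cands[: config.n_prognostic]:
        prognostic[mrna_genes[i]] = 1.0 if config.hazard_ratio >= 1 else -1.0

    truth = TruthSet(subtype_labels=subtype_labels, de_genes=de_genes,
                     triplets=triplets, prognostic_genes=prognostic)

    surv = generate_survival(subtype_labels, config,
                             rng=np.random.default_rng(rng.integers(2**31)))
    covar = _clinical_covariates(subtype_labels, config,
                                 rng=np.random.default_rng(rng.integers(2**31)))

    annot = pd.DataFrame(index=pd.Index(samples, name="sample"))
    annot["group"] = np.where(is_tumor, "tumor", "normal")
    annot["subtype"] = subtype_labels.reindex(annot.index)
    annot = annot.join(surv).join(covar)
    return layers, annot, truth


def generate_survival(
    labels: pd.Series | Sequence[int],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Exponential event times with a multiplicative subtype hazard.

    Group ``g`` (1-based) has hazard ``base * hazard_ratio**(g - 1)``; the
    baseline mean event time is ``follow_up_max / 3``.  Each sample is
    independently censored with probability ``censor_rate``, at a time drawn
    uniformly on ``(0, event time)``, so the expected censored fraction equals
    the configured rate exactly.
    """
    if config.hazard_ratio <= 0:
        raise InputError("hazard_ratio must be > 0")
    labels = pd.Series(labels)
    if labels.empty:
        raise InputError("labels must be nonempty")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    base = 3.0 / config.follow_up_max
    hazard = base * np.power(config.hazard_ratio, labels.to_numpy(float) - 1.0)
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.random(len(labels)) < config.censor_rate
    u = rng.random(len(labels))
    time = np.where(censored, u * t_event, t_event)
    event = (~censored).astype(int)
    return pd.DataFrame({"time": time, "event": event}, index=labels.index)


def _clinical_covariates(
    labels: pd.Series, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Two categorical covariates with subtype-dependent level probabilities.

    Baseline odds of the adverse level are 1:1; subtype k multiplies them by
    ``clinical_odds**(k - 1)``.
    """
    out = {}
    for name, levels in (("stage", ("II", "III-IV")), ("grade", ("low", "high"))):
        odds = np.power(config.clinical_odds, labels.to_numpy(float) - 1.0)
        p_adverse = odds / (1.0 + odds)
        draw = rng.random(len(labels)) < p_adverse
        out[name] = np.where(draw, levels[1], levels[0])
    return pd.DataFrame(out, index=labels.index)


def generate_target_db(
    truth: TruthSet,
    decoy_fraction: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """miRWalk2.0-style evidence table for the planted triplet edges.

    Every planted miRNA-mRNA edge is supported in >= 4 of the 6 database
    columns; every planted miRNA-lncRNA edge in >= 1 of the 3 designated
    lncRNA columns.  Decoy rows (``decoy_fraction`` x number of planted rows)
    pair planted miRNAs with non-target genes at sub-threshold support.
    """
    if not truth.triplets:
        raise InputError("truth has no planted triplets")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []

    def _row(mir: str, target: str, flags: dict[str, int]) -> dict:
        r = {"mirna": mir, "target": target}
        r.update({c: flags.get(c, 0) for c in DB_COLUMNS})
        return r

    lnc_pool = sorted({t["lncrna"] for t in truth.triplets})
    mrna_pool = sorted({t["mrna"] for t in truth.triplets})
    for t in truth.triplets:
        n_sup = rng.integers(4, 7)  # 4..6 of 6
        cols = rng.choice(len(DB_COLUMNS), size=n_sup, replace=False)
        rows.append(_row(t["mirna"], t["mrna"], {DB_COLUMNS[c]: 1 for c in cols}))
        n_sup = rng.integers(1, 4)  # 1..3 of the designated 3
        cols = rng.choice(len(LNC_DB_COLUMNS), size=n_sup, replace=False)
        rows.append(_row(t["mirna"], t["lncrna"], {LNC_DB_COLUMNS[c]: 1 for c in cols}))

    planted_pairs = {(r["mirna"], r["target"]) for r in rows}
    n_decoys = int(round(decoy_fraction * len(rows)))
    mirs = sorted({t["mirna"] for t in truth.triplets})
    attempts = 0
    while n_decoys > 0 and attempts < 50 * n_decoys:
        attempts += 1
        mir = mirs[rng.integers(len(mirs))]
        pool = mrna_pool if rng.random() < 0.5 else lnc_pool
        target = pool[rng.integers(len(pool))]
        if (mir, target) in planted_pairs:
            continue
        if target in mrna_pool:
            n_sup = rng.integers(0, 4)  # 0..3 of 6: below the 4-of-6 rule
            cols = rng.choice(len(DB_COLUMNS), size=n_sup, replace=False)
            flags = {DB_COLUMNS[c]: 1 for c in cols}
        else:
            other = [c for c in DB_COLUMNS if c not in LNC_DB_COLUMNS]
            n_sup = rng.integers(0, len(other) + 1)  # none of the designated 3
            cols = rng.choice(len(other), size=n_sup, replace=False)
            flags = {other[c]: 1 for c in cols}
        rows.append(_row(mir, target, flags))
        planted_pairs.add((mir, target))
        n_decoys -= 1
    return pd.DataFrame(rows, columns=["mirna", "target", *DB_COLUMNS])
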