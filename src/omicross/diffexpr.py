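"""Tumor-vs-normal differential expression.

Per gene: a one-way ANOVA F test on log2(x+1) values (for two groups this is
exactly the squared equal-variance t statistic), Benjamini-Hochberg FDR
control across genes, and a pseudocounted log2 fold change on the linear
scale.  A gene is called differentially expressed when q < 0.05 and
|log2FC| > 0.57 (both strict, the second being about a 1.49-fold change).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix, InputError


def _group_masks(groups: pd.Series, samples: pd.Index) -> tuple[np.ndarray, np.ndarray]:
    g = groups.reindex(samples)
    levels = pd.unique(g.dropna())
    if len(levels) != 2:
        raise InputError(f"need exactly two group levels, got {list(levels)}")
    m1 = (g == levels[0]).to_numpy()
    m2 = (g == levels[1]).to_numpy()
    if m1.sum() < 2 or m2.sum() < 2:
        raise InputError("both groups need >= 2 samples")
    return m1, m2


def two_group_f_test(m: ExpressionMatrix, groups: pd.Series) -> pd.DataFrame:
    """Per-gene one-way ANOVA F and p on log2(x+1), df = (1, n - 2).

    Genes with zero between-group difference and zero within-group variance
    get F = 0, p = 1 (no evidence, rather than 0/0).
    """
    m1, m2 = _group_masks(groups, m.samples)
    x = m.log2p1().to_numpy()
    a, b = x[:, m1], x[:, m2]
    n1, n2 = a.shape[1], b.shape[1]
    n = n1 + n2
    mean1, mean2 = a.mean(axis=1), b.mean(axis=1)
    grand = (n1 * mean1 + n2 * mean2) / n
    ss_between = n1 * (mean1 - grand) ** 2 + n2 * (mean2 - grand) ** 2
    ss_within = ((a - mean1[:, None]) ** 2).sum(axis=1) + ((b - mean2[:, None]) ** 2).sum(axis=1)
    ms_within = ss_within / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ss_between / ms_within
    # degenerate: no spread at all -> no evidence
    f = np.where((ss_within == 0) & (ss_between == 0), 0.0, f)
    f = np.where(np.isinf(f), np.inf, f)
    p = stats.f.sf(f, 1, n - 2)
    p = np.where(f == np.inf, 0.0, p)
    return pd.DataFrame({"F": f, "p": p}, index=m.genes)


def log2_fold_change(m: ExpressionMatrix, groups: pd.Series,
                     numerator: str | None = None) -> pd.Series:
    """log2((mean_num + 1) / (mean_den + 1)) of linear-scale group means.

    ``numerator`` names the group level on top (default: first level in
    appearance order, i.e. tumor for tumor/normal annotations).
    """
    g = groups.reindex(m.samples)
    levels = list(pd.unique(g.dropna()))
    if numerator is not None:
        if numerator not in levels:
            raise InputError(f"{numerator!r} not a group level")
        levels = [numerator] + [l for l in levels if l != numerator]
    m1 = (g == levels[0]).to_numpy()
    m2 = (g == levels[1]).to_numpy()
    x = m.values.to_numpy()
    lfc = np.log2((x[:, m1].mean(axis=1) + 1.0) / (x[:, m2].mean(axis=1) + 1.0))
    return pd.Series(lfc, index=m.genes, name="log2fc")


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    arr = np.asarray(p, dtype=float)
    if arr.size and ((arr < 0) | (arr > 1)).any():
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def de_table(m: ExpressionMatrix, groups: pd.Series,
             fdr: float = 0.05, lfc_abs: float = 0.57,
             numerator: str | None = None) -> pd.DataFrame:
    """Full DE table: F, p, q, log2fc and the call in {up, down, none}."""
    tab = two_group_f_test(m, groups)
    tab["q"] = bh_adjust(tab["p"].to_numpy())
    tab["log2fc"] = log2_fold_change(m, groups, numerator=numerator)
    tab["call"] = call_degs(tab, fdr=fdr, lfc_abs=lfc_abs)
    return tab


def call_degs(de: pd.DataFrame, fdr: float = 0.05, lfc_abs: float = 0.57) -> pd.Series:
    """Strict-threshold calls: up if q < fdr and lfc > lfc_abs, down mirrored."""
    up = (de["q"] < fdr) & (de["log2fc"] > lfc_abs)
    down = (de["q"] < fdr) & (de["log2fc"] < -lfc_abs)
    call = pd.Series("none", index=de.index, name="call")
    call[up] = "up"
    call[down] = "down"
    return call


def deg_lists(de: pd.DataFrame) -> tuple[list[str], list[str]]:
    """(up, down) DEG ID lists from a called DE table."""
    return (list(de.index[de["call"] == "up"]), list(de.index[de["call"] == "down"]))
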