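"""Gene-set enrichment for the subtype contrast, plus over-representation.

The GSEA half ranks genes by the Signal2Noise statistic

    s2n = (mu1 - mu2) / (sigma1 + sigma2),   sigma floored at 0.2 * |mu|
                                             (0.2 when mu = 0),

then walks the ranked list with the weighted running-sum statistic: genes in
the set add |score|^weight / N_R, genes outside subtract 1 / (N - N_H); the
enrichment score ES is the signed maximal deviation from zero.  Significance
uses gene-set permutation: null ES values come from random same-size sets of
ranked genes, NES divides ES by the mean |null ES| of matching sign, and the
FDR q-value is the usual ratio of null-to-observed NES tail fractions.

The over-representation half (`ora_enrich`) is a generic GMT-based
hypergeometric test with BH correction, used to annotate gene lists.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, InputError
from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- ranking

def signal_to_noise(m: ExpressionMatrix | pd.DataFrame, groups: pd.Series,
                    sigma_floor: float = 0.2, group1: str | None = None) -> pd.Series:
    """Signal2Noise score per gene, sorted descending (ties by gene ID).

    An :class:`ExpressionMatrix` is scored on log2(x+1) values; a plain
    DataFrame is scored as given.  Group 1 is ``group1`` when given, else the
    first level of ``groups`` in order of appearance; positive scores mean
    higher in group 1.
    """
    if isinstance(m, ExpressionMatrix):
        x = m.log2p1()
    else:
        x = m
    g = groups.reindex(x.columns)
    levels = list(pd.unique(g.dropna()))
    if len(levels) != 2:
        raise InputError("need exactly two group levels")
    if group1 is not None:
        if group1 not in levels:
            raise InputError(f"{group1!r} is not a group level")
        levels = [group1] + [l for l in levels if l != group1]
    m1 = (g == levels[0]).to_numpy()
    m2 = (g == levels[1]).to_numpy()
    if m1.sum() < 3 or m2.sum() < 3:
        raise InputError("Signal2Noise needs >= 3 samples per group")
    a, b = x.to_numpy()[:, m1], x.to_numpy()[:, m2]

    def _stats(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mu = y.mean(axis=1)
        sd = y.std(axis=1, ddof=1)
        floor = np.where(mu == 0, sigma_floor, sigma_floor * np.abs(mu))
        return mu, np.maximum(sd, floor)

    mu1, sd1 = _stats(a)
    mu2, sd2 = _stats(b)
    s2n = pd.Series((mu1 - mu2) / (sd1 + sd2), index=x.index, name="s2n")
    order = sorted(range(len(s2n)), key=lambda i: (-s2n.iloc[i], s2n.index[i]))
    return s2n.iloc[order]


# ---------------------------------------------------------------- running sum

def _es_at_positions(weights: np.ndarray, positions: np.ndarray, n: int) -> float:
    """ES from hit positions only (O(#hits); extrema occur at hits)."""
    h = len(positions)
    miss = 1.0 / (n - h) if n > h else 0.0
    n_r = weights.sum()
    if n_r == 0:
        raise InputError("all in-set scores are zero; ES undefined")
    cum = np.cumsum(weights) / n_r
    ranks = np.arange(h)
    after = cum - (positions - ranks) * miss  # value just after each hit
    before = np.concatenate(([0.0], cum[:-1])) - (positions - ranks) * miss
    hi = after.max()
    lo = min(before.min(), 0.0)
    return float(hi if hi >= -lo else lo)


def enrichment_score(ranked: pd.Series, gene_set: set[str] | list[str],
                     weight: float = 1.0) -> tuple[float, np.ndarray]:
    """Weighted running-sum enrichment score and the full running sum.

    ``ranked`` is the descending Signal2Noise series.  Returns (ES, running
    sum after each list position).
    """
    in_set = ranked.index.isin(set(gene_set))
    n, n_h = len(ranked), int(in_set.sum())
    if n_h == 0:
        raise InputError("gene set has empty intersection with the ranked list")
    w = np.abs(ranked.to_numpy()) ** weight
    n_r = w[in_set].sum()
    if n_r == 0:
        raise InputError("all in-set scores are zero; ES undefined")
    steps = np.where(in_set, w / n_r, -1.0 / (n - n_h) if n > n_h else 0.0)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), running


# ---------------------------------------------------------------- GSEA proper

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT reader: tab-separated `name <tab> description <tab> genes...`."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise InputError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              description: str = "na") -> None:
    lines = ["\t".join([name, description, *genes]) for name, genes in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def run_gsea(
    m: ExpressionMatrix | pd.DataFrame,
    groups: pd.Series,
    gene_sets: dict[str, list[str]],
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
    min_size: int = 15,
    max_size: int = 500,
) -> pd.DataFrame:
    """Gene-set-permutation GSEA over a GMT dictionary.

    Returns one row per retained set: size, ES, NES, nominal p, FDR q.
    With ``n_perm=0`` the permutation columns are NaN.  Deterministic given
    the seed.
    """
    ranked = signal_to_noise(m, groups)
    universe = ranked.index
    n = len(universe)
    w_abs = np.abs(ranked.to_numpy()) ** weight

    kept: dict[str, np.ndarray] = {}
    for name, genes in gene_sets.items():
        pos = np.flatnonzero(universe.isin(set(genes)))
        if pos.size == 0:
            logger.info("gene set %s skipped: empty intersection", name)
            continue
        if not min_size <= pos.size <= max_size:
            continue
        kept[name] = pos
    if not kept:
        raise InputError("no gene sets survive the size filter")

    rows = []
    rng = np.random.default_rng(seed)
    null_by_size: dict[int, np.ndarray] = {}
    nes_null_pool: list[np.ndarray] = []
    for name, pos in kept.items():
        es = _es_at_positions(w_abs[pos], pos, n)
        size = pos.size
        if n_perm > 0:
            if size not in null_by_size:
                null = np.empty(n_perm)
                for i in range(n_perm):
                    rpos = np.sort(rng.choice(n, size=size, replace=False))
                    null[i] = _es_at_positions(w_abs[rpos], rpos, n)
                null_by_size[size] = null
            null = null_by_size[size]
            same = null[np.sign(null) == np.sign(es)] if es != 0 else null
            denom_mean = np.abs(same).mean() if same.size else np.nan
            nes = es / denom_mean if denom_mean and np.isfinite(denom_mean) else np.nan
            p = float(np.mean(np.abs(same) >= abs(es))) if same.size else 1.0
            # pooled signed-NES null for the FDR ratio
            pos_mean = np.abs(null[null >= 0]).mean() if (null >= 0).any() else np.nan
            neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
            nes_null = np.where(null >= 0, null / pos_mean, null / neg_mean)
            nes_null_pool.append(nes_null[np.isfinite(nes_null)])
        else:
            nes, p = np.nan, np.nan
        rows.append({"set": name, "size": int(size), "ES": es, "NES": nes, "p": p})

    out = pd.DataFrame(rows).set_index("set")
    if n_perm > 0:
        pooled = np.concatenate(nes_null_pool)
        obs = out["NES"].to_numpy()
        q = np.full(len(out), np.nan)
        for i, nes in enumerate(obs):
            if not np.isfinite(nes):
                continue
            if nes >= 0:
                null_tail = np.mean(pooled[pooled >= 0] >= nes) if (pooled >= 0).any() else 0.0
                obs_tail = np.mean(obs[obs >= 0] >= nes)
            else:
                null_tail = np.mean(pooled[pooled < 0] <= nes) if (pooled < 0).any() else 0.0
                obs_tail = np.mean(obs[obs < 0] <= nes)
            q[i] = min(1.0, null_tail / obs_tail) if obs_tail > 0 else np.nan
        out["q"] = q
    else:
        out["q"] = np.nan
    return out.sort_values("NES", ascending=False)


# ---------------------------------------------------------------- ORA

def ora_enrich(query: list[str], universe: list[str],
               gene_sets: dict[str, list[str]]) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    One-sided upper-tail p per set (overlap at least as large as observed),
    BH-adjusted across sets.  ``query`` must be a subset of ``universe``.
    """
    if not query:
        raise InputError("query gene list is empty")
    uni = set(universe)
    q = set(query)
    if not q <= uni:
        raise InputError("query must be a subset of the universe")
    rows = []
    for name, genes in gene_sets.items():
        s = set(genes) & uni
        k = len(s & q)
        p = float(stats.hypergeom.sf(k - 1, len(uni), len(s), len(q)))
        rows.append({"set": name, "set_size": len(s), "overlap": k, "p": min(p, 1.0)})
    out = pd.DataFrame(rows).set_index("set")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values("p")
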