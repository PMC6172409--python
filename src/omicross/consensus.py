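"""Monti-style consensus clustering.

Repeatedly subsample the samples (without replacement, default 80%), cluster
each subsample by hierarchical clustering on the 1 - Pearson-correlation
distance, and aggregate: the consensus index of a sample pair is the fraction
of subsamples containing both in which they landed in the same cluster,

    M(i, j) = (# runs i, j co-clustered) / (# runs i, j co-sampled).

A clean K shows a near-binary M; ambiguity shows as intermediate entries and
is what the PAC / CDF-area statistics in :mod:`omicross.kselect` quantify.

The full sample-sample distance matrix is computed once and subset per rep:
the Pearson distance between two samples does not depend on which other
samples were drawn, so this is exactly equivalent to recomputing per rep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import InputError

_LINKAGES = ("complete", "average", "single")


def pearson_distance(m: pd.DataFrame | np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between sample profiles (columns).

    ``m`` is features x samples.  Output is a dense symmetric matrix with
    zero diagonal and entries in [0, 2].
    """
    x = np.asarray(m, dtype=float)
    if x.shape[0] < 2:
        raise InputError("need >= 2 features to correlate sample profiles")
    sd = x.std(axis=0)
    if (sd == 0).any():
        idx = int(np.argmax(sd == 0))
        name = m.columns[idx] if isinstance(m, pd.DataFrame) else idx
        raise InputError(f"sample {name!r} has zero variance across features")
    r = np.corrcoef(x, rowvar=False)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def hclust_linkage(d: np.ndarray, method: str = "complete") -> np.ndarray:
    """Agglomerative linkage matrix from a square distance matrix."""
    if method not in _LINKAGES:
        raise InputError(f"linkage must be one of {_LINKAGES}")
    return linkage(squareform(d, checks=False), method=method)


def hclust_cut(d: np.ndarray, method: str = "complete", k: int = 2) -> np.ndarray:
    """Cut an agglomerative clustering of ``d`` into ``k`` clusters (1..k).

    Deterministic for a given distance matrix; scipy breaks merge ties by the
    smallest pair index.  Labels are renumbered so cluster 1 is the cluster of
    the first sample, then by first appearance.
    """
    n = d.shape[0]
    if not 1 <= k <= n:
        raise InputError(f"k={k} out of range 1..{n}")
    labels = fcluster(hclust_linkage(d, method), t=k, criterion="maxclust")
    return _renumber(labels)


def _renumber(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by order of first appearance (stable, 1-based)."""
    out = np.zeros_like(labels)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


@dataclass
class ConsensusResult:
    """Consensus matrix, tallies and final labels for one K."""

    k: int
    consensus: pd.DataFrame  # n x n in [0, 1], unit diagonal
    co_sampled: pd.DataFrame  # n x n integer tallies
    labels: pd.Series  # final per-sample cluster, 1..k
    linkage_matrix: np.ndarray = field(repr=False, default=None)
    rep_labels: list[pd.Series] = field(repr=False, default_factory=list)

    @property
    def samples(self) -> pd.Index:
        return self.consensus.index


def _tally(n: int, idx: np.ndarray, labels: np.ndarray,
           co_cluster: np.ndarray, co_sampled: np.ndarray) -> None:
    sub = np.ix_(idx, idx)
    co_sampled[sub] += 1
    same = (labels[:, None] == labels[None, :]).astype(np.int64)
    co_cluster[sub] += same


def build_consensus(
    data: pd.DataFrame,
    k_range: range | list[int] = range(2, 7),
    reps: int = 50,
    p_item: float = 0.8,
    method: str = "complete",
    seed: int = 0,
    distance: np.ndarray | None = None,
    keep_rep_labels: bool = False,
) -> dict[int, ConsensusResult]:
    """Consensus clustering of the columns of ``data`` for each K in ``k_range``.

    ``data`` is features x samples (already transformed/centered by the
    caller).  One master seed drives the per-rep subsample draws, consumed in
    rep order; the same draws are reused across K so per-K results are
    comparable.  ``distance`` may supply a precomputed sample-sample distance
    matrix (e.g. for binary cluster-of-clusters rows).
    """
    if reps < 1:
        raise InputError("reps must be >= 1")
    if not 0.0 < p_item <= 1.0:
        raise InputError("p_item must be in (0, 1]")
    samples = data.columns
    n = len(samples)
    ks = sorted(set(int(k) for k in k_range))
    if ks and ks[-1] > n:
        raise InputError(f"k_max={ks[-1]} exceeds n={n}")

    d_full = pearson_distance(data) if distance is None else np.asarray(distance, float)
    n_sub = int(np.ceil(p_item * n))
    rng = np.random.default_rng(seed)
    draws = [np.sort(rng.choice(n, size=n_sub, replace=False)) for _ in range(reps)]

    results: dict[int, ConsensusResult] = {}
    for k in ks:
        co_cluster = np.zeros((n, n), dtype=np.int64)
        co_sampled = np.zeros((n, n), dtype=np.int64)
        rep_labels: list[pd.Series] = []
        for idx in draws:
            sub_labels = hclust_cut(d_full[np.ix_(idx, idx)], method, k)
            _tally(n, idx, sub_labels, co_cluster, co_sampled)
            if keep_rep_labels:
                rep_labels.append(pd.Series(sub_labels, index=samples[idx]))
        never = (co_sampled == 0) & ~np.eye(n, dtype=bool)
        if never.any():
            warnings.warn(
                f"{int(never.sum()) // 2} sample pairs were never co-sampled; "
                "their consensus entries are set to 0", stacklevel=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            m = np.where(co_sampled > 0, co_cluster / np.maximum(co_sampled, 1), 0.0)
        np.fill_diagonal(m, 1.0)
        res = ConsensusResult(
            k=k,
            consensus=pd.DataFrame(m, index=samples, columns=samples),
            co_sampled=pd.DataFrame(co_sampled, index=samples, columns=samples),
            labels=pd.Series(np.zeros(n, dtype=int), index=samples),
            rep_labels=rep_labels,
        )
        final_clusters(res, method=method)
        results[k] = res
    return results


def final_clusters(res: ConsensusResult, method: str = "complete") -> pd.Series:
    """Final labels: hierarchical clustering of 1 - M cut at K (stored in res)."""
    d = 1.0 - res.consensus.to_numpy()
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    res.linkage_matrix = hclust_linkage(d, method)
    labels = _renumber(fcluster(res.linkage_matrix, t=res.k, criterion="maxclust"))
    res.labels = pd.Series(labels, index=res.samples, name="cluster")
    return res.labels


def recount_consensus(n: int, rep_index_sets: list[np.ndarray],
                      rep_labels: list[np.ndarray]) -> np.ndarray:
    """Brute-force consensus recount from stored per-rep labels (test oracle)."""
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for idx, labs in zip(rep_index_sets, rep_labels):
        for a in range(len(idx)):
            for b in range(len(idx)):
                i, j = idx[a], idx[b]
                den[i, j] += 1
                if labs[a] == labs[b]:
                    num[i, j] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    np.fill_diagonal(m, 1.0)
    return m
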