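"""Cluster-of-clusters (CoC) integration and cluster-number selection.

Per-layer consensus clusterings are integrated by encoding every sample as a
binary membership vector of length sum(K_i) over the t layers (exactly one 1
per layer block), re-running consensus clustering on the encoded rows, and
scoring each candidate K with four statistics:

* ``A(K)`` — area under the empirical CDF of the consensus-matrix entries,
  and its relative change ``delta(K)``;
* ``PAC`` — proportion of ambiguous clustering, the CDF mass between u1 and
  u2 (default 0.1 / 0.9): lower is cleaner;
* ``ASW`` — average silhouette width of the final labels;
* ``CPCC`` — cophenetic correlation of each K's final dendrogram.

Each statistic casts one vote (ASW and CPCC argmax, PAC argmin, delta(K) by an
elbow rule) and the majority wins, smallest K breaking ties — a deterministic
rendering of the usual visual inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_samples

from .consensus import ConsensusResult, build_consensus, pearson_distance
from .datatypes import InputError


def encode_coc(label_sets: list[pd.Series]) -> pd.DataFrame:
    """Binary samples x sum(K_i) encoding of per-dataset cluster labels.

    Block i holds K_i indicator columns; each row has exactly one 1 per
    block, so every row sums to the number of datasets t.
    """
    if not label_sets:
        raise InputError("need at least one labeling")
    index = label_sets[0].index
    for ls in label_sets[1:]:
        if not index.equals(ls.index):
            if set(index) != set(ls.index):
                raise InputError("labelings cover different samples")
            # same samples, different order: align
            ls = ls.reindex(index)
    blocks = []
    for i, ls in enumerate(label_sets):
        ls = ls.reindex(index)
        dummies = pd.get_dummies(ls.astype(int)).astype(int)
        dummies.columns = [f"d{i + 1}_c{c}" for c in dummies.columns]
        blocks.append(dummies)
    return pd.concat(blocks, axis=1)


def _lower_tri(m: pd.DataFrame | np.ndarray) -> np.ndarray:
    a = np.asarray(m, dtype=float)
    return a[np.tril_indices(a.shape[0], k=-1)]


def consensus_cdf_area(m: pd.DataFrame | np.ndarray) -> float:
    """Area under the empirical CDF of the lower-triangular consensus entries.

    The CDF is a right-continuous step function on [0, 1]; the area is the
    sum of step heights times segment widths.
    """
    vals = _lower_tri(m)
    uv, counts = np.unique(vals, return_counts=True)
    cdf = np.cumsum(counts) / vals.size
    edges = np.append(uv, 1.0)
    widths = np.diff(edges)  # last width is 1 - max entry (>= 0)
    return float(np.sum(cdf * widths))


def cdf_area_delta(results: dict[int, ConsensusResult]) -> tuple[dict[int, float], dict[int, float]]:
    """A(K) per K and the relative change delta(K).

    delta(2) = A(2); delta(K+1) = (A(K+1) - A(K)) / A(K).  Requires a
    contiguous K range starting at 2.
    """
    ks = sorted(results)
    if ks[0] != 2 or ks != list(range(2, ks[-1] + 1)):
        raise InputError("K range must be contiguous from 2")
    area = {k: consensus_cdf_area(results[k].consensus) for k in ks}
    return area, delta_from_areas(area)


def delta_from_areas(area: dict[int, float]) -> dict[int, float]:
    """Relative change in CDF area: delta(2) = A(2), then successive ratios."""
    ks = sorted(area)
    delta = {ks[0]: area[ks[0]]}
    for k in ks[1:]:
        prev = area[k - 1]
        delta[k] = (area[k] - prev) / prev if prev > 0 else np.inf
    return delta


def pac(res: ConsensusResult | pd.DataFrame | np.ndarray,
        u1: float = 0.1, u2: float = 0.9) -> float:
    """Proportion of ambiguous clustering: CDF(u2) - CDF(u1).

    Mass of consensus entries strictly between the thresholds (entries <= u1
    count as confidently apart, entries <= u2 as not-confidently together).
    Lower is cleaner; a block-perfect 0/1 matrix scores exactly 0.
    """
    if not 0.0 <= u1 < u2 <= 1.0:
        raise InputError("need 0 <= u1 < u2 <= 1")
    m = res.consensus if isinstance(res, ConsensusResult) else res
    vals = _lower_tri(m)
    return float(np.mean(vals <= u2) - np.mean(vals <= u1))


def asw(labels: pd.Series | np.ndarray, d: np.ndarray) -> float:
    """Average silhouette width of a labeling over a precomputed distance.

    Samples in singleton clusters and samples with a = b = 0 score 0.
    Undefined (raises) when fewer than two clusters are present.
    """
    labs = np.asarray(labels)
    if len(np.unique(labs)) < 2:
        raise InputError("ASW undefined for a single cluster")
    return float(np.mean(silhouette_samples(d, labs, metric="precomputed")))


def cpcc(d: np.ndarray, linkage_matrix: np.ndarray) -> float:
    """Cophenetic correlation between original and dendrogram distances."""
    with np.errstate(invalid="ignore", divide="ignore"):
        c, _ = cophenet(linkage_matrix, squareform(d, checks=False))
    if not np.isfinite(c):
        raise InputError("CPCC undefined (constant distance vector)")
    return float(c)


@dataclass
class KMetrics:
    """Per-K selection statistics, the per-metric votes and the selected K."""

    table: pd.DataFrame  # index K; columns area, delta, pac, asw, cpcc
    votes: dict[str, int]
    selected_k: int


def select_k(table: pd.DataFrame, delta_elbow: float = 0.1,
             min_cluster_frac: float = 0.05) -> tuple[int, dict[str, int]]:
    """Majority vote of the four statistics; ties go to the smallest voted K.

    ASW and CPCC vote their argmax, PAC its argmin, and delta(K) votes the
    largest K whose relative CDF-area gain still exceeds ``delta_elbow``
    (the elbow rule; the smallest K if none qualifies).  Two refinements keep
    the vote meaningful on degenerate tables: a K is ineligible when its
    final labeling could not realize K distinct clusters (cutting a two-block
    consensus matrix at K=5 still yields two clusters and says nothing about
    K=5) or when its smallest cluster falls below ``min_cluster_frac`` of the
    samples (a straggler split, not a subtype); and a metric tied exactly
    across several eligible K votes for the largest of them (equally clean at
    finer resolution).  The *majority* tie still resolves to the smallest
    voted K.
    """
    eligible = table
    if "n_clusters" in table.columns:
        mask = table["n_clusters"].to_numpy() == table.index.to_numpy()
        if "min_cluster_frac" in table.columns:
            mask &= table["min_cluster_frac"].to_numpy() >= min_cluster_frac
        if mask.any():
            eligible = table[mask]
    ks = eligible.index.to_numpy()

    def _vote(col: str, minimize: bool = False) -> int:
        vals = eligible[col].to_numpy(float)
        if np.isnan(vals).all():
            return int(ks.min())
        opt = np.nanmin(vals) if minimize else np.nanmax(vals)
        return int(ks[vals == opt].max())

    votes = {
        "asw": _vote("asw"),
        "cpcc": _vote("cpcc"),
        "pac": _vote("pac", minimize=True),
    }
    qual = ks[eligible["delta"].to_numpy() >= delta_elbow]
    votes["delta"] = int(qual.max()) if qual.size else int(ks.min())
    counts = pd.Series(list(votes.values())).value_counts()
    best = counts[counts == counts.max()].index.min()
    return int(best), votes


def score_consensus_results(
    results: dict[int, ConsensusResult],
    d: np.ndarray,
    u1: float = 0.1,
    u2: float = 0.9,
    delta_elbow: float = 0.1,
    min_cluster_frac: float = 0.05,
) -> KMetrics:
    """Compute A, delta, PAC, ASW and CPCC per K and select K by vote.

    ``d`` is the sample-sample distance the clustering ran on (used for ASW);
    CPCC is computed per K on that K's final dendrogram against 1 - M.
    """
    area, delta = cdf_area_delta(results)
    rows = {}
    for k, res in sorted(results.items()):
        one_minus_m = 1.0 - res.consensus.to_numpy()
        np.fill_diagonal(one_minus_m, 0.0)
        # degenerate labelings/dendrograms (single cluster, constant
        # distances) score NaN and are ignored by the vote
        try:
            asw_k = asw(res.labels, d)
        except InputError:
            asw_k = np.nan
        try:
            cpcc_k = cpcc(one_minus_m, res.linkage_matrix)
        except InputError:
            cpcc_k = np.nan
        rows[k] = {
            "area": area[k],
            "delta": delta[k],
            "pac": pac(res, u1, u2),
            "asw": asw_k,
            "cpcc": cpcc_k,
            "n_clusters": int(res.labels.nunique()),
            "min_cluster_frac": float(res.labels.value_counts().min() / len(res.labels)),
        }
    table = pd.DataFrame.from_dict(rows, orient="index").rename_axis("K")
    selected, votes = select_k(table, delta_elbow, min_cluster_frac)
    return KMetrics(table=table, votes=votes, selected_k=selected)


def coc_select_k(
    per_layer_results: dict[str, dict[int, ConsensusResult]],
    layer_k: dict[str, int] | None = None,
    k_range: range | list[int] = range(2, 7),
    reps: int = 50,
    p_item: float = 0.8,
    seed: int = 0,
    u1: float = 0.1,
    u2: float = 0.9,
    delta_elbow: float = 0.1,
    min_cluster_frac: float = 0.05,
) -> tuple[KMetrics, dict[int, ConsensusResult], pd.DataFrame]:
    """Full CoC stage: encode per-layer labels, re-run CC, select the final K.

    ``layer_k`` fixes the per-layer K used for encoding; when omitted each
    layer votes for itself via PAC (argmin over that layer's consensus runs).
    Returns the K metrics, the CoC consensus results and the binary encoding.
    """
    label_sets = []
    for layer, results in per_layer_results.items():
        if layer_k is not None and layer in layer_k:
            k = layer_k[layer]
        else:
            # PAC argmin among K whose labeling realizes K clusters of
            # non-negligible size; exact ties go to the larger K (equally
            # clean, finer resolution)
            cands = [kk for kk, r in results.items()
                     if r.labels.nunique() == kk
                     and r.labels.value_counts().min() / len(r.labels) >= min_cluster_frac]
            if not cands:
                cands = list(results)
            pacs = {kk: pac(results[kk], u1, u2) for kk in cands}
            best = min(pacs.values())
            k = max(kk for kk, v in pacs.items() if v == best)
        label_sets.append(results[k].labels)
    encoding = encode_coc(label_sets)
    # CC treats columns as samples: transpose the samples x sum(K) encoding
    binary = encoding.T.astype(float)
    d = pearson_distance(binary)
    coc_results = build_consensus(binary, k_range=k_range, reps=reps,
                                  p_item=p_item, seed=seed)
    metrics = score_consensus_results(coc_results, d, u1=u1, u2=u2,
                                      delta_elbow=delta_elbow,
                                      min_cluster_frac=min_cluster_frac)
    return metrics, coc_results, encoding
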