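"""Gene filtering and selection ahead of consensus clustering.

Two steps, applied per omics layer: drop the lowest-mean genes (default the
bottom 25% by arithmetic mean on the linear scale), then keep the genes with
the largest median absolute deviation (MAD) computed on log2(x+1) values —
3000 for mRNA and lncRNA, 300 for miRNA in the reference workflow.  The MAD
scale constant is omitted: it cannot change a top-N ranking.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, InputError


def filter_low_mean(m: ExpressionMatrix, fraction: float = 0.25) -> ExpressionMatrix:
    """Remove the ``floor(fraction * n_genes)`` genes with smallest mean.

    Means are arithmetic means across samples on the linear scale.  Ties are
    broken by input order (earlier genes kept).  ``fraction=0`` is the
    identity.
    """
    if not (0.0 <= fraction < 1.0):
        raise InputError("fraction must be in [0, 1)")
    if m.n_genes == 0 or m.n_samples == 0:
        raise InputError("empty expression matrix")
    n_drop = int(np.floor(fraction * m.n_genes))
    if n_drop == 0:
        return m
    means = m.values.mean(axis=1).to_numpy()
    # ties keep earlier genes: among equal means the later gene is dropped
    # first, so sort ascending on (mean, -index)
    order = np.lexsort((-np.arange(m.n_genes), means))
    drop = set(order[:n_drop])
    keep = [g for i, g in enumerate(m.genes) if i not in drop]
    return m.subset_genes(keep)


def mad_log2(m: ExpressionMatrix) -> pd.Series:
    """Per-gene median absolute deviation of log2(x+1) values (no scale constant)."""
    lg = m.log2p1().to_numpy()
    med = np.median(lg, axis=1, keepdims=True)
    return pd.Series(np.median(np.abs(lg - med), axis=1), index=m.genes)


def select_top_mad(m: ExpressionMatrix, n: int) -> ExpressionMatrix:
    """Keep the ``n`` genes with largest MAD; identity if ``n >= n_genes``.

    Ties are broken by input order (earlier genes win).
    """
    if n < 1:
        raise InputError("n must be >= 1")
    if n >= m.n_genes:
        return m
    mad = mad_log2(m).to_numpy()
    order = np.lexsort((np.arange(m.n_genes), -mad))  # descending MAD, stable
    keep_idx = sorted(order[:n])
    return m.subset_genes([m.genes[i] for i in keep_idx])


def cluster_input(m: ExpressionMatrix) -> pd.DataFrame:
    """Median-centered log2(x+1) matrix used as clustering input.

    Per-gene median centering prevents absolute expression level from
    dominating the Pearson distance between samples.
    """
    lg = m.log2p1()
    return lg.sub(lg.median(axis=1), axis=0)
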