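"""miRNA-mediated lncRNA-mRNA co-expression triplet inference.

Pairs of genes from different layers are called co-expressed when their
Pearson correlation over tumor samples satisfies |r| >= 0.4 and p < 0.05
(two-sided t test on r).  A triplet (miRNA, lncRNA, mRNA) is emitted when a
co-expressed lncRNA-mRNA pair is simultaneously co-expressed with the same
miRNA.  Triplets are then validated against a target-database evidence table:
the miRNA-mRNA edge must appear in at least 4 of the 6 database columns and
the miRNA-lncRNA edge in at least 1 of the 3 designated lncRNA columns.
No sign constraint is applied to the correlations.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, InputError
from .simulate import DB_COLUMNS, LNC_DB_COLUMNS

logger = logging.getLogger(__name__)


def pairwise_correlation(layer_a: ExpressionMatrix, layer_b: ExpressionMatrix,
                         samples: list[str] | pd.Index | None = None) -> pd.DataFrame:
    """Pearson r and two-sided p for every cross-layer gene pair.

    Computed on log2(x+1) over the shared (by default: all common) samples;
    p from t = r * sqrt(n-2) / sqrt(1-r^2) with n-2 df, p = 0 at |r| = 1.
    Zero-variance genes are skipped with a log entry.
    """
    if samples is None:
        samples = [s for s in layer_a.samples if s in set(layer_b.samples)]
    samples = list(samples)
    n = len(samples)
    if n < 4:
        raise InputError("need >= 4 shared samples for correlation")
    xa = layer_a.log2p1()[samples]
    xb = layer_b.log2p1()[samples]

    def _drop_const(x: pd.DataFrame, layer: str) -> pd.DataFrame:
        sd = x.to_numpy().std(axis=1)
        if (sd == 0).any():
            for g in x.index[sd == 0]:
                logger.info("gene %s (%s) has zero variance; skipped", g, layer)
            x = x.loc[sd > 0]
        return x

    xa = _drop_const(xa, layer_a.layer)
    xb = _drop_const(xb, layer_b.layer)

    a = xa.to_numpy()
    b = xb.to_numpy()
    a = (a - a.mean(axis=1, keepdims=True)) / a.std(axis=1, keepdims=True)
    b = (b - b.mean(axis=1, keepdims=True)) / b.std(axis=1, keepdims=True)
    r = np.clip(a @ b.T / n, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), n - 2))
    ii, jj = np.meshgrid(np.arange(len(xa)), np.arange(len(xb)), indexing="ij")
    return pd.DataFrame({
        "gene_a": xa.index[ii.ravel()],
        "gene_b": xb.index[jj.ravel()],
        "r": r.ravel(),
        "p": p.ravel(),
        "n": n,
    })


def filter_coexpressed(ct: pd.DataFrame, r_min: float = 0.4,
                       p_max: float = 0.05) -> pd.DataFrame:
    """Co-expressed pairs: |r| >= r_min (inclusive) and p < p_max (strict)."""
    keep = (ct["r"].abs() >= r_min) & (ct["p"] < p_max)
    return ct[keep].reset_index(drop=True)


def infer_triplets(lnc_mrna: pd.DataFrame, mir_lnc: pd.DataFrame,
                   mir_mrna: pd.DataFrame) -> pd.DataFrame:
    """Enumerate (miRNA, lncRNA, mRNA) triplets from filtered pair tables.

    Pair tables carry gene_a/gene_b as (lncRNA, mRNA), (miRNA, lncRNA) and
    (miRNA, mRNA) respectively.  A triplet requires all three underlying
    pairs; output is deduplicated with the three r/p values attached.
    """
    ml = {(row.gene_a, row.gene_b): row for row in mir_lnc.itertuples()}
    mm = {(row.gene_a, row.gene_b): row for row in mir_mrna.itertuples()}
    mirs_by_lnc: dict[str, list[str]] = {}
    for mir, lnc in ml:
        mirs_by_lnc.setdefault(lnc, []).append(mir)
    records = []
    seen = set()
    for row in lnc_mrna.itertuples():
        lnc, mrna = row.gene_a, row.gene_b
        for mir in mirs_by_lnc.get(lnc, ()):
            if (mir, mrna) not in mm or (mir, lnc, mrna) in seen:
                continue
            seen.add((mir, lnc, mrna))
            e_ml, e_mm = ml[(mir, lnc)], mm[(mir, mrna)]
            records.append({
                "mirna": mir, "lncrna": lnc, "mrna": mrna,
                "r_lnc_mrna": row.r, "p_lnc_mrna": row.p,
                "r_mir_lnc": e_ml.r, "p_mir_lnc": e_ml.p,
                "r_mir_mrna": e_mm.r, "p_mir_mrna": e_mm.p,
            })
    cols = ["mirna", "lncrna", "mrna", "r_lnc_mrna", "p_lnc_mrna",
            "r_mir_lnc", "p_mir_lnc", "r_mir_mrna", "p_mir_mrna"]
    return pd.DataFrame(records, columns=cols)


def validate_triplets(net: pd.DataFrame, evidence: pd.DataFrame,
                      mrna_min_db: int = 4, lnc_min_db: int = 1) -> pd.DataFrame:
    """Flag triplets whose miRNA edges pass the database-support rules.

    The evidence table has columns ``mirna``, ``target`` and the six database
    flags; absent rows count as zero support.  Adds ``mrna_db_support``,
    ``lnc_db_support`` and ``validated`` columns.
    """
    missing = {"mirna", "target", *DB_COLUMNS} - set(evidence.columns)
    if missing:
        raise InputError(f"evidence table lacks columns: {sorted(missing)}")
    ev = evidence.set_index(["mirna", "target"])
    total = ev[list(DB_COLUMNS)].sum(axis=1)
    lnc_total = ev[list(LNC_DB_COLUMNS)].sum(axis=1)

    def _support(series: pd.Series, mir: str, target: str) -> int:
        try:
            v = series.loc[(mir, target)]
        except KeyError:
            return 0
        return int(v.sum() if isinstance(v, pd.Series) else v)

    net = net.copy()
    net["mrna_db_support"] = [
        _support(total, r.mirna, r.mrna) for r in net.itertuples()]
    net["lnc_db_support"] = [
        _support(lnc_total, r.mirna, r.lncrna) for r in net.itertuples()]
    net["validated"] = (net["mrna_db_support"] >= mrna_min_db) & \
                       (net["lnc_db_support"] >= lnc_min_db)
    return net


def to_edge_list(net: pd.DataFrame, validated_only: bool = True) -> pd.DataFrame:
    """Long-format edge list (source, target, edge_type, r, p, sign)."""
    rows = []
    sub = net[net["validated"]] if (validated_only and "validated" in net) else net
    for t in sub.itertuples():
        for src, dst, kind, stem in (
            (t.lncrna, t.mrna, "lncRNA-mRNA", "lnc_mrna"),
            (t.mirna, t.lncrna, "miRNA-lncRNA", "mir_lnc"),
            (t.mirna, t.mrna, "miRNA-mRNA", "mir_mrna"),
        ):
            r = getattr(t, f"r_{stem}")
            p = getattr(t, f"p_{stem}")
            rows.append({"source": src, "target": dst, "edge_type": kind,
                         "r": r, "p": p, "sign": int(np.sign(r)) if r else 0})
    cols = ["source", "target", "edge_type", "r", "p", "sign"]
    return pd.DataFrame(rows, columns=cols).drop_duplicates().reset_index(drop=True)


def export_network(net: pd.DataFrame, path: str | Path,
                   validated_only: bool = True) -> pd.DataFrame:
    """Write the edge list as TSV and SIF next to it; returns the edge list.

    ``path`` is the TSV path; the SIF file replaces the suffix with ``.sif``.
    Writing then reading then writing again produces identical bytes.
    """
    edges = to_edge_list(net, validated_only=validated_only)
    path = Path(path)
    if edges.empty:
        logger.warning("empty network: writing header-only edge list to %s", path)
    edges.to_csv(path, sep="\t", index=False, float_format="%.10g")
    sif = path.with_suffix(".sif")
    with open(sif, "w") as fh:
        for e in edges.itertuples():
            fh.write(f"{e.source}\t{e.edge_type}\t{e.target}\n")
    return edges


def read_edge_list(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
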