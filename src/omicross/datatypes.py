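"""Core containers shared across the pipeline.

Expression data travel as :class:`ExpressionMatrix`, a thin validated wrapper
around a genes x samples :class:`pandas.DataFrame` tagged with the omics layer
it came from.  Gene identifiers are namespaced by layer (``mrna:GATA3``,
``mir:miR-21``, ``lnc:MALAT1``) so that downstream set operations (DEG/feature
intersections, triplet assembly) can never confuse layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

LAYERS = ("mRNA", "miRNA", "lncRNA")

LAYER_PREFIX = {"mRNA": "mrna", "miRNA": "mir", "lncRNA": "lnc"}


class InputError(ValueError):
    """Raised for malformed or degenerate inputs."""


@dataclass
class ExpressionMatrix:
    """Nonnegative genes x samples expression matrix with a layer tag.

    Values are on the linear (FPKM/RPM-like) scale.  Log transforms are
    applied by consumers, never stored here.
    """

    values: pd.DataFrame
    layer: str

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise InputError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.values.index.has_duplicates:
            raise InputError("duplicate gene IDs")
        if self.values.columns.has_duplicates:
            raise InputError("duplicate sample IDs")
        arr = self.values.to_numpy()
        if arr.size and (not np.isfinite(arr).all() or (arr < 0).any()):
            raise InputError("expression values must be finite and >= 0")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.layer)

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(samples)], self.layer)

    def log2p1(self) -> pd.DataFrame:
        """log2(x + 1) transformed values."""
        return np.log2(self.values + 1.0)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path: str | Path, layer: str) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene")
        return cls(df, layer)


@dataclass
class TruthSet:
    """Ground truth emitted by the synthetic generator, for recovery tests."""

    subtype_labels: pd.Series  # indexed by tumor sample ID, values 1..k_true
    de_genes: dict[str, str]  # gene ID -> "up" | "down" (tumor vs normal)
    triplets: list[dict]  # {mirna, lncrna, mrna, sign_lnc_mrna, sign_mir_lnc, sign_mir_mrna}
    prognostic_genes: dict[str, float] = field(default_factory=dict)  # gene -> hazard direction

    def to_json_dict(self) -> dict:
        return {
            "subtype_labels": {k: int(v) for k, v in self.subtype_labels.items()},
            "de_genes": self.de_genes,
            "triplets": self.triplets,
            "prognostic_genes": self.prognostic_genes,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "TruthSet":
        return cls(
            subtype_labels=pd.Series(d["subtype_labels"]),
            de_genes=d["de_genes"],
            triplets=d["triplets"],
            prognostic_genes=d.get("prognostic_genes", {}),
        )


def namespace_gene(layer: str, name: str) -> str:
    return f"{LAYER_PREFIX[layer]}:{name}"


def gene_layer(gene_id: str) -> str:
    """Inverse of :func:`namespace_gene` for namespaced IDs."""
    prefix = gene_id.split(":", 1)[0]
    for layer, p in LAYER_PREFIX.items():
        if p == prefix:
            return layer
    raise InputError(f"gene ID {gene_id!r} has no recognised layer prefix")
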