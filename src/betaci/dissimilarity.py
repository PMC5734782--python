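"""Pairwise community dissimilarities: Bray-Curtis and binary Jaccard.

Bray-Curtis, ``d_ij = Σ_k |x_ki − x_kj| / Σ_k (x_ki + x_kj)``, weights
abundant taxa; binary Jaccard, ``d = 1 − |A∩B| / |A∪B]`` over presence sets,
weights every detected taxon equally and so is far more sensitive to the
rare tail.  Both are bounded in [0, 1].  The metrics are computed on
whatever table the caller supplies — raw counts, rarefied counts, or
CSS-normalized values — leaving the choice of pairing to the sweep engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .normalization import NormalizedTable
from .tables import CountTable, InputError, _require_unique

__all__ = ["DistanceMatrix", "bray_curtis", "jaccard_binary", "METRICS"]

TableLike = Union[CountTable, NormalizedTable]


@dataclass(frozen=True, eq=False)
class DistanceMatrix:
    """Symmetric pairwise dissimilarities among samples (zero diagonal)."""

    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(str(s) for s in self.sample_ids)
        _require_unique(ids, "sample")
        values = np.ascontiguousarray(self.values, dtype=float)
        n = len(ids)
        if values.shape != (n, n):
            raise InputError(f"distance matrix shape {values.shape} does not match {n} samples")
        if not np.all(np.isfinite(values)):
            raise InputError("distance matrix contains non-finite values")
        if np.max(np.abs(values - values.T), initial=0.0) > 1e-12:
            raise InputError("distance matrix is not symmetric (tolerance 1e-12)")
        if np.any(np.abs(np.diagonal(values)) > 1e-12):
            raise InputError("distance matrix diagonal is not zero")
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, 0.0)
        values.setflags(write=False)
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "values", values)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i < j) distances in scipy condensed order."""
        return squareform(self.values, checks=False)

    @classmethod
    def from_condensed(cls, sample_ids, condensed: np.ndarray) -> "DistanceMatrix":
        return cls(tuple(sample_ids), squareform(np.asarray(condensed, dtype=float)))


def _matrix_of(table: TableLike) -> np.ndarray:
    if isinstance(table, CountTable):
        return table.counts.astype(float)
    if isinstance(table, NormalizedTable):
        return np.asarray(table.values, dtype=float)
    raise TypeError(f"expected CountTable or NormalizedTable, got {type(table).__name__}")


def bray_curtis_condensed(x: np.ndarray) -> np.ndarray:
    """Condensed Bray-Curtis distances between the columns of ``x``."""
    return pdist(x.T, metric="braycurtis")


def jaccard_condensed(x: np.ndarray) -> np.ndarray:
    """Condensed binary Jaccard distances between the columns of ``x``.

    Presence is strictly ``> 0``, so the result is identical for raw counts
    and any normalization that preserves the zero pattern (e.g. CSS).
    """
    return pdist((x > 0).T, metric="jaccard")


def bray_curtis(table: TableLike) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between all sample pairs of ``table``."""
    x = _matrix_of(table)
    totals = x.sum(axis=0)
    if np.any(totals == 0):
        j = int(np.argmax(totals == 0))
        raise InputError(
            f"sample {table.sample_ids[j]!r} has total 0; Bray-Curtis is undefined (0/0)"
        )
    return DistanceMatrix.from_condensed(table.sample_ids, bray_curtis_condensed(x))


def jaccard_binary(table: TableLike) -> DistanceMatrix:
    """Binary Jaccard dissimilarity between all sample pairs of ``table``."""
    x = _matrix_of(table)
    present = (x > 0).sum(axis=0)
    if np.any(present == 0):
        j = int(np.argmax(present == 0))
        raise InputError(f"sample {table.sample_ids[j]!r} has an empty presence set")
    return DistanceMatrix.from_condensed(table.sample_ids, jaccard_condensed(x))


#: metric name → condensed-distance function on a taxa × samples matrix
METRICS = {
    "bray-curtis": bray_curtis_condensed,
    "jaccard": jaccard_condensed,
}
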