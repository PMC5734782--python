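"""Cumulative-sum-scaling (CSS) normalization and rarefaction of count tables.

CSS divides each sample's counts by the cumulative sum of its counts up to a
chosen quantile of the sample's positive-count distribution, then multiplies
by a common scale constant.  Unlike rarefying, it keeps every read while
damping the influence of a few very abundant taxa on library-size
differences.  Rarefaction subsamples each sample's reads *without*
replacement to a common depth (a multivariate hypergeometric draw), dropping
samples shallower than the requested depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .tables import CountTable, InputError, _require_unique

__all__ = [
    "NormalizedTable",
    "css_scaling_factors",
    "css_normalize",
    "rarefy",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True, eq=False)
class NormalizedTable:
    """CSS-normalized counts: real-valued, zero pattern preserved.

    ``values[i, j] = counts[i, j] / scaling_factors[j] * scale_constant``.
    """

    taxon_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    scaling_factors: np.ndarray
    quantile_p: float
    scale_constant: float

    def __post_init__(self) -> None:
        taxa = tuple(str(t) for t in self.taxon_ids)
        samples = tuple(str(s) for s in self.sample_ids)
        _require_unique(taxa, "taxon")
        _require_unique(samples, "sample")
        values = np.ascontiguousarray(self.values, dtype=float)
        factors = np.ascontiguousarray(self.scaling_factors, dtype=float)
        if values.shape != (len(taxa), len(samples)):
            raise InputError("values shape does not match identifier lists")
        if factors.shape != (len(samples),) or np.any(factors <= 0):
            raise InputError("scaling factors must be strictly positive, one per sample")
        if np.any(values < 0):
            raise InputError("normalized values must be non-negative")
        if not (0 < self.quantile_p <= 1):
            raise InputError("quantile_p must lie in (0, 1]")
        if self.scale_constant <= 0:
            raise InputError("scale_constant must be positive")
        values.setflags(write=False)
        factors.setflags(write=False)
        object.__setattr__(self, "taxon_ids", taxa)
        object.__setattr__(self, "sample_ids", samples)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "scaling_factors", factors)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def _css_factors_matrix(
    counts: np.ndarray, sample_ids: Sequence[str], quantile_p: float
) -> np.ndarray:
    """Per-sample CSS scaling factors for a counts matrix (taxa × samples)."""
    if not (0 < quantile_p <= 1):
        raise InputError("quantile_p must lie in (0, 1]")
    n_samples = counts.shape[1]
    factors = np.empty(n_samples, dtype=float)
    for j in range(n_samples):
        col = counts[:, j]
        positive = col[col > 0]
        if positive.size == 0:
            raise InputError(f"sample {sample_ids[j]!r} has no positive counts")
        # linear-interpolation order-statistic quantile over sorted positives
        q = np.quantile(positive.astype(float), quantile_p)
        factors[j] = float(positive[positive <= q].sum())
    return factors


def css_scaling_factors(table: CountTable, quantile_p: float = 0.5) -> np.ndarray:
    """CSS scaling factor per sample.

    For sample *j* the factor is the sum of counts ``c_ij <= q_j`` where
    ``q_j`` is the ``quantile_p`` quantile (linear interpolation) of the
    sample's *positive* counts.  With ``quantile_p = 1`` this is the sample's
    total count.
    """
    return _css_factors_matrix(table.counts, table.sample_ids, quantile_p)


def _css_matrix(
    counts: np.ndarray,
    sample_ids: Sequence[str],
    quantile_p: float,
    scale_constant: float,
) -> tuple[np.ndarray, np.ndarray]:
    factors = _css_factors_matrix(counts, sample_ids, quantile_p)
    values = counts.astype(float) / factors[np.newaxis, :] * scale_constant
    return values, factors


def css_normalize(
    table: CountTable, quantile_p: float = 0.5, scale_constant: float = 1000.0
) -> NormalizedTable:
    """CSS-normalize a count table: ``v_ij = c_ij / s_j × scale_constant``."""
    if scale_constant <= 0:
        raise InputError("scale_constant must be positive")
    values, factors = _css_matrix(table.counts, table.sample_ids, quantile_p, scale_constant)
    return NormalizedTable(
        table.taxon_ids, table.sample_ids, values, factors, quantile_p, scale_constant
    )


def _rarefy_matrix(
    counts: np.ndarray, depth: int, rng: np.random.Generator
) -> np.ndarray:
    """Without-replacement subsample of each column of ``counts`` to ``depth``.

    Columns are processed left to right with the one generator, so the result
    is deterministic for a given generator state.  All columns must have
    total >= depth.
    """
    out = np.empty_like(counts)
    for j in range(counts.shape[1]):
        out[:, j] = rng.multivariate_hypergeometric(counts[:, j], depth)
    return out


def rarefy(table: CountTable, depth: int, seed) -> CountTable:
    """Rarefy each sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped (with a logged
    warning) rather than padded; each retained column is an independent
    multivariate hypergeometric draw, so rarefied counts never exceed the
    originals and column sums equal ``depth`` exactly.
    """
    if depth < 1:
        raise InputError(f"rarefaction depth must be >= 1, got {depth}")
    totals = table.sample_totals()
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.warning(
            "rarefy: dropping %d sample(s) shallower than depth %d: %s",
            len(dropped), depth, ", ".join(dropped[:10]) + (" ..." if len(dropped) > 10 else ""),
        )
    if not keep.any():
        raise InputError(f"all samples are shallower than the requested depth {depth}")
    rng = np.random.default_rng(seed)
    sub = _rarefy_matrix(table.counts[:, keep], depth, rng)
    kept_ids = tuple(s for s, k in zip(table.sample_ids, keep) if k)
    return CountTable(table.taxon_ids, kept_ids, sub)
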