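"""ANOSIM R, one-way PERMANOVA (pseudo-F, R²), and permutation p-values.

Both statistics are implemented from their definitions on a distance matrix:

* ANOSIM (Clarke): rank all ``M = N(N−1)/2`` pairwise dissimilarities (ties
  get average ranks) and contrast the mean rank of between-group pairs with
  the mean rank of within-group pairs, ``R = (r̄_B − r̄_W) / (M/2)``;
  R ∈ [−1, 1], with 1 meaning every between-group distance exceeds every
  within-group distance.
* PERMANOVA (Anderson): partition the total sum of squared dissimilarities,
  ``SS_T = (1/N) Σ_{i<j} d_ij²`` and ``SS_W = Σ_g (1/n_g) Σ_{i<j∈g} d_ij²``,
  into among- (``SS_A = SS_T − SS_W``) and within-group components;
  ``pseudo-F = (SS_A/(a−1)) / (SS_W/(N−a))`` and ``R² = SS_A/SS_T``.

Significance comes from uniformly resampled label permutations with the
+1-corrected p-value ``p = (1 + #{perm ≥ obs}) / (1 + n_permutations)``, so
p is never 0.  Average-rank tie handling makes ANOSIM well defined for
bootstrap-with-replacement designs, where duplicated samples create exact
ties at distance 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import rankdata

from .dissimilarity import DistanceMatrix
from .tables import GroupMap, InputError

__all__ = [
    "DegenerateInputError",
    "EffectSizeResult",
    "anosim_r",
    "permanova",
    "permutation_test",
    "anosim_from_condensed",
    "permanova_from_condensed",
    "permutation_test_condensed",
]

#: tolerance for the "greater or equal" comparison in permutation counting,
#: avoiding float-ordering artifacts across platforms
GE_TOL = 1e-12

_PERM_CHUNK = 256  # label permutations processed per vectorized block


class DegenerateInputError(ValueError):
    """All samples identical: the sums of squares cannot be partitioned."""


@dataclass(frozen=True)
class EffectSizeResult:
    """One test outcome: statistic plus permutation p-value.

    ``statistic`` is ANOSIM R (in [−1, 1]) or PERMANOVA R² (in [0, 1]);
    ``pseudo_F`` is set for PERMANOVA only.
    """

    test: str
    statistic: float
    p_value: float
    n_permutations: int
    n_samples: int
    n_groups: int
    pseudo_F: Optional[float] = None

    def __post_init__(self) -> None:
        if self.test not in ("ANOSIM", "PERMANOVA"):
            raise ValueError(f"unknown test {self.test!r}")
        if not (0 < self.p_value <= 1):
            raise ValueError("p_value must lie in (0, 1]")


# ---------------------------------------------------------------------------
# label encoding and validation
# ---------------------------------------------------------------------------

def _encode_labels(D: DistanceMatrix, groups: GroupMap) -> np.ndarray:
    missing = [s for s in D.sample_ids if s not in groups]
    if missing:
        raise InputError(
            f"samples present in the distance matrix but absent from the group map: "
            f"{missing[:5]!r}" + (" ..." if len(missing) > 5 else "")
        )
    names: list[str] = []
    labels = np.empty(D.n_samples, dtype=np.intp)
    for i, s in enumerate(D.sample_ids):
        g = groups[s]
        if g not in names:
            names.append(g)
        labels[i] = names.index(g)
    counts = np.bincount(labels)
    if len(names) < 2:
        raise InputError("at least two groups are required")
    small = [names[g] for g in range(len(names)) if counts[g] < 2]
    if small:
        raise InputError(f"groups with fewer than 2 samples: {small!r}")
    return labels


def _pair_labels(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    iu0, iu1 = np.triu_indices(labels.size, k=1)
    return labels[iu0], labels[iu1]


# ---------------------------------------------------------------------------
# core statistics on condensed distances
# ---------------------------------------------------------------------------

def anosim_from_condensed(d: np.ndarray, labels: np.ndarray) -> float:
    """ANOSIM R from condensed distances ``d`` and integer group labels."""
    d = np.asarray(d, dtype=float)
    a, b = _pair_labels(np.asarray(labels))
    ranks = rankdata(d)
    within = a == b
    m = d.size
    return float((ranks[~within].mean() - ranks[within].mean()) / (m / 2.0))


def permanova_from_condensed(
    d: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """(pseudo-F, R²) from condensed distances and integer group labels."""
    d = np.asarray(d, dtype=float)
    labels = np.asarray(labels)
    n = labels.size
    group_sizes = np.bincount(labels)
    n_groups = group_sizes.size
    if n <= n_groups:
        raise InputError(f"PERMANOVA needs more samples ({n}) than groups ({n_groups})")
    d2 = d * d
    ss_total = d2.sum() / n
    if ss_total == 0:
        raise DegenerateInputError("all samples are identical (SS_T = 0)")
    a, b = _pair_labels(labels)
    within = a == b
    per_group = np.bincount(a[within], weights=d2[within], minlength=n_groups)
    ss_within = float((per_group / group_sizes).sum())
    ss_among = max(ss_total - ss_within, 0.0)
    r2 = ss_among / ss_total
    if ss_within <= 0.0:
        return float("inf"), 1.0
    pseudo_f = (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))
    return float(pseudo_f), float(r2)


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------

def _batched_anosim(ranks: np.ndarray, perms: np.ndarray) -> np.ndarray:
    n = perms.shape[1]
    iu0, iu1 = np.triu_indices(n, k=1)
    m = ranks.size
    total = ranks.sum()
    out = np.empty(perms.shape[0])
    for start in range(0, perms.shape[0], _PERM_CHUNK):
        block = perms[start:start + _PERM_CHUNK]
        within = block[:, iu0] == block[:, iu1]
        m_within = within.sum(axis=1)
        sum_within = within @ ranks
        mean_w = sum_within / m_within
        mean_b = (total - sum_within) / (m - m_within)
        out[start:start + block.shape[0]] = (mean_b - mean_w) / (m / 2.0)
    return out


def _batched_pseudo_f(d2: np.ndarray, perms: np.ndarray) -> np.ndarray:
    n = perms.shape[1]
    iu0, iu1 = np.triu_indices(n, k=1)
    group_sizes = np.bincount(perms[0])
    n_groups = group_sizes.size
    inv_sizes = 1.0 / group_sizes
    ss_total = d2.sum() / n
    out = np.empty(perms.shape[0])
    for start in range(0, perms.shape[0], _PERM_CHUNK):
        block = perms[start:start + _PERM_CHUNK]
        a = block[:, iu0]
        within = a == block[:, iu1]
        ss_within = (np.where(within, inv_sizes[a], 0.0) @ d2)
        ss_among = np.maximum(ss_total - ss_within, 0.0)
        with np.errstate(divide="ignore"):
            f = (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))
        out[start:start + block.shape[0]] = f
    return out


def permutation_test_condensed(
    d: np.ndarray,
    labels: np.ndarray,
    test: str = "ANOSIM",
    n_permutations: int = 1000,
    seed=0,
) -> EffectSizeResult:
    """Permutation test on condensed distances with integer labels.

    Labels are permuted uniformly with replacement from the permutation
    group (distinctness is not enforced); the observed statistic is never
    included among the permuted ones — the +1 correction plays that role.
    """
    if n_permutations < 1:
        raise InputError("n_permutations must be >= 1")
    d = np.asarray(d, dtype=float)
    labels = np.asarray(labels, dtype=np.intp)
    n = labels.size
    n_groups = np.unique(labels).size
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(labels, (n_permutations, 1)), axis=1)

    if test == "ANOSIM":
        observed = anosim_from_condensed(d, labels)
        ranks = rankdata(d)
        perm_stats = _batched_anosim(ranks, perms)
        reference = observed
        pseudo_f = None
        statistic = observed
    elif test == "PERMANOVA":
        pseudo_f, statistic = permanova_from_condensed(d, labels)
        d2 = d * d
        perm_stats = _batched_pseudo_f(d2, perms)
        reference = pseudo_f
    else:
        raise ValueError(f"unknown test {test!r}")

    exceed = int(np.sum(perm_stats >= reference - GE_TOL))
    p = (1 + exceed) / (1 + n_permutations)
    return EffectSizeResult(
        test=test,
        statistic=float(statistic),
        p_value=p,
        n_permutations=n_permutations,
        n_samples=n,
        n_groups=n_groups,
        pseudo_F=pseudo_f,
    )


# ---------------------------------------------------------------------------
# public API on DistanceMatrix + GroupMap
# ---------------------------------------------------------------------------

def anosim_r(D: DistanceMatrix, groups: GroupMap) -> float:
    """ANOSIM R for the grouping of the samples of ``D``."""
    labels = _encode_labels(D, groups)
    return anosim_from_condensed(D.condensed(), labels)


def permanova(D: DistanceMatrix, groups: GroupMap) -> tuple[float, float]:
    """One-way PERMANOVA ``(pseudo_F, R²)`` for the grouping of ``D``."""
    labels = _encode_labels(D, groups)
    return permanova_from_condensed(D.condensed(), labels)


def permutation_test(
    D: DistanceMatrix,
    groups: GroupMap,
    test: str = "ANOSIM",
    n_permutations: int = 1000,
    seed=0,
) -> EffectSizeResult:
    """Observed statistic plus Monte-Carlo permutation p-value.

    The observed statistic does not depend on ``seed``; only the p-value
    varies within Monte-Carlo error.
    """
    labels = _encode_labels(D, groups)
    return permutation_test_condensed(
        D.condensed(), labels, test=test, n_permutations=n_permutations, seed=seed
    )
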