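"""Neutral drift of a census community and depth-dependent detectability.

A :class:`Community` is a census population: absolute taxon abundances
summing to a fixed population size (default five million).  One generation
of neutral drift replaces the abundances with a single multinomial draw of
``population_size`` individuals with probabilities proportional to the
current abundances — the Wright-Fisher model.  There is no selection,
immigration, or speciation: extinct taxa keep zero rows, richness can only
fall, expected relative abundances are a martingale, and heterozygosity
decays by a factor ``(1 − 1/N)`` per generation in expectation.

The detectability experiment derives two independently drifted communities
from one seed community, draws read-samples of each at a grid of sequencing
depths and per-community sample counts, and asks whether ANOSIM on raw
counts (no normalization, no rarefaction) can tell the two communities
apart.  Because drift moves rare taxa proportionally much more than
abundant ones, the two communities only become distinguishable once the
sequencing depth is deep enough to observe the rare tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .dissimilarity import METRICS
from .effect_size import permutation_test_condensed
from .tables import CountTable, InputError, _require_unique

__all__ = [
    "Community",
    "DriftConfig",
    "CommunityStats",
    "drift_generations",
    "sample_community",
    "community_stats",
    "drift_experiment",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True, eq=False)
class Community:
    """Census population: absolute abundances summing to ``population_size``."""

    taxon_ids: tuple[str, ...]
    abundances: np.ndarray
    population_size: int

    def __post_init__(self) -> None:
        taxa = tuple(str(t) for t in self.taxon_ids)
        _require_unique(taxa, "taxon")
        ab = np.ascontiguousarray(self.abundances, dtype=np.int64)
        if ab.ndim != 1 or ab.size != len(taxa):
            raise InputError("abundances must be a vector matching taxon_ids")
        if np.any(ab < 0):
            raise InputError("abundances must be non-negative")
        total = int(ab.sum())
        if total != int(self.population_size):
            raise InputError(
                f"abundances sum to {total}, not population_size={self.population_size}"
            )
        if total < 1:
            raise InputError("population_size must be positive")
        ab.setflags(write=False)
        object.__setattr__(self, "taxon_ids", taxa)
        object.__setattr__(self, "abundances", ab)
        object.__setattr__(self, "population_size", total)

    @classmethod
    def from_abundances(cls, taxon_ids, abundances) -> "Community":
        ab = np.asarray(abundances, dtype=np.int64)
        return cls(tuple(taxon_ids), ab, int(ab.sum()))

    @classmethod
    def from_count_column(cls, table: CountTable, sample_id: str) -> "Community":
        """Seed a census community from one column of a real OTU table."""
        j = table.sample_ids.index(sample_id)
        return cls.from_abundances(table.taxon_ids, table.counts[:, j])

    def relative_abundances(self) -> np.ndarray:
        return self.abundances / self.abundances.sum()


class CommunityStats(NamedTuple):
    richness: int
    heterozygosity: float


@dataclass(frozen=True)
class DriftConfig:
    """Settings for the drift detectability experiment."""

    generations: int = 20
    n_replicates_per_community: tuple[int, ...] = (5, 10, 15, 20)
    depth_grid: tuple[int, ...] = (100, 1000, 5000, 10000, 50000, 100000)
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        reps = tuple(int(n) for n in self.n_replicates_per_community)
        if not reps or any(n < 2 for n in reps):
            raise ValueError("each per-community sample count must be >= 2")
        depths = tuple(int(d) for d in self.depth_grid)
        if not depths or any(d < 1 for d in depths):
            raise ValueError("depths must be >= 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        object.__setattr__(self, "n_replicates_per_community", reps)
        object.__setattr__(self, "depth_grid", depths)


def drift_generations(community: Community, generations: int, seed) -> Community:
    """Evolve a community by ``generations`` rounds of Wright-Fisher drift.

    Each generation is one multinomial draw of ``population_size``
    individuals with probabilities proportional to the current abundances,
    so the population size is conserved exactly and the taxon list is fixed
    (extinct taxa keep zero abundance).
    """
    if generations < 0:
        raise InputError("generations must be >= 0")
    rng = np.random.default_rng(seed)
    ab = community.abundances
    size = community.population_size
    for _ in range(generations):
        ab = rng.multinomial(size, ab / ab.sum())
    return Community(community.taxon_ids, np.asarray(ab, dtype=np.int64), size)


def sample_community(
    community: Community, depth: int, n_samples: int, seed, sample_prefix: str = "sample"
) -> CountTable:
    """Draw ``n_samples`` independent read-samples of ``depth`` reads each.

    Reads are multinomial (with-replacement) draws from the community's
    relative abundances; at depths far below the population size this is
    indistinguishable from a without-replacement census subsample.
    """
    if not (1 <= depth <= community.population_size):
        raise InputError(
            f"depth must lie in [1, {community.population_size}], got {depth}"
        )
    if n_samples < 1:
        raise InputError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    p = community.relative_abundances()
    counts = rng.multinomial(depth, p, size=n_samples).T  # taxa × samples
    ids = tuple(f"{sample_prefix}_{i + 1}" for i in range(n_samples))
    return CountTable(community.taxon_ids, ids, counts)


def community_stats(community: Community) -> CommunityStats:
    """Richness (taxa with abundance > 0) and Gini–Simpson heterozygosity."""
    p = community.relative_abundances()
    richness = int(np.count_nonzero(community.abundances))
    heterozygosity = float(1.0 - np.sum(p * p))
    return CommunityStats(richness, heterozygosity)


def drift_experiment(
    seed_community: Community,
    config: DriftConfig,
    metric: str = "bray-curtis",
) -> pd.DataFrame:
    """ANOSIM detectability of two drifted communities across the depth grid.

    Two communities drift independently from ``seed_community`` (independent
    RNG streams branching at generation 1).  For each (depth, n_samples)
    cell the experiment draws that many read-samples per community, computes
    the distance matrix on raw counts — no normalization, no rarefaction —
    and runs an ANOSIM permutation test.  Returns a tidy table with columns
    ``depth, n_samples, metric, R, p``.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {sorted(METRICS)}, got {metric!r}")
    for depth in config.depth_grid:
        if depth >= seed_community.population_size:
            raise InputError(
                f"depth {depth} must be below the population size "
                f"{seed_community.population_size}"
            )
    master = np.random.SeedSequence(config.seed)
    n_cells = len(config.depth_grid) * len(config.n_replicates_per_community)
    seed_a, seed_b, *cell_seeds = master.spawn(2 + 3 * n_cells)
    comm_a = drift_generations(seed_community, config.generations, seed_a)
    comm_b = drift_generations(seed_community, config.generations, seed_b)

    metric_fn = METRICS[metric]
    rows = []
    cell = 0
    for depth in config.depth_grid:
        for n in config.n_replicates_per_community:
            s_a, s_b, s_perm = cell_seeds[3 * cell: 3 * cell + 3]
            cell += 1
            sample_a = sample_community(comm_a, depth, n, s_a, sample_prefix="A")
            sample_b = sample_community(comm_b, depth, n, s_b, sample_prefix="B")
            x = np.concatenate([sample_a.counts, sample_b.counts], axis=1).astype(float)
            labels = np.repeat([0, 1], n)
            d = metric_fn(x)
            result = permutation_test_condensed(
                d, labels, test="ANOSIM",
                n_permutations=config.n_permutations, seed=s_perm,
            )
            rows.append({
                "depth": depth, "n_samples": n, "metric": metric,
                "R": result.statistic, "p": result.p_value,
            })
            logger.info("drift cell depth=%d n=%d: R=%.3f p=%.4f",
                        depth, n, result.statistic, result.p_value)
    return pd.DataFrame(rows)
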