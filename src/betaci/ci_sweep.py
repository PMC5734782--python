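"""Bootstrap confidence-interval sweeps over effort, depth, and resolution.

The core procedure: for each cell of a (sampling effort × sequencing depth ×
taxonomic resolution) grid, draw ``n_boot`` bootstrap replicates of the study
— collapse the table to the resolution level, rarefy every sample to the
depth, optionally CSS-normalize, resample ``effort`` samples per group *with*
replacement, and compute the effect-size statistic (ANOSIM R or PERMANOVA R²)
— then summarize the replicate distribution by its mean and a percentile
confidence interval (default 95%).  The CI width traces how precision
responds to study-design choices.

Per-replicate pipeline order is collapse → rarefy → (optional CSS) →
bootstrap sample → distance → statistic.  Bootstrap duplicates are kept as
distinct sampling units; the zero distances they create are handled by
ANOSIM's average-rank ties.  Everything is deterministic under
``SweepConfig.seed``: each grid cell derives an independent seed stream from
the master seed and its own factor levels, so results do not depend on cell
iteration order.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .dissimilarity import METRICS
from .effect_size import anosim_from_condensed, permanova_from_condensed
from .normalization import _css_matrix, _rarefy_matrix
from .tables import CountTable, GroupMap, InputError, TaxonomyHierarchy, collapse_resolution

__all__ = [
    "SweepError",
    "SweepConfig",
    "ReplicateSet",
    "CIRecord",
    "percentile_ci",
    "bootstrap_replicates",
    "run_sweep",
    "ci_width_decrease",
    "records_to_frame",
]

logger = logging.getLogger(__name__)

TESTS = ("ANOSIM", "PERMANOVA")


class SweepError(ValueError):
    """A sweep cell cannot be evaluated (e.g. a group exhausted by a depth filter)."""


def _as_optional_grid(values, kind: str) -> tuple:
    """Normalize a grid that may contain None/'none' placeholders."""
    out = []
    for v in values:
        if v is None or (isinstance(v, str) and v.lower() == "none"):
            out.append(None)
        elif kind == "depth":
            iv = int(v)
            if iv < 1:
                raise ValueError(f"depths must be >= 1, got {iv}")
            out.append(iv)
        else:
            out.append(str(v))
    if not out:
        raise ValueError(f"{kind} grid must be non-empty")
    return tuple(out)


@dataclass(frozen=True)
class SweepConfig:
    """Grid and resampling settings for one sweep.

    ``depth_grid`` / ``resolution_levels`` entries of ``None`` mean "skip
    that step".  ``normalization='css'`` applies cumulative sum scaling when
    no rarefaction depth is set (the pairing used for effort-only sweeps);
    depth sweeps run on raw rarefied counts unless
    ``renormalize_after_rarefy`` is switched on.
    """

    effort_grid: tuple[int, ...]
    depth_grid: tuple = (None,)
    resolution_levels: tuple = (None,)
    metric: str = "bray-curtis"
    test: str = "ANOSIM"
    n_boot: int = 1000
    ci_level: float = 0.95
    normalization: str = "css"
    renormalize_after_rarefy: bool = False
    quantile_p: float = 0.5
    scale_constant: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        efforts = tuple(int(e) for e in self.effort_grid)
        if not efforts or any(e < 2 for e in efforts):
            raise ValueError("effort grid must be non-empty with all sizes >= 2")
        object.__setattr__(self, "effort_grid", efforts)
        object.__setattr__(self, "depth_grid", _as_optional_grid(self.depth_grid, "depth"))
        object.__setattr__(
            self, "resolution_levels", _as_optional_grid(self.resolution_levels, "resolution")
        )
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {sorted(METRICS)}, got {self.metric!r}")
        if self.test not in TESTS:
            raise ValueError(f"test must be one of {TESTS}, got {self.test!r}")
        if self.n_boot < 2:
            raise ValueError("n_boot must be >= 2")
        if not (0 < self.ci_level < 1):
            raise ValueError("ci_level must lie in (0, 1)")
        if self.normalization not in ("css", "none"):
            raise ValueError("normalization must be 'css' or 'none'")
        if int(self.seed) < 0:
            raise ValueError("seed must be a non-negative integer")
        object.__setattr__(self, "seed", int(self.seed))

    @classmethod
    def from_yaml(cls, path) -> "SweepConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise InputError(f"sweep config {path} must be a mapping")
        return cls(**raw)


@dataclass(frozen=True)
class ReplicateSet:
    """All ``n_boot`` replicate statistics for one grid cell."""

    effort: int
    depth: Optional[int]
    resolution: Optional[str]
    metric: str
    test: str
    values: np.ndarray

    @property
    def n_boot(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class CIRecord:
    """Mean and percentile CI of the replicate statistics for one cell."""

    test: str
    metric: str
    resolution: Optional[str]
    depth: Optional[int]
    effort: int
    n_boot: int
    mean: float
    lower: float
    upper: float
    width: float
    status: str = "ok"


def percentile_ci(values: Sequence[float], ci_level: float = 0.95) -> tuple[float, float, float]:
    """``(lower, mean, upper)`` percentile summary of bootstrap replicates.

    Bounds are the ``(1−ci_level)/2`` and ``1−(1−ci_level)/2`` linear-
    interpolation percentiles; the point estimate is the arithmetic mean of
    the replicates.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("percentile CI needs at least 2 values")
    if not (0 < ci_level < 1):
        raise ValueError("ci_level must lie in (0, 1)")
    alpha = (1.0 - ci_level) / 2.0
    lower, upper = np.percentile(v, [100.0 * alpha, 100.0 * (1.0 - alpha)])
    return float(lower), float(v.mean()), float(upper)


# ---------------------------------------------------------------------------
# bootstrap engine
# ---------------------------------------------------------------------------

def _cell_seed_sequence(config: SweepConfig, effort, depth, resolution) -> np.random.SeedSequence:
    key = f"{effort}|{depth}|{resolution}|{config.metric}|{config.test}"
    return np.random.SeedSequence([config.seed, zlib.crc32(key.encode())])


def _group_columns(table: CountTable, groups: GroupMap) -> dict[str, np.ndarray]:
    missing = [s for s in table.sample_ids if s not in groups]
    if missing:
        raise InputError(
            f"samples missing from the group map: {missing[:5]!r}"
            + (" ..." if len(missing) > 5 else "")
        )
    order: list[str] = []
    cols: dict[str, list[int]] = {}
    for j, s in enumerate(table.sample_ids):
        g = groups[s]
        if g not in cols:
            cols[g] = []
            order.append(g)
        cols[g].append(j)
    if len(order) < 2:
        raise InputError("at least two groups are required for a sweep")
    return {g: np.asarray(cols[g], dtype=np.intp) for g in order}


def bootstrap_replicates(
    table: CountTable,
    groups: GroupMap,
    config: SweepConfig,
    effort: int,
    depth: Optional[int] = None,
    resolution: Optional[str] = None,
    hierarchy: Optional[TaxonomyHierarchy] = None,
) -> ReplicateSet:
    """``n_boot`` bootstrap effect-size statistics for one grid cell.

    Each replicate: collapse (if ``resolution``), rarefy every deep-enough
    sample to ``depth`` with a replicate-specific stream (if ``depth``),
    optionally CSS-normalize, draw ``effort`` samples per group uniformly
    with replacement (duplicates kept as distinct units), and compute the
    configured metric + test statistic.
    """
    if effort < 2:
        raise SweepError(f"effort must be >= 2, got {effort}")
    if resolution is not None:
        if hierarchy is None:
            raise SweepError(f"resolution level {resolution!r} requested without a hierarchy")
        table = collapse_resolution(table, hierarchy, resolution)

    counts = table.counts
    group_cols = _group_columns(table, groups)
    totals = counts.sum(axis=0)

    if depth is not None:
        surviving = {g: cols[totals[cols] >= depth] for g, cols in group_cols.items()}
        for g, cols in surviving.items():
            if cols.size == 0:
                raise SweepError(
                    f"group {g!r} has no samples with >= {depth} reads (depth filter)"
                )
        # column order of the rarefied sub-matrix
        kept = np.sort(np.concatenate(list(surviving.values())))
        position = {int(j): k for k, j in enumerate(kept)}
        group_positions = {
            g: np.asarray([position[int(j)] for j in cols], dtype=np.intp)
            for g, cols in surviving.items()
        }
        deep_counts = counts[:, kept]
    else:
        group_positions = group_cols
        if config.normalization == "css":
            x_fixed, _ = _css_matrix(
                counts, table.sample_ids, config.quantile_p, config.scale_constant
            )
        else:
            x_fixed = counts.astype(float)

    metric_fn = METRICS[config.metric]
    use_anosim = config.test == "ANOSIM"
    n_groups = len(group_positions)
    group_order = list(group_positions)
    labels = np.repeat(np.arange(n_groups, dtype=np.intp), effort)

    children = _cell_seed_sequence(config, effort, depth, resolution).spawn(config.n_boot)
    values = np.empty(config.n_boot, dtype=float)
    for r in range(config.n_boot):
        rng = np.random.default_rng(children[r])
        if depth is not None:
            x = _rarefy_matrix(deep_counts, depth, rng).astype(float)
            if config.renormalize_after_rarefy and config.normalization == "css":
                x, _ = _css_matrix(x, [str(k) for k in range(x.shape[1])],
                                   config.quantile_p, config.scale_constant)
        else:
            x = x_fixed
        picks = [
            pos[rng.integers(0, pos.size, size=effort)]
            for pos in (group_positions[g] for g in group_order)
        ]
        xb = x[:, np.concatenate(picks)]
        d = metric_fn(xb)
        if use_anosim:
            values[r] = anosim_from_condensed(d, labels)
        else:
            values[r] = permanova_from_condensed(d, labels)[1]

    return ReplicateSet(
        effort=effort, depth=depth, resolution=resolution,
        metric=config.metric, test=config.test, values=values,
    )


def run_sweep(
    table: CountTable,
    groups: GroupMap,
    hierarchy: Optional[TaxonomyHierarchy],
    config: SweepConfig,
) -> list[CIRecord]:
    """One :class:`CIRecord` per (resolution × depth × effort) cell.

    Cells that cannot be evaluated (e.g. every sample of a group shallower
    than a depth) are recorded with ``status='failed: …'`` and NaN summary
    fields rather than aborting the sweep.
    """
    records: list[CIRecord] = []
    n_cells = (
        len(config.resolution_levels) * len(config.depth_grid) * len(config.effort_grid)
    )
    done = 0
    for resolution in config.resolution_levels:
        for depth in config.depth_grid:
            for effort in config.effort_grid:
                done += 1
                try:
                    reps = bootstrap_replicates(
                        table, groups, config, effort,
                        depth=depth, resolution=resolution, hierarchy=hierarchy,
                    )
                    lower, mean, upper = percentile_ci(reps.values, config.ci_level)
                    records.append(CIRecord(
                        test=config.test, metric=config.metric,
                        resolution=resolution, depth=depth, effort=effort,
                        n_boot=config.n_boot, mean=mean, lower=lower,
                        upper=upper, width=upper - lower, status="ok",
                    ))
                except (SweepError, InputError) as exc:
                    logger.warning("cell (res=%s, depth=%s, effort=%s) failed: %s",
                                   resolution, depth, effort, exc)
                    records.append(CIRecord(
                        test=config.test, metric=config.metric,
                        resolution=resolution, depth=depth, effort=effort,
                        n_boot=config.n_boot, mean=float("nan"), lower=float("nan"),
                        upper=float("nan"), width=float("nan"),
                        status=f"failed: {exc}",
                    ))
                logger.info("sweep cell %d/%d done (res=%s, depth=%s, effort=%s)",
                            done, n_cells, resolution, depth, effort)
    return records


def records_to_frame(records: Sequence[CIRecord]) -> pd.DataFrame:
    """Tidy table of sweep results (one row per grid cell)."""
    return pd.DataFrame([
        {
            "test": r.test, "metric": r.metric, "resolution": r.resolution,
            "depth": r.depth, "effort": r.effort, "n_boot": r.n_boot,
            "mean": r.mean, "lower": r.lower, "upper": r.upper,
            "width": r.width, "status": r.status,
        }
        for r in records
    ])


def ci_width_decrease(
    records: Sequence[CIRecord], from_depth: int, to_depth: int
) -> float:
    """Mean fractional CI-width decrease between two depths, as a percentage.

    Cells are matched on (test, metric, resolution, effort); a matched cell
    with zero width at ``from_depth`` is excluded with a warning.
    """
    by_key: dict[tuple, dict[int, CIRecord]] = {}
    for r in records:
        if r.status != "ok" or r.depth is None:
            continue
        by_key.setdefault((r.test, r.metric, r.resolution, r.effort), {})[r.depth] = r
    decreases: list[float] = []
    for key, cell in by_key.items():
        if from_depth not in cell or to_depth not in cell:
            continue
        w_from, w_to = cell[from_depth].width, cell[to_depth].width
        if w_from == 0:
            logger.warning("cell %s has zero CI width at depth %d; excluded", key, from_depth)
            continue
        decreases.append((w_from - w_to) / w_from)
    if not decreases:
        raise ValueError(
            f"no matched cells with both depths {from_depth} and {to_depth}"
        )
    return 100.0 * float(np.mean(decreases))
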