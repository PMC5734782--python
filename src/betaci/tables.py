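"""Count tables, group maps, and taxonomy hierarchies for amplicon community data.

The universal currency of the pipeline is the :class:`CountTable`: a matrix of
non-negative integer read counts with taxa (OTUs) as rows and samples as
columns — the classic OTU-table convention.  Readers accept both orientations
of the tab-separated classic format; BIOM v1 (JSON) tables are supported
behind the same contract.  Sample-to-group assignments (:class:`GroupMap`)
drive the two-group and multi-group comparisons, and a
:class:`TaxonomyHierarchy` records how taxa merge into coarser clusters at
lower similarity cutoffs (e.g. 99% → 97% → 95% → 90%), which is how the
taxonomic-resolution axis of the analysis is represented.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InputError",
    "CountTable",
    "GroupMap",
    "TaxonomyHierarchy",
    "read_count_table",
    "write_count_table",
    "read_biom_v1",
    "read_group_map",
    "write_group_map",
    "read_hierarchy",
    "write_hierarchy",
    "collapse_resolution",
]


class InputError(ValueError):
    """An input file or in-memory structure violates its contract."""


def _require_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for ident in ids:
        if ident in seen:
            raise InputError(f"duplicate {kind} identifier: {ident!r}")
        seen.add(ident)


@dataclass(frozen=True, eq=False)
class CountTable:
    """Taxa × samples matrix of non-negative integer read counts.

    Parameters
    ----------
    taxon_ids
        Row identifiers (ordered, unique).
    sample_ids
        Column identifiers (ordered, unique).
    counts
        Integer matrix of shape ``(n_taxa, n_samples)``; negative or
        non-integral entries are rejected.
    """

    taxon_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        taxa = tuple(str(t) for t in self.taxon_ids)
        samples = tuple(str(s) for s in self.sample_ids)
        _require_unique(taxa, "taxon")
        _require_unique(samples, "sample")
        if len(taxa) < 1 or len(samples) < 1:
            raise InputError("a count table needs at least one taxon and one sample")
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(taxa), len(samples)):
            raise InputError(
                f"counts shape {counts.shape} does not match "
                f"{len(taxa)} taxa × {len(samples)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            as_float = np.asarray(counts, dtype=float)
            if not np.all(np.isfinite(as_float)) or np.any(as_float % 1 != 0):
                raise InputError("counts must be integers")
            counts = as_float
        if np.any(counts < 0):
            i, j = np.argwhere(counts < 0)[0]
            raise InputError(
                f"negative count at taxon {taxa[i]!r}, sample {samples[j]!r}"
            )
        counts = np.ascontiguousarray(counts, dtype=np.int64)
        counts.setflags(write=False)
        object.__setattr__(self, "taxon_ids", taxa)
        object.__setattr__(self, "sample_ids", samples)
        object.__setattr__(self, "counts", counts)

    # -- basic views -------------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_totals(self) -> np.ndarray:
        """Per-sample read totals (column sums)."""
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.taxon_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountTable":
        return cls(tuple(map(str, frame.index)), tuple(map(str, frame.columns)),
                   frame.to_numpy())

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        """Sub-table restricted to ``sample_ids`` (order preserved)."""
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        try:
            idx = [pos[s] for s in sample_ids]
        except KeyError as exc:
            raise InputError(f"unknown sample identifier: {exc.args[0]!r}") from None
        return CountTable(self.taxon_ids, tuple(sample_ids), self.counts[:, idx])

    def equals(self, other: "CountTable") -> bool:
        return (
            isinstance(other, CountTable)
            and self.taxon_ids == other.taxon_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )

    __eq__ = equals  # type: ignore[assignment]

    def __hash__(self) -> None:  # pragma: no cover - mutable payload
        raise TypeError("CountTable is not hashable")


# ---------------------------------------------------------------------------
# classic TSV and BIOM v1 readers / writers
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path, orientation: str = "taxa_rows") -> CountTable:
    """Read a classic tab-separated OTU table.

    The first column holds row identifiers and the header row holds column
    identifiers.  ``orientation`` says whether rows are taxa (canonical) or
    samples; the returned table is always taxa-rows.
    """
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"orientation must be 'taxa_rows' or 'samples_rows', got {orientation!r}")
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise InputError(f"could not parse {path}: {exc}") from exc
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise InputError(f"{path} contains no data rows/columns")
    _require_unique(list(map(str, raw.index)), "row")
    _require_unique(list(map(str, raw.columns)), "column")

    numeric = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise InputError(
            f"non-numeric count {raw.iat[i, j]!r} at row {raw.index[i]!r}, "
            f"column {raw.columns[j]!r} in {path}"
        )
    values = numeric.to_numpy(dtype=float)
    offending = (values < 0) | (values % 1 != 0)
    if offending.any():
        i, j = np.argwhere(offending)[0]
        raise InputError(
            f"count {raw.iat[i, j]!r} at row {raw.index[i]!r}, column "
            f"{raw.columns[j]!r} in {path} is not a non-negative integer"
        )
    row_ids = tuple(map(str, raw.index))
    col_ids = tuple(map(str, raw.columns))
    if orientation == "samples_rows":
        return CountTable(col_ids, row_ids, values.T)
    return CountTable(row_ids, col_ids, values)


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Write a classic taxa-rows TSV that :func:`read_count_table` inverts exactly."""
    table.to_frame().to_csv(Path(path), sep="\t", index_label="taxon_id")


def read_biom_v1(path: str | Path) -> CountTable:
    """Read a BIOM v1 (JSON) table into a :class:`CountTable`.

    Supports both ``sparse`` and ``dense`` matrix encodings; the BIOM
    convention of rows = observations (taxa), columns = samples matches the
    canonical orientation directly.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            obj = json.load(fh)
    except json.JSONDecodeError as exc:
        raise InputError(f"could not parse {path} as BIOM v1 JSON: {exc}") from exc
    try:
        row_ids = tuple(str(r["id"]) for r in obj["rows"])
        col_ids = tuple(str(c["id"]) for c in obj["columns"])
        shape = tuple(obj["shape"])
        matrix_type = obj["matrix_type"]
        data = obj["data"]
    except (KeyError, TypeError) as exc:
        raise InputError(f"{path} is missing required BIOM v1 fields: {exc}") from exc
    if shape != (len(row_ids), len(col_ids)):
        raise InputError(f"{path}: declared shape {shape} does not match id lists")
    values = np.zeros(shape, dtype=float)
    if matrix_type == "sparse":
        for entry in data:
            i, j, v = entry
            values[int(i), int(j)] = v
    elif matrix_type == "dense":
        values[:] = np.asarray(data, dtype=float)
    else:
        raise InputError(f"{path}: unknown matrix_type {matrix_type!r}")
    try:
        return CountTable(row_ids, col_ids, values)
    except InputError as exc:
        raise InputError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# group maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class GroupMap:
    """Mapping from sample identifier to group label."""

    assignments: Mapping[str, str]

    def __post_init__(self) -> None:
        clean: dict[str, str] = {}
        for sample, group in dict(self.assignments).items():
            sample, group = str(sample), str(group)
            if not sample or not group:
                raise InputError("empty sample id or group label in group map")
            clean[sample] = group
        if not clean:
            raise InputError("group map is empty")
        object.__setattr__(self, "assignments", clean)

    def __getitem__(self, sample_id: str) -> str:
        return self.assignments[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.assignments

    def __len__(self) -> int:
        return len(self.assignments)

    def labels(self) -> tuple[str, ...]:
        """Distinct group labels in first-appearance order."""
        out: list[str] = []
        for g in self.assignments.values():
            if g not in out:
                out.append(g)
        return tuple(out)

    def samples(self, label: str) -> tuple[str, ...]:
        return tuple(s for s, g in self.assignments.items() if g == label)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GroupMap) and dict(self.assignments) == dict(other.assignments)


def read_group_map(path: str | Path) -> GroupMap:
    """Read a two-column TSV ``sample_id <TAB> group`` (optional header row)."""
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"could not parse {path}: {exc}") from exc
    if raw.shape[1] != 2:
        raise InputError(f"{path}: expected exactly two tab-separated columns")
    if raw.isna().to_numpy().any():
        raise InputError(f"{path}: missing sample id or group label")
    rows = [(str(a), str(b)) for a, b in raw.itertuples(index=False)]
    if rows and rows[0][0].lower() in ("sample_id", "sample", "#sampleid"):
        rows = rows[1:]
    assignments: dict[str, str] = {}
    for sample, group in rows:
        if sample in assignments and assignments[sample] != group:
            raise InputError(
                f"{path}: sample {sample!r} listed with conflicting groups "
                f"{assignments[sample]!r} and {group!r}"
            )
        assignments[sample] = group
    return GroupMap(assignments)


def write_group_map(groups: GroupMap, path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sample, group in groups.assignments.items():
            fh.write(f"{sample}\t{group}\n")


# ---------------------------------------------------------------------------
# taxonomy hierarchies and resolution collapsing
# ---------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class TaxonomyHierarchy:
    """Nested cluster memberships across taxonomic resolution levels.

    ``levels`` is ordered finest → coarsest (e.g. ``("99","97","95","90")``).
    ``membership[level][taxon_id]`` is the cluster label of the taxon at that
    level.  Refinement consistency — two taxa merged at a finer level stay
    merged at every coarser level — is validated at construction; violations
    are hard errors because a silently inconsistent hierarchy would corrupt
    the resolution axis of any sweep.
    """

    levels: tuple[str, ...]
    membership: Mapping[str, Mapping[str, str]]

    def __post_init__(self) -> None:
        levels = tuple(str(level) for level in self.levels)
        _require_unique(levels, "level")
        if not levels:
            raise InputError("hierarchy needs at least one level")
        membership = {str(k): dict(v) for k, v in dict(self.membership).items()}
        if set(membership) != set(levels):
            raise InputError("membership levels do not match the level list")
        taxa = set(membership[levels[0]])
        for level in levels:
            if set(membership[level]) != taxa:
                raise InputError(f"level {level!r} does not cover the same taxa as {levels[0]!r}")
        for finer, coarser in zip(levels, levels[1:]):
            parent: dict[str, str] = {}
            for taxon in membership[finer]:
                cluster = membership[finer][taxon]
                target = membership[coarser][taxon]
                if cluster in parent and parent[cluster] != target:
                    raise InputError(
                        f"refinement violation: cluster {cluster!r} at level {finer!r} "
                        f"splits into {parent[cluster]!r} and {target!r} at level {coarser!r}"
                    )
                parent[cluster] = target
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "membership", membership)

    def clusters_at(self, level: str) -> Mapping[str, str]:
        if level not in self.membership:
            raise InputError(f"unknown resolution level {level!r}")
        return self.membership[level]


def read_hierarchy(path: str | Path) -> TaxonomyHierarchy:
    """Read a hierarchy TSV: first column taxon_id, one column per level."""
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"could not parse {path}: {exc}") from exc
    if raw.shape[1] == 0:
        raise InputError(f"{path}: no level columns found")
    if raw.isna().to_numpy().any():
        raise InputError(f"{path}: missing cluster label")
    levels = tuple(map(str, raw.columns))
    membership = {
        level: {str(t): str(v) for t, v in raw[level].items()} for level in levels
    }
    return TaxonomyHierarchy(levels, membership)


def write_hierarchy(hierarchy: TaxonomyHierarchy, path: str | Path) -> None:
    taxa = sorted(hierarchy.membership[hierarchy.levels[0]])
    frame = pd.DataFrame(
        {level: [hierarchy.membership[level][t] for t in taxa] for level in hierarchy.levels},
        index=taxa,
    )
    frame.to_csv(Path(path), sep="\t", index_label="taxon_id")


def collapse_resolution(
    table: CountTable, hierarchy: TaxonomyHierarchy, level: str
) -> CountTable:
    """Sum rows that share a cluster label at ``level``.

    Per-sample totals are conserved exactly; the output taxon identifiers are
    the cluster labels, in order of first appearance down the input table.
    """
    clusters = hierarchy.clusters_at(level)
    missing = [t for t in table.taxon_ids if t not in clusters]
    if missing:
        raise InputError(
            f"taxa missing from hierarchy level {level!r}: {missing[:5]!r}"
            + (" ..." if len(missing) > 5 else "")
        )
    new_ids: list[str] = []
    index_of: dict[str, int] = {}
    row_target = np.empty(table.n_taxa, dtype=np.intp)
    for i, taxon in enumerate(table.taxon_ids):
        label = clusters[taxon]
        if label not in index_of:
            index_of[label] = len(new_ids)
            new_ids.append(label)
        row_target[i] = index_of[label]
    out = np.zeros((len(new_ids), table.n_samples), dtype=np.int64)
    np.add.at(out, row_target, table.counts)
    return CountTable(tuple(new_ids), table.sample_ids, out)
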