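"""Per-locus count matrices: I/O, library-size normalization, variability filter.

A :class:`LocusCountMatrix` holds one methylation context's read counts, one
row per restriction locus and one column per library.  Raw matrices are
integer counts straight from the count table; normalization rescales each
library to counts-per-million so libraries of different depth are comparable.
Hyper-variable loci (coefficient of variation above ``10**0.35`` by default)
are discarded before any methylation inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from mcseed.errors import ConfigurationError, DataError, FormatError, StateError

CONTEXTS = ("CG", "CHG", "CHH", "6mA")

CPM_SCALE = 1e6


@dataclass(frozen=True)
class SampleMetadata:
    """One sequencing library: its group label, replicate number and context."""

    library_id: str
    group: str
    replicate: int
    context: str

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ConfigurationError(
                f"unknown context {self.context!r} for library {self.library_id!r}; "
                f"expected one of {CONTEXTS}"
            )
        if self.replicate < 1:
            raise ConfigurationError(
                f"replicate must be a positive integer, got {self.replicate}"
            )


def validate_metadata(metadata: Sequence[SampleMetadata]) -> None:
    """Check library uniqueness and >=2 replicates per (group, context)."""
    ids = [m.library_id for m in metadata]
    if len(set(ids)) != len(ids):
        raise ConfigurationError("duplicate library_id in sample metadata")
    per_cell: dict[tuple[str, str], int] = {}
    for m in metadata:
        per_cell[(m.group, m.context)] = per_cell.get((m.group, m.context), 0) + 1
    for (group, context), n in per_cell.items():
        if n < 2:
            raise ConfigurationError(
                f"group {group!r} / context {context!r} has {n} replicate(s); "
                "statistical tests require at least 2"
            )


@dataclass
class LocusCountMatrix:
    """Counts at restriction loci: ``counts[i, s]`` for position i, library s.

    Positions are 0-based and sorted by (chrom, pos); the column order of
    ``counts`` matches ``metadata``.
    """

    chroms: np.ndarray  # dtype object/str, length n_positions
    positions: np.ndarray  # int, length n_positions
    counts: np.ndarray  # float, shape (n_positions, n_libraries)
    metadata: list[SampleMetadata]
    context: str
    normalized: bool = False

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D matrix")
        n, s = self.counts.shape
        if len(self.chroms) != n or len(self.positions) != n:
            raise FormatError("positions and counts row count mismatch")
        if len(self.metadata) != s:
            raise ConfigurationError(
                f"{s} count columns but {len(self.metadata)} metadata records"
            )
        if not np.all(np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise FormatError("counts must be finite and non-negative")

    @property
    def n_positions(self) -> int:
        return self.counts.shape[0]

    @property
    def n_libraries(self) -> int:
        return self.counts.shape[1]

    @property
    def library_ids(self) -> list[str]:
        return [m.library_id for m in self.metadata]

    def groups(self) -> list[str]:
        """Distinct group labels in metadata order of first appearance."""
        seen: list[str] = []
        for m in self.metadata:
            if m.group not in seen:
                seen.append(m.group)
        return seen

    def group_columns(self, group: str) -> np.ndarray:
        """Column indices belonging to ``group``."""
        idx = np.array([i for i, m in enumerate(self.metadata) if m.group == group])
        if idx.size == 0:
            raise ConfigurationError(f"no libraries with group {group!r}")
        return idx

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.library_ids)
        df.insert(0, "pos", self.positions)
        df.insert(0, "chrom", self.chroms)
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class CVFilterReport:
    """Per-position coefficient of variation and the retention decision."""

    chroms: np.ndarray
    positions: np.ndarray
    cv: np.ndarray  # NaN where mean == 0
    retained: np.ndarray  # bool
    threshold_cv: float

    @property
    def n_discarded(self) -> int:
        return int((~self.retained).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chroms,
                "pos": self.positions,
                "cv": self.cv,
                "retained": self.retained,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _sort_key(chroms: np.ndarray, positions: np.ndarray) -> np.ndarray:
    order = np.lexsort((positions, chroms.astype(str)))
    return order


def read_sample_sheet(path) -> list[SampleMetadata]:
    """Read a sample sheet TSV with columns library_id, group, replicate, context."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"library_id", "group", "replicate", "context"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
    metadata = [
        SampleMetadata(
            library_id=row.library_id,
            group=row.group,
            replicate=int(row.replicate),
            context=row.context,
        )
        for row in df.itertuples()
    ]
    validate_metadata(metadata)
    return metadata


def write_sample_sheet(metadata: Sequence[SampleMetadata], path) -> None:
    pd.DataFrame(
        {
            "library_id": [m.library_id for m in metadata],
            "group": [m.group for m in metadata],
            "replicate": [m.replicate for m in metadata],
            "context": [m.context for m in metadata],
        }
    ).to_csv(path, sep="\t", index=False)


def read_count_table(path, metadata: Sequence[SampleMetadata]) -> LocusCountMatrix:
    """Read a per-locus count TSV (chrom, pos, one column per library).

    Rows are sorted by coordinate on read; duplicate (chrom, pos) rows are
    rejected. Every library declared in ``metadata`` must have a column.
    """
    metadata = list(metadata)
    if not metadata:
        raise ConfigurationError("empty metadata list")
    contexts = {m.context for m in metadata}
    if len(contexts) > 1:
        raise ConfigurationError(
            f"one count table holds a single context, got {sorted(contexts)}"
        )
    df = pd.read_csv(path, sep="\t")
    if "chrom" not in df.columns or "pos" not in df.columns:
        raise FormatError("count table must have 'chrom' and 'pos' columns")
    missing = [m.library_id for m in metadata if m.library_id not in df.columns]
    if missing:
        raise ConfigurationError(f"count table missing library columns: {missing}")
    lib_cols = [m.library_id for m in metadata]
    counts = df[lib_cols].to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        raise FormatError("non-numeric count values in count table")
    if np.any(counts < 0) or not np.all(np.isfinite(counts.astype(float))):
        raise FormatError("negative or non-finite count values in count table")
    chroms = df["chrom"].to_numpy(dtype=object)
    positions = df["pos"].to_numpy(dtype=np.int64)
    if np.any(positions < 0):
        raise FormatError("negative positions in count table")
    keys = list(zip(chroms.tolist(), positions.tolist()))
    if len(set(keys)) != len(keys):
        raise FormatError("duplicate (chrom, pos) rows in count table")
    order = _sort_key(chroms, positions)
    return LocusCountMatrix(
        chroms=chroms[order],
        positions=positions[order],
        counts=counts[order].astype(float),
        metadata=metadata,
        context=metadata[0].context,
        normalized=False,
    )


def normalize_counts(m: LocusCountMatrix) -> LocusCountMatrix:
    """Scale each library to counts-per-million of its column total.

    Idempotent up to floating tolerance: a CPM column re-normalizes to itself.
    """
    col_sums = m.counts.sum(axis=0)
    zero = np.flatnonzero(col_sums == 0)
    if zero.size:
        bad = [m.library_ids[i] for i in zero]
        raise DataError(f"libraries with zero total counts: {bad}")
    normalized = m.counts / col_sums * CPM_SCALE
    return replace(m, counts=normalized, normalized=True)


def filter_by_cv(
    m: LocusCountMatrix,
    colog_threshold: float = -0.35,
    invert: bool = False,
) -> tuple[LocusCountMatrix, CVFilterReport]:
    """Discard hyper-variable loci by coefficient of variation.

    Per position, CV = sd/mean of the normalized counts across all libraries
    (sample sd, ddof=1). A position is retained iff
    ``CV <= 10 ** (-colog_threshold)`` (default threshold 10**0.35 ~= 2.2387),
    i.e. sites whose variability swamps any group signal are dropped.
    Positions with mean 0 are always discarded. ``invert=True`` flips the
    comparison for the literal reading of the printed rule (retain only
    high-CV sites); see the filter-direction note in the README.
    """
    if not m.normalized:
        raise StateError("filter_by_cv requires a normalized matrix")
    mean = m.counts.mean(axis=1)
    sd = m.counts.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    threshold_cv = 10.0 ** (-colog_threshold)
    retained = np.zeros(m.n_positions, dtype=bool)
    ok = mean > 0
    if invert:
        retained[ok] = cv[ok] > threshold_cv
    else:
        retained[ok] = cv[ok] <= threshold_cv
    report = CVFilterReport(
        chroms=m.chroms.copy(),
        positions=m.positions.copy(),
        cv=cv,
        retained=retained,
        threshold_cv=threshold_cv,
    )
    filtered = replace(
        m,
        chroms=m.chroms[retained],
        positions=m.positions[retained],
        counts=m.counts[retained],
    )
    return filtered, report


def subset_metadata(
    metadata: Iterable[SampleMetadata], groups: Sequence[str] | None = None,
    context: str | None = None,
) -> list[SampleMetadata]:
    """Select metadata records by group and/or context, preserving order."""
    out = [
        m
        for m in metadata
        if (groups is None or m.group in groups)
        and (context is None or m.context == context)
    ]
    return out
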