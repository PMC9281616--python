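"""Reading, validating and summarizing the seven-column edge-table format.

Every data set the engine consumes is a flat table of source→target
relationships.  Each row names a source node (an item being ranked: a
biomedical concept, a country, a patient, ...), a target node (the metric or
concept it is ranked against) and the numeric value of that relationship
(a relevance score, an index value, risk points).  Sources and targets each
carry an opaque unique identifier, a display name and a categorical type
("group"); distinct sources may share a display name but never an id, and
edges always point from a source to a target.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Union

import numpy as np
import pandas as pd

COLUMNS = (
    "source_id",
    "source_name",
    "source_type",
    "target_id",
    "target_name",
    "target_type",
    "edge_value",
)

_STRING_COLUMNS = COLUMNS[:6]


class EdgeTableError(ValueError):
    """Base class for edge-table ingestion failures."""


class SchemaError(EdgeTableError):
    """The CSV header does not match the required seven columns."""


class RowValueError(EdgeTableError):
    """A cell could not be parsed (e.g. a non-numeric edge_value)."""


class StructuralError(EdgeTableError):
    """Rows violate a table-level invariant (duplicates, role conflicts, ...)."""

    def __init__(self, report: "ValidationReport"):
        self.report = report
        lines = "; ".join(i.message for i in report.issues[:10])
        more = "" if len(report.issues) <= 10 else f" (+{len(report.issues) - 10} more)"
        super().__init__(f"invalid edge table: {lines}{more}")


@dataclass(frozen=True)
class EdgeRecord:
    source_id: str
    source_name: str
    source_type: str
    target_id: str
    target_name: str
    target_type: str
    edge_value: float


@dataclass(frozen=True)
class ValidationIssue:
    row: int | None
    field: str
    kind: str
    message: str


@dataclass(frozen=True)
class ValidationReport:
    issues: tuple[ValidationIssue, ...] = ()

    @property
    def is_valid(self) -> bool:
        return not self.issues

    def __str__(self) -> str:
        if self.is_valid:
            return "OK: edge table is valid"
        return "\n".join(
            f"[{i.kind}] row={i.row if i.row is not None else '-'} "
            f"field={i.field}: {i.message}"
            for i in self.issues
        )


@dataclass(frozen=True)
class GraphSummary:
    n_records: int
    n_unique_source_ids: int
    n_unique_source_names: int
    n_targets: int
    n_source_types: int
    n_target_types: int
    edge_value_min: float | None
    edge_value_max: float | None


class EdgeTable:
    """An ordered, validated collection of source→target edge records.

    Wraps a pandas DataFrame with the canonical seven columns; row order is
    file order and is preserved by every operation that subsets the table.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing columns: {', '.join(missing)}")
        frame = frame.loc[:, list(COLUMNS)].reset_index(drop=True)
        frame = frame.astype(
            {c: "string" for c in _STRING_COLUMNS} | {"edge_value": "float64"}
        )
        self._frame = frame

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[EdgeRecord | tuple]) -> "EdgeTable":
        rows = [
            tuple(r) if not isinstance(r, EdgeRecord)
            else (r.source_id, r.source_name, r.source_type,
                  r.target_id, r.target_name, r.target_type, r.edge_value)
            for r in records
        ]
        return cls(pd.DataFrame(rows, columns=list(COLUMNS)))

    # -- accessors ---------------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        """The underlying DataFrame (copy; mutating it does not affect the table)."""
        return self._frame.copy()

    def __len__(self) -> int:
        return len(self._frame)

    def __iter__(self) -> Iterator[EdgeRecord]:
        for row in self._frame.itertuples(index=False):
            yield EdgeRecord(*row)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EdgeTable):
            return NotImplemented
        return self._frame.equals(other._frame)

    def __repr__(self) -> str:
        return (
            f"EdgeTable({len(self)} records, "
            f"{len(self.source_ids)} sources, {len(self.target_ids)} targets)"
        )

    @property
    def source_ids(self) -> frozenset[str]:
        return frozenset(self._frame["source_id"])

    @property
    def target_ids(self) -> frozenset[str]:
        return frozenset(self._frame["target_id"])

    @property
    def source_names(self) -> frozenset[str]:
        return frozenset(self._frame["source_name"])

    @property
    def target_names(self) -> frozenset[str]:
        return frozenset(self._frame["target_name"])

    @property
    def types(self) -> frozenset[str]:
        return frozenset(self._frame["source_type"]) | frozenset(
            self._frame["target_type"]
        )


def _strip_frame(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    for col in _STRING_COLUMNS:
        frame[col] = frame[col].astype("string").str.strip()
    return frame


def read_edge_table(source: Union[str, Path, io.TextIOBase]) -> EdgeTable:
    """Parse a CSV stream or path into a validated :class:`EdgeTable`.

    The header must contain exactly the seven canonical columns, in any
    order.  String cells are whitespace-trimmed; ``edge_value`` is parsed as
    a decimal number.  Any structural invariant violation (duplicate
    source–target pair, conflicting attributes for an id, an id used both as
    source and target, non-finite values) raises :class:`StructuralError`.
    """
    raw = pd.read_csv(source, dtype=str, skipinitialspace=True)  # values parsed below
    raw.columns = [str(c).strip() for c in raw.columns]
    missing = sorted(set(COLUMNS) - set(raw.columns))
    extra = sorted(set(raw.columns) - set(COLUMNS))
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing columns: {', '.join(missing)}")
        if extra:
            parts.append(f"unexpected columns: {', '.join(extra)}")
        raise SchemaError("; ".join(parts))

    raw = _strip_frame(raw)

    def parse_value(cell):
        # Python's float() is correctly rounded, so written values re-read
        # bit-identically
        try:
            return float(cell)
        except (TypeError, ValueError):
            return np.nan

    values = raw["edge_value"].map(parse_value).astype("float64")
    bad = values.isna() & raw["edge_value"].notna() & (raw["edge_value"] != "")
    if bad.any():
        rows = list(raw.index[bad][:10])
        raise RowValueError(
            f"edge_value not parseable as a number at rows {rows} "
            f"(0-based, excluding header)"
        )
    frame = raw.assign(edge_value=values.astype("float64"))

    report = validate_edge_table(frame)
    if not report.is_valid:
        raise StructuralError(report)
    return EdgeTable(frame)


def write_edge_table(table: EdgeTable, dest: Union[str, Path, io.TextIOBase]) -> None:
    """Serialize in the canonical column order; inverse of :func:`read_edge_table`."""
    table.frame.to_csv(dest, index=False, lineterminator="\n")


def validate_edge_table(table: Union[EdgeTable, pd.DataFrame]) -> ValidationReport:
    """Check every table-level invariant, reporting (never raising) problems.

    Issue kinds: ``missing_value``, ``empty_field``, ``non_finite_value``,
    ``duplicate_pair``, ``conflicting_attributes``, ``role_conflict``.
    """
    frame = table.frame if isinstance(table, EdgeTable) else table
    issues: list[ValidationIssue] = []

    def add(row, field_, kind, message):
        issues.append(ValidationIssue(row, field_, kind, message))

    for col in _STRING_COLUMNS:
        cells = frame[col].astype("string")
        for row in frame.index[cells.isna() | (cells.str.strip() == "")]:
            add(int(row), col, "empty_field", f"{col} is empty at row {int(row)}")

    values = pd.to_numeric(frame["edge_value"], errors="coerce")
    for row in frame.index[frame["edge_value"].isna()]:
        add(int(row), "edge_value", "missing_value",
            f"edge_value missing at row {int(row)}")
    finite = np.isfinite(values.fillna(np.nan).to_numpy(dtype=float))
    for row in frame.index[~finite & frame["edge_value"].notna()]:
        add(int(row), "edge_value", "non_finite_value",
            f"edge_value is not finite at row {int(row)}")

    dup = frame.duplicated(subset=["source_id", "target_id"], keep=False)
    for (sid, tid), grp in frame[dup].groupby(["source_id", "target_id"], sort=True):
        rows = list(map(int, grp.index))
        add(rows[1], "source_id", "duplicate_pair",
            f"duplicate source–target pair ({sid}, {tid}) at rows {rows}")

    for role in ("source", "target"):
        attrs = frame.groupby(f"{role}_id", sort=True)[
            [f"{role}_name", f"{role}_type"]
        ].nunique()
        for ident in attrs.index[(attrs > 1).any(axis=1)]:
            rows = list(map(int, frame.index[frame[f"{role}_id"] == ident]))
            add(rows[0], f"{role}_id", "conflicting_attributes",
                f"{role}_id {ident} has conflicting name/type across rows {rows}")

    both = set(frame["source_id"].dropna()) & set(frame["target_id"].dropna())
    for ident in sorted(both):
        rows = list(map(int, frame.index[
            (frame["source_id"] == ident) | (frame["target_id"] == ident)
        ]))
        add(rows[0], "source_id", "role_conflict",
            f"id {ident} appears both as a source and as a target (rows {rows})")

    return ValidationReport(tuple(issues))


def summarize(table: EdgeTable) -> GraphSummary:
    """Headline counts and the global edge-value range of a table."""
    frame = table.frame
    if frame.empty:
        return GraphSummary(0, 0, 0, 0, 0, 0, None, None)
    return GraphSummary(
        n_records=len(frame),
        n_unique_source_ids=frame["source_id"].nunique(),
        n_unique_source_names=frame["source_name"].nunique(),
        n_targets=frame["target_id"].nunique(),
        n_source_types=frame["source_type"].nunique(),
        n_target_types=frame["target_type"].nunique(),
        edge_value_min=float(frame["edge_value"].min()),
        edge_value_max=float(frame["edge_value"].max()),
    )
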