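"""The ordered filter cascade with live composite-score recomputation.

Filters stack in a fixed order so they interact predictably:

1. selection filters (target names, source names, type labels),
2. edge-value bounds (absolute, or a percentile range resolved against the
   currently retained edges),
3. composite scores recomputed over the surviving edges; sources left with
   no edges drop out,
4. composite-score ("combined value") bounds applied to the *recomputed*
   scores,
5. the max-node cap keeping the highest-scoring sources,
6. targets with no surviving edges drop out.

Because scores are recomputed at stage 3, edge filtering changes both the
size and the meaning of a source node, and the global combined-value bounds
adapt: a recomputed score may land outside the pre-filter range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

from .edge_table import EdgeTable
from .scoring import (
    AggregatorLike,
    DEFAULT_AGGREGATOR,
    ScoreBounds,
    composite_scores,
    score_bounds,
)

Interval = tuple[float, float]


def _check_interval(name: str, interval: Optional[Interval]) -> Optional[Interval]:
    if interval is None:
        return None
    lo, hi = float(interval[0]), float(interval[1])
    if lo > hi:
        raise ValueError(f"{name}: lower bound {lo} exceeds upper bound {hi}")
    return (lo, hi)


@dataclass(frozen=True)
class FilterSpec:
    """One user filter state.  Absent fields impose no constraint.

    All intervals are closed on both ends (slider semantics: a value equal
    to a bound is retained).  ``edge_value_range`` and
    ``edge_percentile_range`` are mutually exclusive ways of bounding edge
    values.
    """

    edge_value_range: Optional[Interval] = None
    edge_percentile_range: Optional[Interval] = None
    combined_range: Optional[Interval] = None
    max_nodes: Optional[int] = None
    include_targets: Optional[frozenset[str]] = None
    include_source_names: Optional[frozenset[str]] = None
    include_types: Optional[frozenset[str]] = None

    def __post_init__(self):
        object.__setattr__(
            self, "edge_value_range",
            _check_interval("edge_value_range", self.edge_value_range))
        pr = _check_interval("edge_percentile_range", self.edge_percentile_range)
        if pr is not None and not (0.0 <= pr[0] and pr[1] <= 100.0):
            raise ValueError(f"edge_percentile_range must lie in [0, 100], got {pr}")
        object.__setattr__(self, "edge_percentile_range", pr)
        object.__setattr__(
            self, "combined_range",
            _check_interval("combined_range", self.combined_range))
        if self.edge_value_range is not None and self.edge_percentile_range is not None:
            raise ValueError(
                "edge_value_range and edge_percentile_range are mutually exclusive")
        if self.max_nodes is not None and self.max_nodes < 1:
            raise ValueError(f"max_nodes must be >= 1, got {self.max_nodes}")
        for name in ("include_targets", "include_source_names", "include_types"):
            value = getattr(self, name)
            if value is not None:
                object.__setattr__(self, name, frozenset(value))


@dataclass(frozen=True)
class FilteredView:
    """The retained subgraph snapshot derived from one FilterSpec.

    ``scores`` are computed only from retained edges; ``bounds`` is None
    exactly when the view is empty.
    """

    table: EdgeTable
    source_ids: frozenset[str]
    target_ids: frozenset[str]
    scores: dict[str, float]
    bounds: Optional[ScoreBounds]

    @property
    def is_empty(self) -> bool:
        return len(self.table) == 0

    @property
    def node_ids(self) -> frozenset[str]:
        return self.source_ids | self.target_ids


def resolve_percentile_range(
    table: EdgeTable, p_lo: float, p_hi: float
) -> Interval:
    """Map a percentile range onto an absolute edge-value interval.

    Uses the linear-interpolation quantile of all edge values, so e.g. the
    inner 50–75 percentile band of {1..8} resolves to [4.5, 6.25].
    """
    if not (0.0 <= p_lo <= p_hi <= 100.0):
        raise ValueError(f"percentiles must satisfy 0 <= lo <= hi <= 100, "
                         f"got [{p_lo}, {p_hi}]")
    if len(table) == 0:
        raise ValueError("cannot resolve percentiles against an empty table")
    values = table.frame["edge_value"].to_numpy(dtype=float)
    lo, hi = np.quantile(values, [p_lo / 100.0, p_hi / 100.0], method="linear")
    return (float(lo), float(hi))


def cap_by_composite(scores: dict[str, float], max_nodes: int) -> frozenset[str]:
    """The ``max_nodes`` sources with the highest composite scores.

    Every retained score is >= every dropped score; ties at the boundary
    break deterministically by ascending source_id.
    """
    if max_nodes < 1:
        raise ValueError(f"max_nodes must be >= 1, got {max_nodes}")
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return frozenset(sid for sid, _ in ranked[:max_nodes])


def apply_filter_cascade(
    table: EdgeTable,
    spec: FilterSpec = FilterSpec(),
    method: AggregatorLike = DEFAULT_AGGREGATOR,
) -> FilteredView:
    """Run the full ordered cascade and return the retained view.

    A contradictory spec is not an error: it simply yields the empty view.
    Note the type-selection semantics: a non-empty ``include_types`` must
    contain both an edge's source type and its target type for the edge to
    survive, so selecting only source types empties the view (sources
    without targets have no edges left).
    """
    frame = table.frame

    # stage 1: selection filters
    if spec.include_targets is not None:
        frame = frame[frame["target_name"].isin(spec.include_targets)]
    if spec.include_source_names is not None:
        frame = frame[frame["source_name"].isin(spec.include_source_names)]
    if spec.include_types is not None:
        frame = frame[
            frame["source_type"].isin(spec.include_types)
            & frame["target_type"].isin(spec.include_types)
        ]

    # stage 2: edge-value bounds (percentiles resolve against current edges)
    value_range = spec.edge_value_range
    if spec.edge_percentile_range is not None and len(frame) > 0:
        value_range = resolve_percentile_range(
            EdgeTable(frame), *spec.edge_percentile_range
        )
    if value_range is not None:
        lo, hi = value_range
        frame = frame[(frame["edge_value"] >= lo) & (frame["edge_value"] <= hi)]

    # stage 3: recompute composites on surviving edges; edge-less sources
    # are already gone because a source exists only through its rows
    retained = EdgeTable(frame)
    scores = composite_scores(retained, method)

    # stage 4: combined-value bounds against the recomputed scores
    if spec.combined_range is not None:
        lo, hi = spec.combined_range
        scores = {sid: s for sid, s in scores.items() if lo <= s <= hi}

    # stage 5: max-node cap by recomputed composite
    if spec.max_nodes is not None:
        keep = cap_by_composite(scores, spec.max_nodes)
        scores = {sid: s for sid, s in scores.items() if sid in keep}

    # stage 6: drop edges of dropped sources, then edge-less targets
    frame = frame[frame["source_id"].isin(scores)]
    retained = EdgeTable(frame)
    return FilteredView(
        table=retained,
        source_ids=retained.source_ids,
        target_ids=retained.target_ids,
        scores=scores,
        bounds=score_bounds(scores) if scores else None,
    )
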