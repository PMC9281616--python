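"""Per-source composite scores under pluggable aggregation methods.

A composite score condenses all of the edge values leaving one source node
into a single number.  The default combiner is the arithmetic mean (the
natural choice for aggregated relevance scores); the geometric mean suits
bounded [0, 1] indices combined multiplicatively (an HDI-style composite),
and the plain sum suits additive point systems (Framingham-style risk
points).  Custom combiners can be registered by name; a combiner receives
the source's edge values and, when it needs them, the source's full record
subset, so extra columns can participate in the score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .edge_table import EdgeTable

#: Signature of a composite-score combiner: values are the source's outgoing
#: edge values (1-D float array, never empty); records is that source's row
#: subset of the edge table (None when a caller has only bare values).
AggregatorFn = Callable[[np.ndarray, Optional[pd.DataFrame]], float]

AggregatorLike = Union[str, AggregatorFn]

DEFAULT_AGGREGATOR = "arithmetic_mean"


class AggregationDomainError(ValueError):
    """An aggregator was fed values outside its mathematical domain."""


def arithmetic_mean(values: np.ndarray, records: pd.DataFrame | None = None) -> float:
    return float(np.mean(values))


def geometric_mean(values: np.ndarray, records: pd.DataFrame | None = None) -> float:
    # mean-of-logs form: stable for long products of small index values
    if np.any(values <= 0):
        bad = float(values[values <= 0][0])
        raise AggregationDomainError(
            f"geometric_mean requires strictly positive values, got {bad}"
        )
    return float(np.exp(np.mean(np.log(values))))


def edge_sum(values: np.ndarray, records: pd.DataFrame | None = None) -> float:
    return float(np.sum(values))


_REGISTRY: dict[str, AggregatorFn] = {
    "arithmetic_mean": arithmetic_mean,
    "geometric_mean": geometric_mean,
    "sum": edge_sum,
}


def register_aggregator(name: str, fn: AggregatorFn, *, overwrite: bool = False) -> None:
    """Register a custom combiner selectable by ``name`` in configuration."""
    if name in _REGISTRY and not overwrite:
        raise ValueError(f"aggregator {name!r} already registered")
    _REGISTRY[name] = fn


def get_aggregator(method: AggregatorLike) -> AggregatorFn:
    if callable(method):
        return method
    try:
        return _REGISTRY[method]
    except KeyError:
        known = ", ".join(sorted(_REGISTRY))
        raise KeyError(f"unknown aggregator {method!r}; known: {known}") from None


def available_aggregators() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))


def aggregate_edge_values(
    values: Sequence[float], method: AggregatorLike = DEFAULT_AGGREGATOR
) -> float:
    """Combine one source's outgoing edge values into its composite score."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot aggregate an empty collection of edge values")
    return get_aggregator(method)(arr, None)


def composite_scores(
    table: EdgeTable, method: AggregatorLike = DEFAULT_AGGREGATOR
) -> dict[str, float]:
    """One composite score per source_id, combined over exactly its own rows.

    A source with a single outgoing edge scores exactly that edge value
    under every built-in combiner.  Sources absent from the table are absent
    from the result.
    """
    fn = get_aggregator(method)
    frame = table.frame
    scores: dict[str, float] = {}
    for source_id, sub in frame.groupby("source_id", sort=True):
        values = sub["edge_value"].to_numpy(dtype=float)
        try:
            scores[str(source_id)] = float(fn(values, sub))
        except AggregationDomainError as exc:
            raise AggregationDomainError(
                f"source {source_id!r}: {exc}"
            ) from exc
    return scores


@dataclass(frozen=True)
class ScoreBounds:
    """The adaptive global [min, max] of the current composite scores.

    Recomputed after every edge-filter application: removing a source's
    low-valued edges can push its recomputed composite above the previous
    global maximum, so the bounds track the *current* graph state rather
    than the unfiltered one.
    """

    lo: float
    hi: float

    def __post_init__(self):
        if self.lo > self.hi:
            raise ValueError(f"lo ({self.lo}) must not exceed hi ({self.hi})")

    def contains(self, value: float) -> bool:
        return self.lo <= value <= self.hi


def score_bounds(scores: Mapping[str, float]) -> ScoreBounds:
    """(min, max) over a non-empty composite-score map."""
    if not scores:
        raise ValueError("score bounds are undefined for an empty score map")
    values = list(scores.values())
    return ScoreBounds(lo=min(values), hi=max(values))
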