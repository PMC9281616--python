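"""Styled renderer elements and the cached graph state.

``build_elements`` turns a filtered, positioned view into the flat list of
node and edge dictionaries a Cytoscape.js-compatible renderer consumes.
``GraphState`` caches the full pipeline so that removal-only filter updates
prune the element list without re-simulating the layout — the single most
expensive step — while any update that re-introduces nodes (or changes the
layout parameters) triggers a fresh simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .edge_table import EdgeTable
from .filtering import FilteredView, FilterSpec, apply_filter_cascade
from .layout import LayoutParams, PositionMap, adjusted_spring_layout
from .scoring import AggregatorLike, DEFAULT_AGGREGATOR

#: Default categorical palette (colorblind-aware hues).
PALETTE = (
    "#4C72B0", "#DD8452", "#55A868", "#C44E52", "#8172B3",
    "#937860", "#DA8BC3", "#8C8C8C", "#CCB974", "#64B5CD",
    "#5F9E6E", "#B55D60", "#857AAB", "#777777", "#D1BB6F",
    "#71AEC0", "#683B79", "#2E7D32", "#AD1457", "#00695C",
)


@dataclass(frozen=True)
class StyleConfig:
    """Colors and pixel geometry of the rendered graph.

    Targets are baseline larger than every source node (``min_px < max_px <
    target_size_px``) so they remain identifiable however the composite
    scores scale the sources.  ``position_scale`` maps abstract layout
    coordinates to screen pixels, negating y for the renderer's y-down
    convention.
    """

    source_color: str = "#4C72B0"
    source_gradient_color: str = "#1B2A4A"
    target_color: str = "#C44E52"
    type_colors: Mapping[str, str] = field(default_factory=dict)
    color_seed: int = 0
    node_size_range: tuple[float, float] = (15.0, 45.0)
    target_size_px: float = 60.0
    edge_width_px: float = 2.0
    position_scale: float = 750.0

    def __post_init__(self):
        lo, hi = self.node_size_range
        if not (lo < hi < self.target_size_px):
            raise ValueError(
                "need min_px < max_px < target_size_px, got "
                f"{lo} / {hi} / {self.target_size_px}"
            )
        object.__setattr__(self, "type_colors", dict(self.type_colors))


#: The renderer element list: plain dicts in Cytoscape.js JSON shape.
ElementList = list[dict]


def node_display_sizes(
    scores: Mapping[str, float], size_range: tuple[float, float]
) -> dict[str, float]:
    """Affine (min–max) map from the current score bounds to pixel sizes.

    The lowest-scoring source gets ``min_px``, the highest ``max_px``; when
    all scores are equal every source gets the midpoint.
    """
    if not scores:
        raise ValueError("cannot size an empty score map")
    min_px, max_px = size_range
    lo, hi = min(scores.values()), max(scores.values())
    if hi == lo:
        mid = (min_px + max_px) / 2.0
        return {sid: mid for sid in scores}
    slope = (max_px - min_px) / (hi - lo)
    return {sid: min_px + (s - lo) * slope for sid, s in scores.items()}


def type_color_map(view: FilteredView, style: StyleConfig) -> dict[str, str]:
    """Deterministic color per type label; explicit overrides always win.

    Non-overridden types get palette entries in an order shuffled by
    ``color_seed`` (the "randomize colors" button re-seeds), assigned to
    the sorted type labels so equal seeds give equal maps.
    """
    labels = sorted(view.table.types)
    rng = np.random.default_rng(style.color_seed)
    palette = list(PALETTE)
    rng.shuffle(palette)
    mapping = {}
    free = 0
    for label in labels:
        if label in style.type_colors:
            mapping[label] = style.type_colors[label]
        else:
            mapping[label] = palette[free % len(palette)]
            free += 1
    return mapping


def build_elements(
    view: FilteredView, positions: PositionMap, style: StyleConfig = StyleConfig()
) -> ElementList:
    """One element per retained node and per retained edge.

    Source nodes carry their composite score and a score-proportional
    display size and are colored by type; target nodes get the fixed target
    size and color (unless their type is explicitly overridden).  Abstract
    coordinates are scaled by ``position_scale`` with y negated.
    """
    missing = sorted(view.node_ids - set(positions))
    if missing:
        raise ValueError(f"no position for node(s): {', '.join(missing)}")
    if view.is_empty:
        return []

    colors = type_color_map(view, style)
    sizes = node_display_sizes(view.scores, style.node_size_range)
    frame = view.table.frame
    scale = style.position_scale

    def screen(node_id: str) -> dict:
        x, y = positions[node_id]
        return {"x": x * scale, "y": -y * scale}

    elements: ElementList = []
    sources = frame.drop_duplicates("source_id").sort_values("source_id")
    for r in sources.itertuples(index=False):
        sid = str(r.source_id)
        elements.append({
            "data": {
                "id": sid,
                "label": str(r.source_name),
                "type": str(r.source_type),
                "role": "source",
                "score": view.scores[sid],
                "size": sizes[sid],
                "color": colors[str(r.source_type)],
            },
            "position": screen(sid),
        })
    targets = frame.drop_duplicates("target_id").sort_values("target_id")
    for r in targets.itertuples(index=False):
        tid = str(r.target_id)
        ttype = str(r.target_type)
        elements.append({
            "data": {
                "id": tid,
                "label": str(r.target_name),
                "type": ttype,
                "role": "target",
                "size": style.target_size_px,
                "color": style.type_colors.get(ttype, style.target_color),
            },
            "position": screen(tid),
        })
    for r in frame.itertuples(index=False):
        sid, tid = str(r.source_id), str(r.target_id)
        elements.append({
            "data": {
                "id": f"{sid}->{tid}",
                "source": sid,
                "target": tid,
                "edge_value": float(r.edge_value),
                "width": style.edge_width_px,
            },
        })
    return elements


@dataclass(frozen=True)
class GraphState:
    """The cached full-pipeline state of one loaded edge table.

    ``positions`` covers exactly the currently retained nodes;
    ``position_cache`` additionally keeps positions of nodes hidden by the
    current filter, so they can be pruned and restored without touching the
    simulation.
    """

    table: EdgeTable
    spec: FilterSpec
    view: FilteredView
    positions: PositionMap
    aggregator: AggregatorLike = DEFAULT_AGGREGATOR
    layout_params: LayoutParams = LayoutParams()
    style: StyleConfig = StyleConfig()
    position_cache: PositionMap = field(default_factory=dict)

    def elements(self) -> ElementList:
        return build_elements(self.view, self.positions, self.style)


def initialize_state(
    table: EdgeTable,
    spec: FilterSpec = FilterSpec(),
    *,
    aggregator: AggregatorLike = DEFAULT_AGGREGATOR,
    layout_params: LayoutParams = LayoutParams(),
    style: StyleConfig = StyleConfig(),
) -> GraphState:
    """Run cascade + layout once and cache everything."""
    view = apply_filter_cascade(table, spec, aggregator)
    positions = adjusted_spring_layout(view, layout_params)
    return GraphState(
        table=table,
        spec=spec,
        view=view,
        positions=positions,
        aggregator=aggregator,
        layout_params=layout_params,
        style=style,
        position_cache=dict(positions),
    )


def update_state(
    state: GraphState,
    new_spec: FilterSpec,
    *,
    layout_params: Optional[LayoutParams] = None,
    style: Optional[StyleConfig] = None,
    resimulate: bool = False,
) -> GraphState:
    """Apply a new filter spec, re-simulating only when structure demands it.

    Scores and bounds are always recomputed through the cascade.  If the
    new retained node set is a subset of the cached one (a removal-only
    update) the surviving nodes keep their exact cached positions and no
    simulation runs.  Any re-introduced node, changed layout parameters, or
    an explicit ``resimulate`` re-runs the anchored layout and refreshes
    the cache.
    """
    params = layout_params if layout_params is not None else state.layout_params
    new_style = style if style is not None else state.style
    if (
        new_spec == state.spec
        and params == state.layout_params
        and not resimulate
    ):
        return state if new_style == state.style else replace(state, style=new_style)

    view = apply_filter_cascade(state.table, new_spec, state.aggregator)
    removal_only = view.node_ids <= set(state.position_cache)
    if removal_only and params == state.layout_params and not resimulate:
        positions = {n: state.position_cache[n] for n in view.node_ids}
        cache = state.position_cache
    else:
        positions = adjusted_spring_layout(view, params)
        cache = dict(positions)
    return replace(
        state,
        spec=new_spec,
        view=view,
        positions=positions,
        layout_params=params,
        style=new_style,
        position_cache=cache,
    )
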