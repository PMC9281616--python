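"""Two-dimensional node placement: the three-stage anchored spring layout.

Classic force-directed layouts let target nodes get buried inside large
source clusters, which hides exactly the structure a composite-score graph
is meant to show.  The anchored ("adjusted spring") layout avoids this with
a coarse-to-fine scheme:

1. **Target skeleton.**  Only the targets are simulated, joined by
   artificial edges whose weight is *inversely* proportional to the number
   of sources the two targets share — heavily shared targets are pulled
   together weakly, leaving room between them for their eventual shared
   sources.  After a fixed number of Fruchterman–Reingold iterations the
   target positions are frozen.
2. **Gaussian infill.**  Each source is dropped near the centroid of its
   own connected targets with independent 2-D Gaussian jitter (placing all
   of them exactly on the centroid would give the repulsive force nothing
   to act on).
3. **Weighted refinement.**  The full graph is simulated with the real edge
   values as weights, for a (typically small) user-set iteration count,
   with targets held immobile throughout.

Coordinates live in an abstract plane with y increasing upward; the
renderer export (see :mod:`compositegraph.view_state`) applies the screen
scale and y-flip.  All operations are pure functions of their inputs and a
seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .filtering import FilteredView

Position = tuple[float, float]
PositionMap = dict[str, Position]
WeightedEdge = tuple[str, str, float]

BASELINE_KINDS = ("random", "circular", "kamada_kawai", "spring")


@dataclass(frozen=True)
class LayoutParams:
    """Tunables of the anchored spring layout.

    ``target_spread`` and ``source_spread`` are the optimal-distance *k*
    parameters of the skeleton and refinement simulations respectively —
    larger values spread the corresponding stage further apart.
    ``placement_sigma`` (the Gaussian infill spread) defaults to
    ``0.1 * source_spread`` so jitter scales with the layout.
    ``refine_iterations = 0`` leaves sources at their Gaussian placements.
    """

    target_spread: float = 1.0
    source_spread: float = 1.0
    target_iterations: int = 50
    refine_iterations: int = 15
    placement_sigma: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        if self.target_spread <= 0 or self.source_spread <= 0:
            raise ValueError("spread parameters must be positive")
        if self.target_iterations < 1:
            raise ValueError("target_iterations must be >= 1")
        if self.refine_iterations < 0:
            raise ValueError("refine_iterations must be >= 0")
        if self.placement_sigma is not None and self.placement_sigma <= 0:
            raise ValueError("placement_sigma must be positive")

    @property
    def sigma(self) -> float:
        return (
            self.placement_sigma
            if self.placement_sigma is not None
            else 0.1 * self.source_spread
        )


@dataclass(frozen=True)
class TargetSkeleton:
    """Targets plus the temporary artificial edges used only in stage 1."""

    target_ids: tuple[str, ...]
    artificial_edges: tuple[WeightedEdge, ...]


def build_target_skeleton(view: FilteredView) -> TargetSkeleton:
    """Connect every pair of targets that share at least one source.

    The artificial weight is 1 / n_shared: two targets sharing 80 sources
    attract each other *less* than two sharing 40, which reserves space
    between heavily shared targets for the sources placed in stage 2.
    Shared-source counting is pairwise.  A lone target yields no edges.
    """
    targets = sorted(view.target_ids)
    frame = view.table.frame
    sources_of = {
        t: set(frame.loc[frame["target_id"] == t, "source_id"]) for t in targets
    }
    edges = []
    for t_i, t_j in itertools.combinations(targets, 2):
        n_shared = len(sources_of[t_i] & sources_of[t_j])
        if n_shared > 0:
            edges.append((t_i, t_j, 1.0 / n_shared))
    return TargetSkeleton(tuple(targets), tuple(edges))


def force_directed(
    nodes: Iterable[str],
    edges: Sequence[WeightedEdge],
    *,
    k: float,
    iterations: int,
    seed: int = 0,
    fixed: Iterable[str] = (),
    initial: Optional[Mapping[str, Position]] = None,
) -> PositionMap:
    """Weighted Fruchterman–Reingold iteration with immovable anchor nodes.

    The attractive force along an edge of weight *w* is ``w * d^2 / k`` and
    the pairwise repulsion is ``k^2 / d``, so an isolated unit-weight pair
    equilibrates at separation *k*.  Displacements are capped by the usual
    linearly cooling temperature.  Nodes listed in ``fixed`` never move;
    ``iterations = 0`` returns the initial positions unchanged.  Positions
    missing from ``initial`` are drawn uniformly from the seeded RNG, so
    identical inputs and seed give identical output.
    """
    ids = sorted(set(nodes))
    if not ids:
        return {}
    if k <= 0:
        raise ValueError("k must be positive")
    index = {v: i for i, v in enumerate(ids)}
    n = len(ids)

    rng = np.random.default_rng(seed)
    pos = rng.random((n, 2))
    if initial is not None:
        for node, (x, y) in initial.items():
            if node in index:
                pos[index[node]] = (x, y)

    fixed_mask = np.zeros(n, dtype=bool)
    for node in fixed:
        if node not in index:
            raise ValueError(f"fixed node {node!r} is not among the layout nodes")
        fixed_mask[index[node]] = True

    if iterations == 0 or n == 1 or fixed_mask.all():
        return {v: (float(pos[index[v], 0]), float(pos[index[v], 1])) for v in ids}

    adj = np.zeros((n, n))
    for u, v, w in edges:
        if u in index and v in index and u != v:
            adj[index[u], index[v]] = w
            adj[index[v], index[u]] = w

    # linear cooling from a tenth of the current frame extent, as in the
    # standard FR schedule
    t = float(max(np.ptp(pos[:, 0]), np.ptp(pos[:, 1]))) * 0.1
    if t <= 0:
        t = 0.1
    dt = t / (iterations + 1)

    for _ in range(iterations):
        delta = pos[:, None, :] - pos[None, :, :]
        distance = np.linalg.norm(delta, axis=-1)
        np.clip(distance, 0.01, None, out=distance)
        force = k * k / distance**2 - adj * distance / k
        displacement = np.einsum("ijk,ij->ik", delta, force)
        length = np.linalg.norm(displacement, axis=-1)
        np.clip(length, 0.01, None, out=length)
        step = displacement * (np.minimum(length, t) / length)[:, None]
        pos[~fixed_mask] += step[~fixed_mask]
        t -= dt

    return {v: (float(pos[index[v], 0]), float(pos[index[v], 1])) for v in ids}


def place_source_nodes(
    view: FilteredView,
    target_positions: Mapping[str, Position],
    sigma: float,
    seed: int = 0,
) -> PositionMap:
    """Stage-2 Gaussian infill around each source's own target centroid.

    Each source receives an independent draw, per axis, of std. dev.
    ``sigma`` centered on the centroid of the targets it connects to.
    Deterministic given the seed (sources are visited in sorted order).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    frame = view.table.frame
    targets_of = frame.groupby("source_id", sort=True)["target_id"].agg(set)
    rng = np.random.default_rng(seed)
    placed: PositionMap = {}
    for source_id in sorted(view.source_ids):
        anchor = np.array(
            [target_positions[t] for t in sorted(targets_of[source_id])], dtype=float
        )
        centroid = anchor.mean(axis=0)
        x, y = rng.normal(loc=centroid, scale=sigma, size=2)
        placed[str(source_id)] = (float(x), float(y))
    return placed


def adjusted_spring_layout(
    view: FilteredView, params: LayoutParams = LayoutParams()
) -> PositionMap:
    """Run the full three-stage pipeline; targets never move after stage 1.

    A lone target (no second anchor to simulate against) is pinned at the
    origin.  Disconnected target components are simulated jointly in one
    run; only shared sources bind them.
    """
    if view.is_empty:
        return {}
    skeleton = build_target_skeleton(view)
    targets = list(skeleton.target_ids)

    if len(targets) == 1:
        target_positions: PositionMap = {targets[0]: (0.0, 0.0)}
    else:
        target_positions = force_directed(
            targets,
            skeleton.artificial_edges,
            k=params.target_spread,
            iterations=params.target_iterations,
            seed=params.seed,
        )

    source_positions = place_source_nodes(
        view, target_positions, sigma=params.sigma, seed=params.seed + 1
    )

    real_edges = [
        (str(r.source_id), str(r.target_id), float(r.edge_value))
        for r in view.table.frame.itertuples(index=False)
    ]
    initial = {**target_positions, **source_positions}
    refined = force_directed(
        list(initial),
        real_edges,
        k=params.source_spread,
        iterations=params.refine_iterations,
        seed=params.seed,
        fixed=targets,
        initial=initial,
    )
    # stage-1 anchors are fixed by contract; restate them exactly so the
    # guarantee is bit-level, not merely numerical
    for t in targets:
        refined[t] = target_positions[t]
    return refined


def baseline_layout(
    view: FilteredView,
    kind: str,
    seed: int = 0,
    *,
    k: Optional[float] = None,
    iterations: int = 50,
) -> PositionMap:
    """Classic layouts for comparison: random, circular, Kamada–Kawai, spring.

    ``spring`` is the plain (un-anchored) weighted Fruchterman–Reingold run
    of :func:`force_directed`; ``k`` defaults to 1/sqrt(n) as usual.
    """
    if view.is_empty:
        return {}
    graph = nx.Graph()
    graph.add_nodes_from(sorted(view.node_ids))
    for r in view.table.frame.itertuples(index=False):
        graph.add_edge(str(r.source_id), str(r.target_id),
                       weight=float(r.edge_value))

    if kind == "random":
        pos = nx.random_layout(graph, seed=seed)
    elif kind == "circular":
        pos = nx.circular_layout(graph)
    elif kind == "kamada_kawai":
        pos = nx.kamada_kawai_layout(graph)
    elif kind == "spring":
        if k is None:
            k = 1.0 / np.sqrt(graph.number_of_nodes())
        edges = [(u, v, d["weight"]) for u, v, d in graph.edges(data=True)]
        return force_directed(
            graph.nodes, edges, k=k, iterations=iterations, seed=seed
        )
    else:
        raise ValueError(
            f"unknown layout kind {kind!r}; expected one of {BASELINE_KINDS}"
        )
    return {str(v): (float(p[0]), float(p[1])) for v, p in pos.items()}
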