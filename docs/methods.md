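# Methods

## Data model

The engine consumes a flat table of directed source→target relationships
with seven columns: opaque ids, display names and categorical types for
both endpoints, plus a finite numeric `edge_value`. Identifiers are the
unit of identity: two sources may share a display name (the same concept
ranked in two separate analyses) but never an id, an id never appears on
both sides of an edge, and a (source, target) pair occurs at most once.
Duplicate pairs are rejected rather than silently overwritten because a
dropped duplicate would silently change composite scores. A node exists
only through its edge rows; an empty table is valid input and propagates
as the empty graph.

## Composite scores

For a source with outgoing edge values `v_1 … v_n` the composite is
`f(v_1 … v_n)`:

| combiner | formula | natural use |
|---|---|---|
| `arithmetic_mean` (default) | `∑v_i / n` | aggregated relevance scores |
| `geometric_mean` | `exp(mean(log v_i))`, requires `v_i > 0` | bounded (0, 1] indices |
| `sum` | `∑v_i` | additive point systems |

The geometric mean is computed as the mean of logarithms for numerical
stability; equality tests use 1e-12 relative tolerance. Custom combiners
register by name and receive, besides the value array, the source's full
row subset, so extra columns can inform a score. Targets never carry
composite scores; their display role is anchoring.

The global score bounds (`ScoreBounds`) are the min/max of the *current*
score map and are recomputed after every cascade run. This is what makes
the combined-value slider "adaptive": filtering a source's weakest edges
can raise its recomputed composite above the previous global maximum.

## Filter cascade

Stage order is fixed so the filters compose predictably:

1. selection by target name, source name, and type label — a non-empty
   type selection must contain *both* endpoint types for an edge to
   survive, so selecting only source types yields the empty view;
2. edge-value bounds; a percentile range is first resolved to absolute
   bounds via the linear-interpolation quantile of the currently retained
   edge values;
3. composite recomputation over surviving edges (edge-less sources drop);
4. combined-value bounds against the recomputed scores;
5. the max-node cap keeping the top scorers, ties broken by ascending
   source id for reproducibility;
6. targets left without edges drop.

All intervals are closed: slider semantics make boundary values inclusive,
which also makes the half-split stress case exact at the 0.5 boundary.
Selection runs before the value filters so that target removal is
reflected in the recomputed composites (removing one index target from an
HDI-style table changes every entity's geometric mean). Contradictory
specs are not errors — they produce the empty view.

Two properties deliberately hold only in restricted form. Re-applying a
spec to its own output is idempotent for absolute bounds but not for
percentile bounds, which re-resolve against the surviving edges — that
re-resolution is their purpose. And widening a constraint enlarges the
retained set only per constraint: widening the edge interval under a
max-node cap can reshuffle recomputed scores and hence the cap ranking.

## Anchored spring layout

Plain force-directed layouts bury anchor targets inside large source
clusters. The engine's layout is a coarse-to-fine scheme:

1. **Target skeleton.** Every pair of targets sharing at least one source
   is joined by an artificial edge of weight `1 / n_shared` (pairwise
   counting). The inverse weighting is intentional: heavily shared targets
   attract weakly, leaving room between them for the shared sources placed
   later. The skeleton is simulated with weighted Fruchterman–Reingold
   (FR) for `target_iterations` (default 50) at optimal distance
   `k = target_spread`, then frozen. A lone target is pinned at the
   origin. Disconnected components are simulated jointly in one run.
2. **Gaussian infill.** Each source gets an independent 2-D normal draw
   (per-axis std. dev. `placement_sigma`, default `0.1 × source_spread`
   so jitter scales with the layout) centered on the centroid of its own
   targets. Exact centroid placement would give the repulsive term nothing
   to act on.
3. **Weighted refinement.** The full graph runs FR with the real edge
   values as weights and `k = source_spread` for `refine_iterations`
   (default 15 — deliberately fewer than the skeleton stage, since this
   stage dominates runtime and starts from a good initial state), targets
   held immobile. `refine_iterations = 0` leaves sources at their
   Gaussian placements.

The FR iteration is implemented in-package on dense numpy arrays:
attraction `w·d²/k` along edges, repulsion `k²/d` between all pairs,
displacement capped by a linearly cooling temperature (initially a tenth
of the frame extent). An isolated unit-weight pair therefore equilibrates
at separation `k` — this, and the requirement that anchored runs neither
rescale nor recentre coordinates (frozen targets must stay bit-identical),
is why the engine does not call a library spring layout, which normalizes
its output extent. Distances are clipped at 0.01 to bound forces between
near-coincident nodes; node order is sorted before simulation so results
are independent of input ordering. Every layout operation is a pure
function of (view, parameters, seed). The refinement uses raw edge values
as FR weights; no transform is applied.

Memory is O(n²) in node count (dense pairwise forces), comfortable through
the few-thousand-node range the engine targets; graphs beyond that are
expected to be filtered down before simulation.

Baselines (`random`, `circular`, `kamada_kawai`) delegate to networkx;
`spring` is definitionally the package's own FR with no anchors.

## Elements, styling and caching

Renderer export is an element list in Cytoscape.js JSON shape. Source
display size is an affine min–max map from the current score bounds to
`node_size_range` (midpoint when all scores are equal); targets get a
fixed size strictly larger than any source. Colors come from a fixed
20-hue palette assigned to sorted type labels in a `color_seed`-shuffled
order, with explicit per-type overrides winning; targets default to a
dedicated color unless overridden. Abstract coordinates are multiplied by
`position_scale` (default 750) with y negated for the renderer's y-down
convention.

`GraphState` caches the table, spec, view, positions and a position cache
that also retains currently hidden nodes. An update whose retained node
set is covered by the cache is removal-only: surviving nodes keep their
exact cached coordinates and no simulation runs, which is what makes
interactive tightening cheap (simulation dominates initialization time —
the `bench` fixture measures this rather than asserting absolute times).
A node without a cached position, a layout-parameter change, or an
explicit re-simulate request re-runs the full layout and replaces the
cache. Scores and bounds are recomputed through the cascade on every
update regardless.

## Synthetic generators

The fixtures module emulates the structure of three reference workloads:
a stress series (one target, `20(i+1)` single-edge sources alternating
values 0.25/0.75, so a 0.5 edge filter halves any even-sized graph), an
HDI-shaped table (three uniform (0, 1] index edges per entity, geometric
mean composite, four development-category types assigned by composite
quartile), and a risk-point table (one small-integer edge per risk factor
per sex-typed patient, with age carrying the widest point range, summed to
a total score). The value distributions are synthetic stand-ins chosen for
plausibility; they reproduce edge multiplicity, value ranges, the natural
aggregator and node typing, **not** the marginals of any real data set —
passing tests demonstrate engine behaviour on these structures, not
statistical fidelity to published data.

## Problem sizes and tolerances

The test and acceptance workloads use stress sizes up to 10,000 sources
for the filtering path and up to a few hundred nodes for layout
simulations, 500 random tables (≤ 200 rows) for brute-force cross-checks
at 1e-12 relative tolerance, and 20 seeds for the cluster-separation
check; these sizes exercise every code path at full fidelity while keeping
a complete run in the order of seconds. Exact-equality assertions
(positions under caching, frozen targets) are bit-level, not approximate,
because the implementation guarantees them by construction.

## Limitations

- The dense FR kernel is not Barnes–Hut accelerated; very large graphs
  must be filtered before simulation.
- The interactive web layer is a thin optional adapter; all computation it
  displays is engine-side and tested headlessly.
- Percentile filters are estimator-dependent by nature; the engine fixes
  the linear-interpolation quantile.
- Extra input columns are passed through to custom combiners but carry no
  defined semantics of their own.
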