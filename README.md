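# compositegraph

An interactive composite-score network engine for source–target edge
tables.

Many ranking and relevance analyses — knowledge-graph link ranking,
composite development indices, clinical point scores — produce the same
shape of data: a set of *source* items, each related to one or more
*target* concepts by a numeric edge value. The useful summary of a source
is its **composite score**: one number combining all of its outgoing edge
values. Reading such results from tables is slow; visualizing them as a
static network hides the fact that the composite score *changes* as data
are filtered. `compositegraph` is the headless engine for that workflow:
it recomputes composite scores live as filters are applied, and lays the
graph out so that target concepts and their source clusters stay visually
separated.

The engine is aimed at analysts consuming ranked network output (e.g.
aggregated HeteSim relevance scores from biomedical knowledge-graph
studies) as well as non-network composite data such as HDI-style indices
or risk-point systems.

## The model

Input is a seven-column edge table (`source_id, source_name, source_type,
target_id, target_name, target_type, edge_value`), one row per
source→target relationship. On top of it the engine computes:

- **Composite scores.** For source *s* with outgoing edge values
  `v_1 … v_n`, the composite is `C(s) = f(v_1 … v_n)` with `f` the
  arithmetic mean by default; the geometric mean `(∏ v_i)^(1/n)` and the
  sum `∑ v_i` are built in, and custom combiners can be registered. A
  single-edge source always scores its edge value.
- **The filter cascade**, in a fixed order: name/type selection → edge
  value bounds (absolute or percentile) → *composite recomputation on the
  surviving edges* → composite bounds → a max-node cap keeping the
  top-scoring sources. Because scores are recomputed mid-cascade, the
  global composite range adapts: removing a source's weakest edges can
  push its score above the old maximum.
- **The anchored spring layout**, three stages: (1) simulate only the
  targets, joined by artificial edges weighted `1 / n_shared` (inverse to
  the number of shared sources) for 50 Fruchterman–Reingold iterations,
  then freeze them; (2) drop each source near the centroid of its own
  targets with Gaussian jitter; (3) refine the full graph with the real
  edge values as weights, targets held immobile.
- **Cached view state.** Removal-only filter updates prune the rendered
  element list and keep every surviving position bit-identical; layouts
  are re-simulated only when nodes without cached positions appear, layout
  parameters change, or a re-simulation is requested.

## Worked example

```python
import io
from compositegraph import (read_edge_table, composite_scores,
                            apply_filter_cascade, FilterSpec)

csv = """source_id,source_name,source_type,target_id,target_name,target_type,edge_value
gene_a,BRCA1,protein,d1,disease_x,disease,4
gene_a,BRCA1,protein,d2,disease_y,disease,7
gene_a,BRCA1,protein,d3,disease_z,disease,12
gene_b,TP53,protein,d1,disease_x,disease,2
gene_c,EGFR,protein,d2,disease_y,disease,8
"""
table = read_edge_table(io.StringIO(csv))
print(composite_scores(table))
# {'gene_a': 7.666666666666667, 'gene_b': 2.0, 'gene_c': 8.0}

view = apply_filter_cascade(table, FilterSpec(edge_value_range=(5.0, 12.0)))
print(view.scores)                      # {'gene_a': 9.5, 'gene_c': 8.0}
print((view.bounds.lo, view.bounds.hi))  # (8.0, 9.5)
```

`gene_a` starts at mean(4, 7, 12) ≈ 7.67 inside the global score range
[2, 8]. Filtering edges below 5 removes its weakest edge *and* all of
`gene_b`; `gene_a`'s score is recomputed to mean(7, 12) = 9.5, and the
adaptive bounds expand to (8.0, 9.5) to follow it.

The same pipeline from the shell:

```bash
compositegraph validate edges.csv
compositegraph render edges.csv -o elements.json --edge-range 5:12 --seed 1
compositegraph fixtures --kind hdi --n 189 --seed 1 --output hdi_like.csv
compositegraph bench --sizes 20,100,500,2000 --reps 3 --output bench.csv
```

`render` writes a Cytoscape.js-compatible element list (positioned, styled
nodes plus edges); identical flags and seed give byte-identical output.

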