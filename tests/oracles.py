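"""Independent brute-force re-implementations used as test oracles.

Everything here is written with explicit loops, sets and plain arithmetic —
deliberately sharing no code path with the package — so that agreement is
evidence, not tautology.
"""

from __future__ import annotations

import math

import pandas as pd

from compositegraph.edge_table import COLUMNS, EdgeTable

# record tuple layout mirrors the canonical column order
SID, SNAME, STYPE, TID, TNAME, TTYPE, VALUE = range(7)


def oracle_quantile(values, p):
    """Linear-interpolation quantile, written out by hand."""
    xs = sorted(values)
    h = (len(xs) - 1) * p / 100.0
    lo, hi = math.floor(h), math.ceil(h)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def oracle_scores(rows, method="arithmetic_mean"):
    """Per-source composite by an explicit per-source loop."""
    by_source = {}
    for r in rows:
        by_source.setdefault(r[SID], []).append(r[VALUE])
    out = {}
    for sid, vals in by_source.items():
        if method == "arithmetic_mean":
            out[sid] = sum(vals) / len(vals)
        elif method == "sum":
            out[sid] = sum(vals)
        elif method == "geometric_mean":
            out[sid] = math.prod(vals) ** (1.0 / len(vals))
        else:
            raise ValueError(method)
    return out


def oracle_cascade(rows, spec, method="arithmetic_mean"):
    """The filter cascade materialized stage by stage as set operations.

    Returns (retained rows, source ids, target ids, scores).
    """
    rows = list(rows)
    if spec.include_targets is not None:
        rows = [r for r in rows if r[TNAME] in spec.include_targets]
    if spec.include_source_names is not None:
        rows = [r for r in rows if r[SNAME] in spec.include_source_names]
    if spec.include_types is not None:
        rows = [r for r in rows
                if r[STYPE] in spec.include_types and r[TTYPE] in spec.include_types]

    value_range = spec.edge_value_range
    if spec.edge_percentile_range is not None and rows:
        vals = [r[VALUE] for r in rows]
        value_range = (
            oracle_quantile(vals, spec.edge_percentile_range[0]),
            oracle_quantile(vals, spec.edge_percentile_range[1]),
        )
    if value_range is not None:
        rows = [r for r in rows if value_range[0] <= r[VALUE] <= value_range[1]]

    scores = oracle_scores(rows, method)
    if spec.combined_range is not None:
        lo, hi = spec.combined_range
        scores = {s: v for s, v in scores.items() if lo <= v <= hi}
    if spec.max_nodes is not None:
        ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        scores = dict(ranked[: spec.max_nodes])

    rows = [r for r in rows if r[SID] in scores]
    sources = {r[SID] for r in rows}
    targets = {r[TID] for r in rows}
    return rows, sources, targets, scores


def make_random_table(rng, max_sources=40, max_targets=4):
    """A random *valid* edge table: unique pairs, consistent attributes,
    disjoint source/target id spaces, positive finite values.

    Returns (rows, EdgeTable); rows are tuples in canonical column order.
    """
    n_targets = int(rng.integers(1, max_targets + 1))
    n_sources = int(rng.integers(1, max_sources + 1))
    targets = [(f"t{j}", f"T{j}", f"tt{j % 2}") for j in range(n_targets)]
    rows = []
    for i in range(n_sources):
        sid = f"s{i}"
        sname = f"S{i // 2}"  # names may legitimately repeat across ids
        stype = f"g{i % 3}"
        n_edges = int(rng.integers(1, n_targets + 1))
        picked = rng.choice(n_targets, size=n_edges, replace=False)
        for j in sorted(int(p) for p in picked):
            tid, tname, ttype = targets[j]
            value = float(rng.uniform(0.1, 10.0))
            rows.append((sid, sname, stype, tid, tname, ttype, value))
    table = EdgeTable(pd.DataFrame(rows, columns=list(COLUMNS)))
    return rows, table


def make_random_spec(rng, rows):
    """A random FilterSpec drawing its bounds from the table's actual values."""
    from compositegraph.filtering import FilterSpec

    values = sorted(r[VALUE] for r in rows)
    kwargs = {}
    mode = rng.integers(0, 3)
    if mode == 1:
        lo, hi = sorted(rng.uniform(min(values) - 1, max(values) + 1, size=2))
        kwargs["edge_value_range"] = (float(lo), float(hi))
    elif mode == 2:
        lo, hi = sorted(rng.uniform(0, 100, size=2))
        kwargs["edge_percentile_range"] = (float(lo), float(hi))
    if rng.random() < 0.5:
        scores = sorted(oracle_scores(rows).values())
        lo, hi = sorted(rng.uniform(min(scores) - 1, max(scores) + 1, size=2))
        kwargs["combined_range"] = (float(lo), float(hi))
    if rng.random() < 0.5:
        kwargs["max_nodes"] = int(rng.integers(1, 12))
    if rng.random() < 0.3:
        names = sorted({r[TNAME] for r in rows})
        keep = max(1, int(rng.integers(1, len(names) + 1)))
        kwargs["include_targets"] = frozenset(names[:keep])
    if rng.random() < 0.3:
        names = sorted({r[SNAME] for r in rows})
        keep = max(1, int(rng.integers(1, len(names) + 1)))
        kwargs["include_source_names"] = frozenset(names[:keep])
    if rng.random() < 0.3:
        labels = sorted({r[STYPE] for r in rows} | {r[TTYPE] for r in rows})
        keep = max(1, int(rng.integers(1, len(labels) + 1)))
        kwargs["include_types"] = frozenset(labels[:keep])
    return FilterSpec(**kwargs)
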