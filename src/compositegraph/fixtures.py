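"""Synthetic edge tables emulating the engine's reference workloads.

Three generators cover the structural shapes the engine is exercised
against, without shipping any real data set:

* ``stress_table`` — one target fanned out to *n* single-edge sources with
  edge values alternating 0.25 / 0.75, so an edge filter at 0.5 removes
  exactly half of an even-sized graph.  Sizes follow the law 20 * (i + 1)
  over loop index *i*, i.e. 20 sources at i = 0 up to 10,000 at i = 499.
* ``indexed_dev_table`` — an HDI-shaped data set: each entity carries three
  bounded (0, 1] index edges (life, education, income) whose geometric
  mean is the development composite; entities are typed into four
  development-category buckets by composite quartile.
* ``risk_points_table`` — a Framingham-style point system: each sex-typed
  patient has one small-integer edge per risk factor, and the sum
  aggregator gives the total point score.

Value distributions are synthetic stand-ins: they emulate structure (edge
multiplicity, value ranges, the natural aggregator, node typing), not the
real-world marginals of any published data set.
"""

from __future__ import annotations

import time
from typing import Sequence

import numpy as np
import pandas as pd

from .edge_table import COLUMNS, EdgeTable
from .filtering import FilterSpec
from .layout import LayoutParams
from .scoring import geometric_mean
from .view_state import initialize_state, update_state

DEV_CATEGORIES = (
    "low development",
    "medium development",
    "high development",
    "very high development",
)

INDEX_TARGETS = ("life_index", "education_index", "income_index")

RISK_TARGETS = (
    "age",
    "smoking_status",
    "total_cholesterol",
    "hdl_cholesterol",
    "systolic_bp",
    "diabetes",
)

#: Inclusive integer point range per risk factor (age dominates, as in
#: sex-stratified point charts).
_RISK_POINT_RANGES = {
    "age": (0, 15),
    "smoking_status": (0, 4),
    "total_cholesterol": (0, 11),
    "hdl_cholesterol": (-2, 2),
    "systolic_bp": (0, 7),
    "diabetes": (0, 4),
}


def stress_size(loop_index: int) -> int:
    """Source count of the stress series at a given loop index: 20(i+1)."""
    if loop_index < 0:
        raise ValueError("loop_index must be >= 0")
    return 20 * (loop_index + 1)


def _width(n: int) -> int:
    return len(str(n))


def stress_table(n_sources: int) -> EdgeTable:
    """One target, ``n_sources`` single-edge sources, values 0.25/0.75 alternating."""
    if n_sources < 1:
        raise ValueError("n_sources must be >= 1")
    w = _width(n_sources)
    rows = [
        (
            f"S{i:0{w}d}", f"S{i:0{w}d}", "stress",
            "T0", "T0", "target",
            0.25 if i % 2 == 0 else 0.75,
        )
        for i in range(n_sources)
    ]
    return EdgeTable(pd.DataFrame(rows, columns=list(COLUMNS)))


def indexed_dev_table(n_entities: int, seed: int = 0) -> EdgeTable:
    """HDI-shaped table: three (0, 1] index edges per entity, quartile-typed.

    The geometric mean of each entity's three indices is its development
    composite; entities are bucketed into the four development categories
    by composite quartile (ascending).
    """
    if n_entities < 1:
        raise ValueError("n_entities must be >= 1")
    rng = np.random.default_rng(seed)
    w = _width(n_entities)
    # uniform on (0, 1]: complement of the half-open [0, 1) draw
    values = 1.0 - rng.random((n_entities, len(INDEX_TARGETS)))
    composites = np.array([geometric_mean(row) for row in values])

    if n_entities >= len(DEV_CATEGORIES):
        cuts = np.quantile(composites, [0.25, 0.5, 0.75])
    else:
        cuts = np.array([np.inf, np.inf, np.inf])
    buckets = np.searchsorted(cuts, composites, side="right")

    rows = []
    for i in range(n_entities):
        entity = f"C{i:0{w}d}"
        category = DEV_CATEGORIES[min(int(buckets[i]), 3)]
        for j, target in enumerate(INDEX_TARGETS):
            rows.append(
                (entity, entity, category, target, target, "index",
                 float(values[i, j]))
            )
    return EdgeTable(pd.DataFrame(rows, columns=list(COLUMNS)))


def risk_points_table(n_patients: int, seed: int = 0) -> EdgeTable:
    """Framingham-style points: one integer edge per risk factor per patient."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    w = _width(n_patients)
    rows = []
    for i in range(n_patients):
        patient = f"P{i:0{w}d}"
        sex = "male" if rng.random() < 0.5 else "female"
        for target in RISK_TARGETS:
            lo, hi = _RISK_POINT_RANGES[target]
            points = int(rng.integers(lo, hi + 1))
            rows.append(
                (patient, patient, sex, target, target, "risk_factor",
                 float(points))
            )
    return EdgeTable(pd.DataFrame(rows, columns=list(COLUMNS)))


def bench(
    sizes: Sequence[int],
    repetitions: int = 3,
    *,
    layout_params: LayoutParams = LayoutParams(),
) -> pd.DataFrame:
    """Time full state initialization vs. a removal-only update per size.

    For each stress size: build the table, time ``initialize_state`` (which
    includes the layout simulation), then time an update filtering edges
    below 0.5 — a removal-only change that prunes exactly half the sources
    from the cached element list without re-simulating.  Reported times are
    medians over ``repetitions`` and are machine-local; nothing asserts
    absolute values.
    """
    if not sizes:
        raise ValueError("sizes must be non-empty")
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    half_spec = FilterSpec(edge_value_range=(0.5, 1.0))
    records = []
    for n in sizes:
        table = stress_table(n)
        init_times, update_times = [], []
        for _ in range(repetitions):
            t0 = time.perf_counter()
            state = initialize_state(table, layout_params=layout_params)
            t1 = time.perf_counter()
            update_state(state, half_spec)
            t2 = time.perf_counter()
            init_times.append(t1 - t0)
            update_times.append(t2 - t1)
        records.append(
            (n, float(np.median(init_times)), float(np.median(update_times)))
        )
    return pd.DataFrame(
        records, columns=["n_sources", "init_time", "removal_update_time"]
    )
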