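import numpy as np
import pandas as pd
import pytest

from compositegraph.edge_table import COLUMNS, EdgeTable
from compositegraph.filtering import (
    FilterSpec,
    apply_filter_cascade,
    cap_by_composite,
    resolve_percentile_range,
)
from compositegraph.fixtures import indexed_dev_table, stress_table
from compositegraph.scoring import composite_scores, geometric_mean

from oracles import make_random_spec, make_random_table, oracle_cascade


def one_to_eight_table() -> EdgeTable:
    rows = [(f"s{v}", f"s{v}", "g", "T", "T", "t", float(v)) for v in range(1, 9)]
    return EdgeTable(pd.DataFrame(rows, columns=list(COLUMNS)))


class TestSpec:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"edge_value_range": (5, 1)},
            {"combined_range": (2, 0)},
            {"edge_percentile_range": (30, 110)},
            {"max_nodes": 0},
            {"edge_value_range": (0, 1), "edge_percentile_range": (0, 100)},
        ],
    )
    def test_invalid_specs_are_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FilterSpec(**kwargs)


class TestCascade:
    def test_empty_spec_is_a_no_op(self, table3):
        view = apply_filter_cascade(table3)
        assert view.table == table3
        assert view.scores == composite_scores(table3)
        assert (view.bounds.lo, view.bounds.hi) == (1.5, 3.5)

    def test_edge_filter_recomputes_scores_and_expands_bounds(self, worked_table):
        before = apply_filter_cascade(worked_table)
        assert (before.bounds.lo, before.bounds.hi) == (2.0, 8.0)
        after = apply_filter_cascade(
            worked_table, FilterSpec(edge_value_range=(5.0, float("inf")))
        )
        # the {4, 7, 12} source loses its lowest edge: mean{7, 12} = 9.5
        assert after.scores["W"] == pytest.approx(9.5)
        assert after.bounds.hi == pytest.approx(9.5)
        assert after.bounds.hi > before.bounds.hi

    @pytest.mark.parametrize("n", [2, 20, 100])
    def test_stress_half_split_at_the_inclusive_boundary(self, n):
        view = apply_filter_cascade(
            stress_table(n), FilterSpec(edge_value_range=(0.5, 1.0))
        )
        assert len(view.source_ids) == n // 2

    def test_target_removal_changes_the_geometric_composite(self):
        table = indexed_dev_table(12, seed=4)
        full = apply_filter_cascade(table, method="geometric_mean")
        trimmed = apply_filter_cascade(
            table,
            FilterSpec(include_targets=frozenset({"life_index", "income_index"})),
            method="geometric_mean",
        )
        frame = table.frame
        for sid in trimmed.source_ids:
            sub = frame[(frame["source_id"] == sid)
                        & (frame["target_name"] != "education_index")]
            expected = geometric_mean(sub["edge_value"].to_numpy())
            assert trimmed.scores[sid] == pytest.approx(expected, rel=1e-12)
            assert trimmed.scores[sid] != pytest.approx(full.scores[sid], rel=1e-9)

    def test_selecting_only_source_types_empties_the_view(self, table3):
        view = apply_filter_cascade(
            table3, FilterSpec(include_types=frozenset({"G1", "G2"}))
        )
        assert view.is_empty
        assert view.bounds is None

    def test_contradictory_spec_yields_the_empty_view_not_an_error(self, table4):
        view = apply_filter_cascade(
            table4, FilterSpec(edge_value_range=(100.0, 200.0))
        )
        assert view.is_empty and view.scores == {}

    def test_targets_without_surviving_edges_are_dropped(self, table3):
        # keeping only S1's name leaves T3 edge-less
        view = apply_filter_cascade(
            table3, FilterSpec(include_source_names=frozenset({"S1"}))
        )
        assert view.target_ids == {"T1_id", "T2_id"}

    def test_combined_range_applies_to_recomputed_scores(self, worked_table):
        # prefilter mean of W is 23/3 < 8; postfilter it is 9.5, so a
        # combined range of [8, 10] keeps W only because recomputation
        # happens first
        view = apply_filter_cascade(
            worked_table,
            FilterSpec(edge_value_range=(5.0, 20.0), combined_range=(8.5, 10.0)),
        )
        assert view.source_ids == {"W"}


class TestPercentiles:
    def test_inner_50_75_band_of_one_to_eight(self):
        table = one_to_eight_table()
        assert resolve_percentile_range(table, 50, 75) == pytest.approx((4.5, 6.25))
        view = apply_filter_cascade(
            table, FilterSpec(edge_percentile_range=(50, 75))
        )
        assert set(view.table.frame["edge_value"]) == {5.0, 6.0}

    def test_full_range_retains_everything(self, table3):
        lo, hi = resolve_percentile_range(table3, 0, 100)
        assert (lo, hi) == (1.0, 4.0)
        view = apply_filter_cascade(table3, FilterSpec(edge_percentile_range=(0, 100)))
        assert view.table == table3

    def test_identical_values_collapse_to_a_point(self):
        rows = [(f"s{i}", f"s{i}", "g", "T", "T", "t", 3.0) for i in range(5)]
        table = EdgeTable(pd.DataFrame(rows, columns=list(COLUMNS)))
        assert resolve_percentile_range(table, 10, 90) == (3.0, 3.0)

    def test_empty_table_is_a_contract_violation(self):
        empty = EdgeTable(pd.DataFrame(columns=list(COLUMNS)))
        with pytest.raises(ValueError):
            resolve_percentile_range(empty, 0, 100)


class TestMaxNodeCap:
    def test_ties_break_by_ascending_source_id(self):
        assert cap_by_composite({"a": 1.0, "b": 1.0, "c": 0.5}, 1) == {"a"}
        assert cap_by_composite({"a": 1.0, "b": 1.0, "c": 0.5}, 2) == {"a", "b"}

    def test_cap_at_or_above_population_keeps_everyone(self):
        scores = {"a": 1.0, "b": 2.0}
        assert cap_by_composite(scores, 2) == {"a", "b"}
        assert cap_by_composite(scores, 99) == {"a", "b"}

    def test_every_retained_score_dominates_every_dropped_score(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            scores = {f"s{i}": float(rng.uniform(0, 5))
                      for i in range(rng.integers(1, 30))}
            keep = cap_by_composite(scores, int(rng.integers(1, 10)))
            dropped = set(scores) - keep
            if keep and dropped:
                assert min(scores[s] for s in keep) >= max(
                    scores[s] for s in dropped
                )

    def test_top_three_after_target_removal(self):
        table = indexed_dev_table(30, seed=9)
        view = apply_filter_cascade(
            table,
            FilterSpec(
                include_targets=frozenset({"life_index", "income_index"}),
                max_nodes=3,
            ),
            method="geometric_mean",
        )
        assert len(view.source_ids) == 3
        # the three survivors are the best by the *recomputed* composite
        no_cap = apply_filter_cascade(
            table,
            FilterSpec(include_targets=frozenset({"life_index", "income_index"})),
            method="geometric_mean",
        )
        best = sorted(no_cap.scores, key=lambda s: (-no_cap.scores[s], s))[:3]
        assert view.source_ids == set(best)


class TestProperties:
    def test_cascade_matches_bruteforce_on_random_tables(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            rows, table = make_random_table(rng)
            spec = make_random_spec(rng, rows)
            view = apply_filter_cascade(table, spec)
            _, sources, targets, scores = oracle_cascade(rows, spec)
            assert view.source_ids == sources
            assert view.target_ids == targets
            assert view.scores.keys() == scores.keys()
            for sid in scores:
                assert view.scores[sid] == pytest.approx(scores[sid], rel=1e-12)

    def test_cascade_is_idempotent(self):
        # percentile bounds are excluded: they re-resolve against the current
        # edge set by design, so they are not fixed under re-application
        rng = np.random.default_rng(13)
        for _ in range(40):
            rows, table = make_random_table(rng)
            spec = make_random_spec(rng, rows)
            if spec.edge_percentile_range is not None:
                continue
            once = apply_filter_cascade(table, spec)
            twice = apply_filter_cascade(once.table, spec)
            assert twice.source_ids == once.source_ids
            assert twice.scores == pytest.approx(once.scores)

    def test_widening_one_constraint_never_shrinks_the_retained_set(self):
        # monotonicity holds per constraint (widening the edge interval can
        # reshuffle recomputed scores, so it must not be combined with a cap)
        rng = np.random.default_rng(29)
        for _ in range(30):
            rows, table = make_random_table(rng)
            values = [r[6] for r in rows]
            lo, hi = np.quantile(values, [0.4, 0.6])
            narrow = FilterSpec(edge_value_range=(float(lo), float(hi)))
            wide = FilterSpec(edge_value_range=(float(lo) - 1.0, float(hi) + 1.0))
            assert (
                apply_filter_cascade(table, narrow).source_ids
                <= apply_filter_cascade(table, wide).source_ids
            )
            base = FilterSpec(edge_value_range=(float(lo), float(hi)), max_nodes=3)
            raised = FilterSpec(edge_value_range=(float(lo), float(hi)), max_nodes=9)
            assert (
                apply_filter_cascade(table, base).source_ids
                <= apply_filter_cascade(table, raised).source_ids
            )

    def test_filtering_never_synthesizes_edges(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            rows, table = make_random_table(rng)
            spec = make_random_spec(rng, rows)
            view = apply_filter_cascade(table, spec)
            original = set(map(tuple, table.frame.itertuples(index=False)))
            retained = set(map(tuple, view.table.frame.itertuples(index=False)))
            assert retained <= original
            # every retained source has >= 1 edge; every edge has retained ends
            assert view.source_ids == set(view.table.frame["source_id"])
            assert view.target_ids == set(view.table.frame["target_id"])
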