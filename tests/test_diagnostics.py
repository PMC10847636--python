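"""Contingency tables, accuracy metrics, Fisher tests and cutoff search."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fallscreen import (
    Cohort,
    ContingencyTable2x2,
    ItemResult,
    Rule,
    SideCutoff,
    SideLevel,
    apply_rule,
    build_table,
    compute_metrics,
    fisher_exact_two_sided,
    optimize_cutoff,
)
from fallscreen.cohort import AdherenceItemResult, ManagementCategory
from helpers_oracles import fisher_two_sided_enumeration
from test_cohort import make_record


class TestBuildTable:
    def test_side_only_table_from_fixture(self, fixture_cohort):
        results = apply_rule(fixture_cohort, Rule.SIDE_ONLY)
        t = build_table(results, fixture_cohort)
        assert (t.tp, t.fn, t.fp, t.tn) == (31, 5, 210, 152)

    def test_adherence_only_table_from_fixture(self, fixture_cohort):
        results = apply_rule(fixture_cohort, Rule.ADHERENCE_ONLY)
        t = build_table(results, fixture_cohort)
        assert (t.tp, t.fn, t.fp, t.tn) == (29, 9, 160, 204)

    def test_empty_results_give_zero_table(self, fixture_cohort):
        t = build_table([], fixture_cohort)
        assert (t.tp, t.fn, t.fp, t.tn) == (0, 0, 0, 0)

    def test_unknown_patient_id_raises(self, fixture_cohort):
        from fallscreen import Classification, ScreeningResult

        ghost = ScreeningResult("nope", Classification.POSITIVE, Rule.SIDE_ONLY)
        with pytest.raises(KeyError, match="nope"):
            build_table([ghost], fixture_cohort)


class TestComputeMetrics:
    @pytest.mark.parametrize(
        "cells, expected",
        [
            ((31, 5, 210, 152), (0.86, 0.42, 0.28)),
            ((29, 9, 160, 204), (0.76, 0.56, 0.32)),
            ((1, 0, 0, 1), (1.0, 1.0, 1.0)),
        ],
    )
    def test_examples_after_reporting_rounding(self, cells, expected):
        m = compute_metrics(ContingencyTable2x2(*cells)).rounded(2)
        assert (m.sensitivity, m.specificity, m.youden) == expected

    def test_youden_identity_before_rounding(self):
        m = compute_metrics(ContingencyTable2x2(31, 5, 210, 152))
        assert m.youden == pytest.approx(m.sensitivity + m.specificity - 1, abs=0)

    @pytest.mark.parametrize(
        "cells, fragment",
        [((0, 0, 3, 4), "faller"), ((3, 4, 0, 0), "non-faller")],
    )
    def test_zero_margin_error_names_the_margin(self, cells, fragment):
        with pytest.raises(ValueError, match=fragment):
            compute_metrics(ContingencyTable2x2(*cells))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="tp"):
            ContingencyTable2x2(-1, 0, 0, 1)

    @settings(derandomize=True, max_examples=200)
    @given(
        tp=st.integers(0, 20),
        fn=st.integers(0, 20),
        fp=st.integers(0, 20),
        tn=st.integers(0, 20),
        k=st.integers(1, 7),
    )
    def test_invariance_to_scaling_all_cells(self, tp, fn, fp, tn, k):
        if tp + fn == 0 or fp + tn == 0:
            return
        m1 = compute_metrics(ContingencyTable2x2(tp, fn, fp, tn))
        m2 = compute_metrics(ContingencyTable2x2(k * tp, k * fn, k * fp, k * tn))
        assert m1.sensitivity == pytest.approx(m2.sensitivity)
        assert m1.specificity == pytest.approx(m2.specificity)
        assert m1.youden == pytest.approx(m2.youden)


class TestFisher:
    def test_most_probable_table_gives_p_one(self):
        assert fisher_exact_two_sided(ContingencyTable2x2(5, 5, 5, 5)) == 1.0

    def test_memory_item_table_is_significant(self):
        assert fisher_exact_two_sided(ContingencyTable2x2(29, 9, 160, 204)) < 0.05

    def test_small_table_matches_enumeration_oracle(self):
        p = fisher_exact_two_sided(ContingencyTable2x2(12, 5, 2, 10))
        oracle = float(fisher_two_sided_enumeration(12, 5, 2, 10))
        assert p == pytest.approx(oracle, abs=1e-12)

    @settings(derandomize=True, max_examples=300)
    @given(
        tp=st.integers(0, 15),
        fn=st.integers(0, 15),
        fp=st.integers(0, 15),
        tn=st.integers(0, 15),
    )
    def test_agrees_with_enumeration_on_random_tables(self, tp, fn, fp, tn):
        if tp + fn + fp + tn == 0:
            return
        p = fisher_exact_two_sided(ContingencyTable2x2(tp, fn, fp, tn))
        oracle = float(fisher_two_sided_enumeration(tp, fn, fp, tn))
        assert 0.0 < p <= 1.0 or oracle == 0.0
        assert p == pytest.approx(oracle, abs=1e-12)


def _mini_cohort(faller_levels, non_faller_levels):
    recs = []
    for i, lvl in enumerate(faller_levels):
        recs.append(
            make_record(
                id=f"f{i}",
                side=lvl,
                fell_within_14d=True,
                management=ManagementCategory.C1_SENSOR_RESTRAINT,
            )
        )
    for i, lvl in enumerate(non_faller_levels):
        recs.append(make_record(id=f"n{i}", side=lvl))
    return Cohort.from_records(recs)


class TestOptimizeCutoff:
    def test_fixture_selects_2a_2b(self, fixture_cohort):
        best, grid = optimize_cutoff(fixture_cohort)
        assert str(best) == "2a/2b"
        assert len(grid) == 5

    def test_fixture_youden_at_2b_3_rounds_to_quarter(self, fixture_cohort):
        from fallscreen import round_half_up

        _, grid = optimize_cutoff(fixture_cohort)
        row = grid[grid["cutoff"] == "2b/3"].iloc[0]
        assert round_half_up(row["youden"], 2) == 0.25

    def test_perfect_separation_tie_breaks_to_lowest_boundary(self):
        cohort = _mini_cohort(
            [SideLevel.L0] * 4, [SideLevel.L4] * 6
        )
        best, grid = optimize_cutoff(cohort)
        assert str(best) == "0/1"
        assert grid["youden"].max() == pytest.approx(1.0)

    def test_requires_testable_records_in_both_groups(self):
        cohort = _mini_cohort([SideLevel.NOT_TESTABLE], [SideLevel.L2A])
        with pytest.raises(ValueError, match="testable"):
            optimize_cutoff(cohort)

    def test_grid_rows_reproducible_from_primitives(self, fixture_cohort):
        from fallscreen import classify_side

        _, grid = optimize_cutoff(fixture_cohort)
        for _, row in grid.iterrows():
            cut = SideCutoff.parse(row["cutoff"])
            results = [classify_side(r, cut) for r in fixture_cohort]
            m = compute_metrics(build_table(results, fixture_cohort))
            assert m.youden == pytest.approx(row["youden"], abs=0)
            assert m.n_analyzed == row["n"]

    def test_moving_faller_below_boundary_never_decreases_sensitivity(
        self, fixture_cohort
    ):
        """Monotone data shift: reclassifying one faller's balance from above
        to below a boundary can only help sensitivity at that boundary."""
        boundary = SideCutoff.parse("2a/2b")
        base_results = apply_rule(fixture_cohort, Rule.SIDE_ONLY, cutoff=boundary)
        base_sens = compute_metrics(build_table(base_results, fixture_cohort)).sensitivity
        # move the single level-3 faller down to level 2a
        recs = [
            dataclasses.replace(r, side=SideLevel.L2A)
            if r.fell_within_14d and r.side is SideLevel.L3
            else r
            for r in fixture_cohort
        ]
        shifted = Cohort.from_records(recs)
        new_results = apply_rule(shifted, Rule.SIDE_ONLY, cutoff=boundary)
        new_sens = compute_metrics(build_table(new_results, shifted)).sensitivity
        assert new_sens >= base_sens
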