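"""Screening rules: single predictors and the two-stage combined rule."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fallscreen import (
    Classification,
    Cohort,
    ExclusionReason,
    ItemResult,
    Rule,
    SideCutoff,
    SideLevel,
    apply_rule,
    classify_adherence,
    classify_combined,
    classify_side,
)
from fallscreen.cohort import AdherenceItemResult, ManagementCategory
from fallscreen.screening import exclusion_counts
from test_cohort import make_record

CUT_2A_2B = SideCutoff.parse("2a/2b")
CUT_2B_3 = SideCutoff.parse("2b/3")


class TestSideCutoff:
    def test_parse_round_trip(self):
        assert str(SideCutoff.parse("2a/2b")) == "2a/2b"

    @pytest.mark.parametrize("token", ["2a/3", "4/3", "not_testable/0", "2a", "x/y"])
    def test_rejects_non_adjacent_or_malformed(self, token):
        with pytest.raises(ValueError):
            SideCutoff.parse(token)


class TestClassifySide:
    def test_level_at_or_below_boundary_is_positive(self):
        res = classify_side(make_record(side=SideLevel.L2A), CUT_2A_2B)
        assert res.classification is Classification.POSITIVE

    @pytest.mark.parametrize("cutoff", ["0/1", "1/2a", "2a/2b", "2b/3", "3/4"])
    def test_best_balance_is_negative_at_any_cutoff(self, cutoff):
        res = classify_side(make_record(side=SideLevel.L4), SideCutoff.parse(cutoff))
        assert res.classification is Classification.NEGATIVE

    def test_not_testable_is_excluded(self):
        res = classify_side(make_record(side=SideLevel.NOT_TESTABLE), CUT_2A_2B)
        assert res.classification is Classification.EXCLUDED
        assert res.exclusion_reason is ExclusionReason.SIDE_MISSING


class TestClassifyAdherence:
    @pytest.mark.parametrize(
        "mi, expected",
        [
            (ItemResult.POSITIVE, Classification.POSITIVE),
            (ItemResult.NEGATIVE, Classification.NEGATIVE),
            (ItemResult.MISSING, Classification.EXCLUDED),
        ],
    )
    def test_direct_mapping(self, mi, expected):
        rec = make_record(adherence=AdherenceItemResult(memory_instruction=mi))
        assert classify_adherence(rec).classification is expected

    def test_fixture_analysis_set_size(self, fixture_cohort):
        results = apply_rule(fixture_cohort, Rule.ADHERENCE_ONLY)
        analyzed = [r for r in results if r.classification is not Classification.EXCLUDED]
        assert len(analyzed) == 402


class TestClassifyCombined:
    def test_good_balance_forces_negative_even_if_item_positive(self):
        rec = make_record(
            side=SideLevel.L3,
            adherence=AdherenceItemResult(memory_instruction=ItemResult.POSITIVE),
        )
        assert classify_combined(rec).classification is Classification.NEGATIVE

    def test_poor_balance_with_negative_item_is_negative(self):
        rec = make_record(
            side=SideLevel.L1,
            adherence=AdherenceItemResult(memory_instruction=ItemResult.NEGATIVE),
        )
        assert classify_combined(rec).classification is Classification.NEGATIVE

    def test_poor_balance_with_positive_item_is_positive(self):
        rec = make_record(
            side=SideLevel.L0,
            adherence=AdherenceItemResult(memory_instruction=ItemResult.POSITIVE),
        )
        assert classify_combined(rec).classification is Classification.POSITIVE

    @pytest.mark.parametrize(
        "side, mi, reason",
        [
            (SideLevel.NOT_TESTABLE, ItemResult.POSITIVE, ExclusionReason.SIDE_MISSING),
            (SideLevel.L1, ItemResult.MISSING, ExclusionReason.ADHERENCE_MISSING),
            (SideLevel.NOT_TESTABLE, ItemResult.MISSING, ExclusionReason.BOTH_MISSING),
        ],
    )
    def test_missing_inputs_are_excluded_with_reason(self, side, mi, reason):
        rec = make_record(side=side, adherence=AdherenceItemResult(memory_instruction=mi))
        res = classify_combined(rec)
        assert res.classification is Classification.EXCLUDED
        assert res.exclusion_reason is reason

    def test_fixture_analysis_set_and_forced_negatives(self, fixture_cohort):
        results = apply_rule(fixture_cohort, Rule.COMBINED)
        analyzed = [r for r in results if r.classification is not Classification.EXCLUDED]
        assert len(analyzed) == 390
        by_id = fixture_cohort.by_id()
        good_balance = [
            r
            for r in analyzed
            if by_id[r.patient_id].side in (SideLevel.L3, SideLevel.L4)
        ]
        assert len(good_balance) == 103
        assert all(
            r.classification is Classification.NEGATIVE for r in good_balance
        )


class TestApplyRule:
    def test_empty_cohort_gives_empty_results(self):
        assert apply_rule(Cohort.from_records([]), Rule.COMBINED) == []

    def test_side_only_fixture_analysis_size(self, fixture_cohort):
        results = apply_rule(fixture_cohort, Rule.SIDE_ONLY)
        analyzed = [r for r in results if r.classification is not Classification.EXCLUDED]
        assert len(analyzed) == 398

    def test_combined_exclusion_cascade(self, fixture_cohort):
        """18 missing SIDE and 14 missing memory item overlap in 6 patients,
        so the combined rule drops 26 of 416."""
        results = apply_rule(fixture_cohort, Rule.COMBINED)
        counts = exclusion_counts(results)
        assert sum(counts.values()) == 26
        assert counts[ExclusionReason.BOTH_MISSING] == 6
        assert counts[ExclusionReason.SIDE_MISSING] == 12  # 18 total NT - 6 both
        assert counts[ExclusionReason.ADHERENCE_MISSING] == 8  # 14 total - 6 both


# ---------------------------------------------------------------------------
# Rule-consistency invariants over arbitrary records
# ---------------------------------------------------------------------------

@st.composite
def _records(draw):
    fell = draw(st.booleans())
    return make_record(
        side=draw(st.sampled_from(list(SideLevel))),
        adherence=AdherenceItemResult(
            memory_instruction=draw(st.sampled_from(list(ItemResult)))
        ),
        fell_within_14d=fell,
        management=(
            draw(st.sampled_from([c for c in ManagementCategory if c is not ManagementCategory.NONE]))
            if fell
            else ManagementCategory.NONE
        ),
    )


records = _records()


@settings(derandomize=True, max_examples=300)
@given(records)
def test_combined_never_upgrades_good_balance(rec):
    side_res = classify_side(rec, CUT_2B_3)
    if side_res.classification is Classification.NEGATIVE:
        assert classify_combined(rec).classification is not Classification.POSITIVE


@settings(derandomize=True, max_examples=300)
@given(records)
def test_combined_positive_implies_both_stages_positive(rec):
    if classify_combined(rec).classification is Classification.POSITIVE:
        assert classify_adherence(rec).classification is Classification.POSITIVE
        assert rec.side.testable and rec.side <= SideLevel.L2B


@settings(derandomize=True, max_examples=300)
@given(records)
def test_combined_exclusions_are_union_of_single_rule_exclusions(rec):
    excluded_side = classify_side(rec, CUT_2A_2B).classification is Classification.EXCLUDED
    excluded_adh = classify_adherence(rec).classification is Classification.EXCLUDED
    excluded_comb = classify_combined(rec).classification is Classification.EXCLUDED
    assert excluded_comb == (excluded_side or excluded_adh)
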