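"""Imperfect-reference correction: formulas, reduction, identifiability."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diagval import (
    NotIdentifiableError,
    PairedTable,
    ReferenceProfile,
    adjusted_report,
    adjusted_sensitivity,
    adjusted_specificity,
    bootstrap_adjusted_ci,
    estimated_disease_count,
    naive_profile,
    post_test_probability,
    round_half_up,
)

PERFECT = ReferenceProfile(1.0, 1.0)

tables = st.tuples(
    st.integers(0, 60), st.integers(0, 60), st.integers(0, 60), st.integers(0, 60)
).filter(lambda cells: sum(cells) > 0).map(lambda cells: PairedTable(*cells))


class TestCorrectedEstimators:
    def test_study_sensitivity(self, study_table, mammogram_profile):
        s = adjusted_sensitivity(study_table, mammogram_profile)
        assert round_half_up(s, 3) == 0.896

    def test_study_specificity(self, study_table, mammogram_profile):
        e = adjusted_specificity(study_table, mammogram_profile)
        assert round_half_up(e, 3) == 0.964

    def test_hand_evaluated_formulas(self):
        table = PairedTable(40, 5, 10, 45)
        ref = ReferenceProfile(0.9, 0.9)
        assert adjusted_sensitivity(table, ref) == pytest.approx(35.5 / 40)
        assert adjusted_specificity(table, ref) == pytest.approx(39.5 / 40)
        assert estimated_disease_count(table, ref) == pytest.approx(50.0)

    def test_study_disease_count_and_prevalence(self, study_table, mammogram_profile):
        d = estimated_disease_count(study_table, mammogram_profile)
        assert d == pytest.approx(196.26 / 0.758, abs=0.05)
        assert round_half_up(100.0 * d / study_table.n, 1) == 76.2

    def test_not_identifiable_when_positives_below_false_positive_floor(self):
        # 50% reference-positive but the reference alone would produce 40%
        # false positives among a disease-free cohort this size.
        table = PairedTable(5, 5, 0, 0)
        with pytest.raises(NotIdentifiableError, match="false positives"):
            adjusted_sensitivity(table, ReferenceProfile(0.9, 0.4))

    def test_not_identifiable_when_positives_exceed_reference_ceiling(self):
        table = PairedTable(9, 1, 0, 0)
        with pytest.raises(NotIdentifiableError):
            adjusted_specificity(table, ReferenceProfile(0.6, 0.9))

    @settings(derandomize=True, max_examples=100)
    @given(tables)
    def test_perfect_reference_reduces_to_naive(self, table):
        profile = naive_profile(table)
        if table.ref_pos > 0:
            assert adjusted_sensitivity(table, PERFECT) == pytest.approx(
                profile.sensitivity.point, abs=1e-12
            )
        if table.ref_neg > 0:
            assert adjusted_specificity(table, PERFECT) == pytest.approx(
                profile.specificity.point, abs=1e-12
            )
        assert estimated_disease_count(table, PERFECT) == table.ref_pos

    def test_sensitivity_decreases_with_reference_specificity(self, study_table):
        # On positively-associated tables (PPV > prevalence), lowering beta
        # enlarges the false-positive correction and inflates S.
        grid = [0.75, 0.8, 0.85, 0.889, 0.93, 0.97]
        values = [
            adjusted_sensitivity(study_table, ReferenceProfile(0.869, beta))
            for beta in grid
        ]
        assert all(v1 >= v2 for v1, v2 in zip(values, values[1:]))


class TestAdjustedReport:
    def test_study_downstream_indicators(self, study_table, mammogram_profile):
        report = adjusted_report(study_table, mammogram_profile)
        assert round_half_up(100 * report.ppv, 1) == 98.8
        assert round_half_up(100 * report.npv, 1) == 74.4
        assert round_half_up(100 * report.prevalence, 1) == 76.2
        assert round_half_up(report.youden, 1) == 0.9
        assert round_half_up(report.lr_pos, 1) == 24.9
        assert round_half_up(report.lr_neg, 2) == 0.11
        assert round_half_up(100 * report.post_test_probability, 1) == 98.2
        # Validity computes to 91.2 on this table (printed elsewhere as 91.3).
        assert abs(100 * report.validity_index - 91.2) <= 0.05
        assert report.flags == ()

    def test_validity_identity_exact(self, study_table, mammogram_profile):
        report = adjusted_report(study_table, mammogram_profile)
        assert report.validity_index == pytest.approx(
            report.sensitivity * report.prevalence
            + report.specificity * (1 - report.prevalence),
            abs=1e-15,
        )
        assert report.youden == report.sensitivity + report.specificity - 1.0

    def test_hand_evaluated_ppv(self):
        report = adjusted_report(PairedTable(40, 5, 10, 45), ReferenceProfile(0.9, 0.9))
        assert report.prevalence == pytest.approx(0.5)
        assert report.ppv == pytest.approx(0.8875 * 0.5 / (0.8875 * 0.5 + 0.0125 * 0.5))

    def test_perfect_reference_report_equals_naive_column(self, study_table):
        report = adjusted_report(study_table, PERFECT)
        profile = naive_profile(study_table)
        assert report.sensitivity == pytest.approx(profile.sensitivity.point)
        assert report.specificity == pytest.approx(profile.specificity.point)
        assert report.ppv == pytest.approx(profile.ppv.point)
        assert report.npv == pytest.approx(profile.npv.point)
        assert report.validity_index == pytest.approx(profile.validity_index.point)
        assert report.lr_pos == pytest.approx(profile.lr_pos.point)
        assert report.lr_neg == pytest.approx(profile.lr_neg.point)

    def test_out_of_range_estimate_flagged_not_clamped(self):
        # A table whose corrected specificity exceeds 1 under these (alpha, beta).
        table = PairedTable(30, 0, 5, 65)
        ref = ReferenceProfile(0.6, 0.99)
        report = adjusted_report(table, ref)
        assert report.specificity > 1.0
        assert any("outside [0, 1]" in flag for flag in report.flags)
        clamped = adjusted_report(table, ref, clamp=True)
        assert clamped.specificity == 1.0 and clamped.clamped

    def test_perfect_adjusted_specificity_marks_lr_pos_undefined(self):
        report = adjusted_report(PairedTable(9, 1, 1, 9), ReferenceProfile(0.9, 1.0), clamp=True)
        if report.specificity == 1.0:
            assert math.isnan(report.lr_pos)
            assert any("LR+" in flag for flag in report.flags)


class TestPostTestProbability:
    def test_study_value(self, study_table, mammogram_profile):
        s = adjusted_sensitivity(study_table, mammogram_profile)
        e = adjusted_specificity(study_table, mammogram_profile)
        pre = study_table.ref_pos / study_table.n
        assert round_half_up(post_test_probability(pre, s / (1 - e)), 3) == 0.982

    def test_uninformative_ratio_is_identity(self):
        assert post_test_probability(0.37, 1.0) == pytest.approx(0.37)

    def test_hand_value(self):
        assert post_test_probability(0.5, 3.0) == pytest.approx(0.75)

    @pytest.mark.parametrize("pre,lr", [(0.0, 2.0), (1.0, 2.0), (0.5, 0.0), (0.5, -1.0)])
    def test_boundaries_are_errors_not_clamps(self, pre, lr):
        with pytest.raises(ValueError):
            post_test_probability(pre, lr)


class TestBootstrapCI:
    def test_interval_brackets_point_and_is_reproducible(self, study_table, mammogram_profile):
        result = bootstrap_adjusted_ci(study_table, mammogram_profile, n_boot=400, seed=11)
        s = 0.896
        lo, hi = result["sensitivity"]
        assert lo < s < hi
        again = bootstrap_adjusted_ci(study_table, mammogram_profile, n_boot=400, seed=11)
        assert again == result
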