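import numpy as np
import pandas as pd
import pytest

from bcellref import (ContinuousReference, MissingReferenceError, RangeError,
                      ReferenceBand, SubsetPanel, ValidationError,
                      compare_markers, evaluate_patient)


def make_reference(subset, measure, a=30, b=-25, c=-1.0, lo90=-8, hi90=8,
                   lo95=-12, hi95=12, kind="absolute_count"):
    return ContinuousReference(
        subset=subset, measure=measure, denominator="cd19",
        a=a, b_scaled=b, c=c, x0=0.0, n=200, ssr=1.0, measure_kind=kind,
        bands=(ReferenceBand(0.90, lo90, hi90), ReferenceBand(0.95, lo95, hi95)))


class TestSubsetPanel:
    def test_fraction_out_of_range(self):
        with pytest.raises(ValidationError, match="fraction"):
            SubsetPanel({("naive", "pct"): 120.0})

    def test_negative_count(self):
        with pytest.raises(ValidationError, match="negative"):
            SubsetPanel({("switched", "abs"): -1.0})

    def test_memory_sum_enforced(self):
        with pytest.raises(ValidationError, match="sum"):
            SubsetPanel({("memory", "abs"): 50.0, ("nonswitched", "abs"): 10.0,
                         ("switched", "abs"): 10.0})

    def test_from_row(self, included_cohort):
        panel = SubsetPanel.from_row(included_cohort.iloc[0], "cd19")
        assert ("naive", "pct") in panel.values
        assert panel.denominator_marker == "CD19"

    def test_dual_platform_helper(self):
        assert SubsetPanel.absolute_from_dual_platform(2000, 15.0) == 300.0
        with pytest.raises(ValidationError):
            SubsetPanel.absolute_from_dual_platform(-1, 15.0)


class TestEvaluatePatient:
    def test_absent_switched_memory_flagged_below(self):
        """A 7-month-old with 0 switched memory cells/μl falls below a
        reference whose lower 90% limit at 0.58 y is positive."""
        ref = make_reference("switched", "abs")
        lo90, _ = ref.limits(0.58, 0.90)
        assert lo90 > 0
        panel = SubsetPanel({("switched", "abs"): 0.0})
        report = evaluate_patient(panel, 0.58, [ref])
        ev = report.evaluations[0]
        assert ev.flags[0.90] == "below"
        assert ev.abnormal

    def test_observed_equal_predicted_is_within(self):
        ref = make_reference("naive", "pct", a=60, b=38, c=-0.3, kind="fraction_percent")
        observed = ref.predicted(5.0)
        report = evaluate_patient(SubsetPanel({("naive", "pct"): observed}), 5.0, [ref])
        assert set(report.evaluations[0].flags.values()) == {"within"}

    def test_boundary_value_is_within(self):
        # closed intervals: exactly on the upper 90% limit counts as within
        ref = make_reference("memory", "abs")
        _, hi90 = ref.limits(3.0, 0.90)
        report = evaluate_patient(SubsetPanel({("memory", "abs"): hi90}), 3.0, [ref])
        ev = report.evaluations[0]
        assert ev.flags[0.90] == "within"

    def test_flag_trichotomy_and_nesting(self):
        ref = make_reference("naive", "abs")
        rng = np.random.default_rng(0)
        for observed in rng.uniform(-20, 80, 200):
            report = evaluate_patient(
                SubsetPanel({("naive", "abs"): max(observed, 0.0)}), 4.0, [ref])
            flags = report.evaluations[0].flags
            assert set(flags.values()) <= {"below", "within", "above"}
            # nested bands: outside the wide band implies outside the narrow one
            if flags[0.95] == "below":
                assert flags[0.90] == "below"
            if flags[0.95] == "above":
                assert flags[0.90] == "above"

    def test_missing_reference_is_per_subset(self):
        refs = [make_reference("switched", "abs")]
        panel = SubsetPanel({("switched", "abs"): 5.0, ("naive", "abs"): 100.0})
        report = evaluate_patient(panel, 1.0, refs)
        assert len(report.evaluations) == 1
        assert report.errors and report.errors[0][0] == "naive"

    def test_no_reference_at_all_raises(self):
        with pytest.raises(MissingReferenceError):
            evaluate_patient(SubsetPanel({("naive", "abs"): 1.0}), 1.0, [])

    def test_adult_age_rejected(self):
        with pytest.raises(RangeError):
            evaluate_patient(SubsetPanel({("naive", "abs"): 1.0}), 19.0,
                             [make_reference("naive", "abs")])

    def test_round_trip_within_rate_matches_confidence(self, included_cohort):
        """Evaluating the fitting cohort against its own reference flags
        ~10% of subjects outside the 90% band."""
        from bcellref import ExponentialAgeModel, build_reference

        res = ExponentialAgeModel.from_dataframe(included_cohort, "naive_pct_cd19",
                                                 subset_label="naive",
                                                 measure_label="pct").fit()
        ref = build_reference(res, "fraction_percent", denominator="cd19")
        ages = included_cohort["age_days"] / 365.0
        lo, hi = ref.limits(ages.to_numpy(), 0.90)
        vals = included_cohort["naive_pct_cd19"].to_numpy()
        within = np.mean((vals >= lo) & (vals <= hi))
        assert within == pytest.approx(0.90, abs=0.03)


class TestCompareMarkers:
    def test_identical_markers(self):
        df = pd.DataFrame({
            "totalB_abs_cd19": [200.0, 300.0], "totalB_abs_cd20": [200.0, 300.0],
            "naive_pct_cd19": [90.0, 80.0], "naive_pct_cd20": [90.0, 80.0],
            "switched_pct_cd19": [2.0, 5.0], "switched_pct_cd20": [2.0, 5.0],
            "cd20_coexpr_pct": [100.0, 100.0]})
        mc = compare_markers(df)
        assert mc.median_abs_count_diff == 0.0
        assert mc.coexpression_pct == 100.0

    def test_toy_median_difference(self):
        df = pd.DataFrame({
            "totalB_abs_cd19": [200.0, 300.0], "totalB_abs_cd20": [195.0, 290.0],
            "naive_pct_cd19": [90.0, 80.0], "naive_pct_cd20": [92.0, 82.0],
            "switched_pct_cd19": [4.0, 6.0], "switched_pct_cd20": [2.0, 4.0]})
        mc = compare_markers(df)
        assert mc.median_abs_count_diff == pytest.approx(7.5)  # median of {5, 10}
        assert mc.median_naive_pct_diff == pytest.approx(-2.0)
        assert mc.median_switched_pct_diff == pytest.approx(2.0)

    def test_default_cohort_coexpression(self, included_cohort):
        mc = compare_markers(included_cohort)
        assert mc.coexpression_pct == pytest.approx(99.0, abs=0.5)

    def test_missing_columns_named(self):
        with pytest.raises(ValidationError, match="totalB_abs_cd20"):
            compare_markers(pd.DataFrame({"totalB_abs_cd19": [1.0]}))
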