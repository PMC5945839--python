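import numpy as np
import pandas as pd
import pytest

from bcellref import (ValidationError, build_grouped_reference, build_reference,
                      fit_exponential, max_daily_increment, overlay_report,
                      step_discontinuity)
from bcellref.groups import GroupedReference


def cohort_frame(ages_years, **columns):
    df = pd.DataFrame({"age_days": np.asarray(ages_years) * 365.0})
    for name, vals in columns.items():
        df[name] = np.asarray(vals, dtype=float)
    return df


class TestBuildGroupedReference:
    def test_single_group_constant_value(self):
        df = cohort_frame(np.linspace(0, 18, 30), x=np.full(30, 50.0))
        grouped = build_grouped_reference(df, (0, 18), columns=["x"])
        row = grouped.table.iloc[0]
        assert all(row[f"p{p}"] == 50.0 for p in (5, 10, 50, 90, 95))
        assert row["mean"] == 50.0
        assert row["n"] == 30

    def test_interpolated_median_of_1_to_100(self):
        df = cohort_frame(np.linspace(0, 17.9, 100), x=np.arange(1, 101))
        grouped = build_grouped_reference(df, (0, 18), columns=["x"])
        assert grouped.table.iloc[0]["p50"] == pytest.approx(50.5)

    def test_percentiles_nondecreasing_on_default_cohort(self, included_cohort):
        grouped = build_grouped_reference(
            included_cohort, columns=["naive_pct_cd19", "switched_abs_cd19"])
        for _, row in grouped.table.iterrows():
            vals = [row[f"p{p}"] for p in (5, 10, 50, 90, 95)]
            assert vals == sorted(vals)

    def test_empty_group_named(self):
        df = cohort_frame([0.5, 0.6, 10.0], x=[1, 2, 3])
        with pytest.raises(ValidationError, match=r"\[2.0, 5.0\)"):
            build_grouped_reference(df, (0, 2, 5, 18), columns=["x"])

    def test_every_subject_in_exactly_one_group(self, included_cohort):
        grouped = build_grouped_reference(included_cohort, columns=["naive_pct_cd19"])
        total = grouped.table[grouped.table["column"] == "naive_pct_cd19"]["n"].sum()
        assert total == included_cohort["naive_pct_cd19"].notna().sum()


class TestStepDiscontinuity:
    def test_two_group_jump(self):
        df = cohort_frame([0.5] * 5 + [10.0] * 5, x=[40] * 5 + [10] * 5)
        grouped = build_grouped_reference(df, (0, 2, 18), columns=["x"])
        jumps = step_discontinuity(grouped, "x", 50)
        assert jumps["jump"].tolist() == [30.0]

    def test_age_constant_process_has_no_steps(self):
        rng = np.random.default_rng(1)
        df = cohort_frame(rng.uniform(0, 18, 20_000), x=rng.normal(50, 5, 20_000))
        grouped = build_grouped_reference(df, (0, 1, 2, 5, 11, 18), columns=["x"])
        jumps = step_discontinuity(grouped, "x", 50)
        assert (jumps["jump"] < 1.0).all()

    def test_unknown_percentile(self):
        df = cohort_frame([0.5, 10.0, 1.0, 15.0], x=[1, 2, 3, 4])
        grouped = build_grouped_reference(df, (0, 2, 18), columns=["x"])
        with pytest.raises(ValidationError, match="percentile"):
            step_discontinuity(grouped, "x", 37)

    def test_grouped_median_jumps_exceed_smooth_daily_increment(self, included_cohort):
        """Binned references jump at boundaries by far more than the smooth
        curve can move in any single day — the motivation for continuous
        reference values."""
        res = fit_exponential(included_cohort["age_days"] / 365.0,
                              included_cohort["naive_pct_cd19"],
                              subset_label="naive", measure_label="pct")
        ref = build_reference(res, "fraction_percent", denominator="cd19")
        grouped = build_grouped_reference(included_cohort, columns=["naive_pct_cd19"])
        jumps = step_discontinuity(grouped, "naive_pct_cd19", 50)
        assert jumps["jump"].max() > max_daily_increment(ref)


class TestOverlayReport:
    def test_noiseless_grouped_band_inside_continuous(self):
        # zero residual spread: within each bin the grouped 10th-90th band
        # must lie inside the continuous 95% band's range over that bin
        ages = np.linspace(0.01, 18, 300)
        vals = 60 + 38 * np.exp(-0.3 * ages)
        df = cohort_frame(ages, naive_pct_cd19=vals)
        res = fit_exponential(ages, vals, subset_label="naive", measure_label="pct")
        ref = build_reference(res, "fraction_percent", denominator="cd19")
        grouped = build_grouped_reference(df, columns=["naive_pct_cd19"])
        p10 = grouped.percentile("naive_pct_cd19", 10)
        p90 = grouped.percentile("naive_pct_cd19", 90)
        for g, (lo_age, hi_age) in enumerate(zip(grouped.group_edges,
                                                 grouped.group_edges[1:])):
            bin_ages = np.linspace(lo_age, hi_age, 50)
            lo95, hi95 = ref.limits(bin_ages, 0.95)
            assert p10[g] >= lo95.min() - 1e-6
            assert p90[g] <= hi95.max() + 1e-6

    def test_rising_trajectory_step_overshoots_at_group_start(self, included_cohort):
        res = fit_exponential(included_cohort["age_days"] / 365.0,
                              included_cohort["nonswitched_pct_cd19"],
                              subset_label="nonswitched", measure_label="pct")
        ref = build_reference(res, "fraction_percent", denominator="cd19")
        grouped = build_grouped_reference(included_cohort,
                                          columns=["nonswitched_pct_cd19"])
        # oldest group's p90 evaluated at that group's youngest age
        oldest_lo = grouped.group_edges[-2]
        p90_oldest = grouped.percentile("nonswitched_pct_cd19", 90)[-1]
        _, upper90 = ref.limits(oldest_lo, 0.90)
        still_rising = ref.predicted(oldest_lo) < ref.predicted(18.0) - 1e-9
        if still_rising:
            assert p90_oldest > ref.predicted(oldest_lo)

    def test_published_table_pass_through(self):
        rows = pd.DataFrame({
            "column": ["memory_pct_cd20"] * 2,
            "p10": [6.1, 10.2], "p50": [10.0, 20.0], "p90": [16.9, 35.6],
        })
        grouped = GroupedReference.from_published((0, 11, 18), rows)
        assert grouped.n_groups == 2
        np.testing.assert_allclose(grouped.step_value("memory_pct_cd20", 90, [12.0]),
                                   [35.6])

    def test_mismatched_subset_rejected(self):
        df = cohort_frame([0.5, 5.0, 10.0, 16.0], switched_pct_cd19=[1, 5, 8, 9])
        grouped = build_grouped_reference(df, (0, 18), columns=["switched_pct_cd19"])
        res = fit_exponential([0, 1, 2, 4, 8.0], [98, 80, 60, 40, 20.0],
                              subset_label="naive", measure_label="pct")
        ref = build_reference(res, "fraction_percent", denominator="cd19")
        with pytest.raises(ValidationError, match="naive_pct_cd19"):
            overlay_report(grouped, ref)


class TestRefinementConsistency:
    def test_narrow_groups_converge_to_smooth_curve(self):
        # noiseless declining curve, ever finer bins: grouped medians track it
        ages = np.linspace(0.01, 18, 2000)
        vals = 60 + 38 * np.exp(-0.3 * ages)
        df = cohort_frame(ages, x=vals)
        edges = tuple(np.linspace(0, 18, 37))  # half-year bins
        grouped = build_grouped_reference(df, edges, columns=["x"])
        mids = [(a + b) / 2 for a, b in zip(edges, edges[1:])]
        medians = grouped.percentile("x", 50)
        curve_mid = 60 + 38 * np.exp(-0.3 * np.asarray(mids))
        assert np.max(np.abs(medians - curve_mid)) < 1.0
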