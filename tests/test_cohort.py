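"""Cohort construction, survivorship projection and assemblage summaries."""

import math

import numpy as np
import pandas as pd
import pytest

import loggerhead as lh
from loggerhead.cohort import (
    FEMALES_BY_NR_5PCT,
    FEMALES_BY_NR_10PCT,
    FIXED_FEMALES,
    FIXED_MALES,
)

SURV = lh.StageSurvival()
PROD = lh.HatchlingProduction()


class TestHatchlingProduction:
    def test_fixed_production(self):
        assert lh.hatchlings_fixed(PROD) == 2_587_500

    def test_zero_nests(self):
        assert lh.hatchlings_fixed(PROD, nests=0) == 0

    def test_range_floor_nest_count(self):
        assert lh.hatchlings_fixed(PROD, nests=30_000) == 1_725_000

    def test_sinusoid_extrema_over_run(self):
        hatchlings = [lh.hatchlings_sinusoid(o, PROD)[1] for o in range(1, 166)]
        assert min(hatchlings) == 1_725_000
        assert max(hatchlings) == 3_449_942

    def test_sinusoid_order_one_direct_arithmetic(self):
        nests, hatch = lh.hatchlings_sinusoid(1, PROD)
        expected_nests = math.floor(math.sin(1 / 2.5) * 15_000 + 45_000)
        assert nests == expected_nests
        assert hatch == math.floor(expected_nests * 115 * 0.5)

    def test_order_is_one_based(self):
        with pytest.raises(ValueError):
            lh.hatchlings_sinusoid(0, PROD)

    def test_invalid_production_rejected(self):
        with pytest.raises(ValueError):
            lh.HatchlingProduction(eggs_per_nest=0)
        with pytest.raises(ValueError):
            lh.HatchlingProduction(ocean_entry_fraction=1.5)


class TestSexSplit:
    def test_fixed_split_m1_m2(self):
        for variant in ("M1", "M2"):
            rule = lh.SexSplitRule(variant)
            assert lh.sex_split(2_587_500, 10, rule) == (FIXED_FEMALES,
                                                         FIXED_MALES)

    def test_m3_lookup_with_male_by_subtraction(self):
        f, m = lh.sex_split(2_587_500, 9, lh.SexSplitRule("M3"))
        assert f == 2_134_687
        assert m == 2_587_500 - 2_134_687 == 452_813

    def test_m4_lookup_extreme(self):
        f, _ = lh.sex_split(2_587_500, 12, lh.SexSplitRule("M4"))
        assert f == 2_458_125

    def test_m4_lookup_matches_floored_fractions(self):
        # every table entry equals floor(proportion x fixed total)
        for nr, frac in zip((8, 9, 10, 11, 12), (0.75, 0.80, 0.85, 0.90, 0.95)):
            assert FEMALES_BY_NR_10PCT[nr] == math.floor(frac * 2_587_500)
        for nr, frac in zip((8, 9, 10, 11, 12), (0.80, 0.825, 0.85, 0.875, 0.90)):
            assert FEMALES_BY_NR_5PCT[nr] == math.floor(frac * 2_587_500)

    def test_m5_proportional_split(self):
        assert lh.sex_split(2_000_000, 10, lh.SexSplitRule("M5")) == (1_700_000,
                                                                      300_000)

    def test_split_conserves_total(self):
        for variant in ("M3", "M4", "M5"):
            for nr in (8, 9, 10, 11, 12):
                f, m = lh.sex_split(2_587_500, nr, lh.SexSplitRule(variant))
                assert f + m == 2_587_500

    def test_lookup_miss_is_config_error(self):
        with pytest.raises(ValueError, match="NR=7"):
            lh.sex_split(100, 7, lh.SexSplitRule("M3"))


class TestSurvivorship:
    def test_age_zero_is_a0s(self):
        assert lh.survivorship_proportion(0, 10, SURV) == pytest.approx(0.4)

    def test_oceanic_phase_unrolled(self):
        assert lh.survivorship_proportion(9, 10, SURV) == pytest.approx(
            0.4 * 0.713 ** 9)

    def test_first_neritic_survival_in_recruitment_year(self):
        assert lh.survivorship_proportion(10, 10, SURV) == pytest.approx(
            0.4 * 0.713 ** 9 * 0.854)

    def test_age_77_matches_loop_oracle(self):
        p = 0.4
        for age in range(1, 78):
            p *= 0.713 if age <= 9 else 0.854
        assert lh.survivorship_proportion(77, 10, SURV) == pytest.approx(
            p, rel=1e-12)

    def test_curve_agrees_with_scalar(self):
        curve = lh.survivorship_curve(8, SURV)
        for age in (0, 1, 7, 8, 40, 77):
            assert curve[age] == pytest.approx(
                lh.survivorship_proportion(age, 8, SURV), rel=1e-12)

    def test_age_out_of_range(self):
        with pytest.raises(ValueError):
            lh.survivorship_proportion(78, 10, SURV)

    def test_survival_rates_validated(self):
        with pytest.raises(ValueError):
            lh.StageSurvival(os=1.2)


class TestProject:
    def test_m1_equilibrium_total(self, m1_summary):
        totals = m1_summary.groupby("year")["total"].sum()
        assert len(totals) == 165
        assert (totals == 288_232).all()

    def test_m1_age_group_shares(self, m1_summary):
        year = m1_summary[m1_summary["year"] == 1950]
        counts = year.set_index("group")["total"].reindex(
            ["NR-19", "20-29", "30-77"])
        assert lh.whole_percent_shares(counts) == [80, 16, 4]

    def test_zero_hatchlings_zero_counts(self):
        prod = lh.HatchlingProduction(fixed_nests=0)
        config = lh.ModelConfig(variant="M5", production=prod,
                                reported_span=5)
        # M5 burn-in cohorts use the fixed production (0 nests here)
        table = lh.project(config)
        burn_in = table[table["cohort_year"] < 1856]
        assert (burn_in["count"] == 0).all()

    def test_toy_projection_hand_enumerated(self):
        # one reported cohort, tiny ages: nr=2, max_age=4
        sched = lh.RecruitmentSchedule({}, default_nr=2)
        config = lh.ModelConfig(variant="M1", schedule=sched, burn_in=4,
                                max_age=4, reported_span=1, start_year=2000)
        table = lh.project(config)
        cohort = table[(table["cohort_year"] == 2000) & (table["sex"] == "F")]
        h = FIXED_FEMALES
        expected = [
            math.floor(h * 0.4),                            # age 0, oceanic
            math.floor(h * 0.4 * 0.713),                    # age 1, oceanic
            math.floor(h * 0.4 * 0.713 * 0.854),            # age 2, neritic
            math.floor(h * 0.4 * 0.713 * 0.854 ** 2),       # age 3
            math.floor(h * 0.4 * 0.713 * 0.854 ** 3),       # age 4
        ]
        assert list(cohort.sort_values("age")["count"]) == expected
        assert list(cohort.sort_values("age")["realm"]) == [
            "oceanic", "oceanic", "neritic", "neritic", "neritic"]
        assert list(cohort.sort_values("age")["year"]) == list(
            range(2000, 2005))

    def test_conservation_counts_non_increasing_with_age(self, m1_table):
        for (_, _), grp in m1_table.groupby(["cohort_year", "sex"]):
            counts = grp.sort_values("age")["count"].to_numpy()
            assert (np.diff(counts) <= 0).all()

    def test_closed_form_matches_float_simulation(self):
        for nr in (8, 10, 12):
            curve = lh.survivorship_curve(nr, SURV)
            float_total = float(np.sum(FIXED_FEMALES * curve[nr:]))
            closed = lh.neritic_total_closed_form(FIXED_FEMALES, nr, SURV)
            assert closed == pytest.approx(float_total, rel=1e-9)

    def test_floored_total_close_to_float_total(self, m1_summary):
        float_total = sum(
            lh.neritic_total_closed_form(h, 10, SURV)
            for h in (FIXED_FEMALES, FIXED_MALES))
        floored = m1_summary.groupby("year")["total"].sum().iloc[0]
        n_cells = 2 * 68  # sexes x neritic ages 10..77
        assert 0 <= float_total - floored < 2 * n_cells

    def test_burn_in_must_cover_max_age(self):
        with pytest.raises(ValueError):
            lh.ModelConfig(burn_in=10, max_age=77)


class TestAgeGroupSummary:
    def test_m2_female_proportion_fixed(self, variant_summaries):
        # every cohort enters at exactly 0.85 female; per-cell flooring can
        # shift a group's realised ratio by at most ~cells/total
        summary = variant_summaries["M2"].dropna(subset=["proportion_female"])
        n_cells = 2 * 96  # sexes x ages, generous for the widest group
        tol = n_cells / summary["total"]
        assert ((summary["proportion_female"] - 0.85).abs() <= tol).all()

    def test_m3_m4_mixture_bounds(self, variant_summaries):
        # flooring shifts a group ratio by at most cells/total (~1e-4)
        for variant, lo, hi in (("M3", 0.80, 0.90), ("M4", 0.75, 0.95)):
            pf = variant_summaries[variant]["proportion_female"].dropna()
            assert pf.min() >= lo - 1e-3
            assert pf.max() <= hi + 1e-3

    def test_groups_partition_neritic_total(self, m1_table, m1_summary):
        neritic = m1_table[(m1_table["realm"] == "neritic")
                           & m1_table["year"].between(1856, 2020)]
        assert (m1_summary.groupby("year")["total"].sum()
                == neritic.groupby("year")["count"].sum()).all()

    def test_single_cohort_concentrated_in_own_group(self):
        sched = lh.RecruitmentSchedule({}, default_nr=10)
        config = lh.ModelConfig(variant="M1", schedule=sched, burn_in=77,
                                max_age=77, reported_span=1, start_year=2000)
        table = lh.project(config)
        # in the single reported year, the age-25 cohort sits in 20-29
        year_2000 = table[(table["year"] == 2000) & (table["age"] == 25)]
        summary = lh.age_group_summary(table)
        g2 = summary[summary["group"] == "20-29"]
        assert g2["total"].iloc[0] >= year_2000["count"].sum() > 0


class TestMfRatio:
    def test_fixed_split_ratio(self, m1_summary):
        ratios = lh.mf_ratio_series(m1_summary, "30-77").dropna()
        assert np.allclose(ratios, 388_125 / 2_199_375, atol=2e-3)

    def test_m1_median_ratio_printed_value(self, m1_summary):
        median = lh.mf_ratio_series(m1_summary, "30-77").median()
        assert round(median, 2) == 0.17

    def test_m4_ratio_skewed_toward_increases(self, variant_summaries):
        ratios = lh.mf_ratio_series(variant_summaries["M4"], "30-77").dropna()
        med = ratios.median()
        assert ratios.min() < med < ratios.max()
        # peak excursions above the median exceed those below it
        assert ratios.max() - med > med - ratios.min()


class TestWholePercentShares:
    def test_sums_to_100(self, rng):
        for _ in range(20):
            counts = rng.integers(1, 1000, size=3)
            assert sum(lh.whole_percent_shares(counts)) == 100

    def test_exact_split_unchanged(self):
        assert lh.whole_percent_shares([80, 16, 4]) == [80, 16, 4]

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            lh.whole_percent_shares([0, 0, 0])
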