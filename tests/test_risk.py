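import numpy as np
import pytest

from gastroseg.phantoms import PatientRecord, generate_cohort, simulate_logistic_cohort
from gastroseg.risk import (
    ContingencyTable2x2,
    PerfectSeparationError,
    analyze,
    chi_square,
    crosstab,
    crosstab_location,
    logistic_fit,
    logistic_fit_xy,
    odds_ratio,
    proportions,
)


@pytest.fixture(scope="module")
def exact_cohort():
    records, _ = generate_cohort(56, 30, exact=True, seed=1, with_images=False)
    return records


def _record(recurrence, **kw):
    base = dict(
        patient_id="p", age_group="under60", sex="male", diameter_group="lt6cm",
        tnm_group="I_II", chemo=False, location="distal", recurrence=recurrence,
    )
    base.update(kw)
    return PatientRecord(**base)


class TestCrosstab:
    def test_published_age_table(self, exact_cohort):
        t = crosstab(exact_cohort, "age")
        assert (t.a, t.b, t.c, t.d) == (44, 12, 7, 23)

    def test_single_record_single_cell(self):
        t = crosstab([_record(True, age_group="ge60")], "age")
        assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 0)

    def test_counts_partition_cohort_for_every_factor(self, exact_cohort):
        for factor in ("age", "sex", "diameter", "tnm", "chemo"):
            assert crosstab(exact_cohort, factor).total == 86
        assert crosstab_location(exact_cohort).sum() == 86

    def test_unknown_factor_rejected(self, exact_cohort):
        with pytest.raises(ValueError, match="unknown factor"):
            crosstab(exact_cohort, "grade")


class TestProportions:
    def test_published_age_percentages(self, exact_cohort):
        p = proportions(crosstab(exact_cohort, "age"))
        assert p["recurrence"]["level1"] == 78.57
        assert p["recurrence"]["level0"] == 21.43
        assert p["no_recurrence"]["level1"] == 23.33
        assert p["no_recurrence"]["level0"] == 76.67

    def test_zero_numerator(self):
        p = proportions(ContingencyTable2x2(0, 10, 5, 5))
        assert p["recurrence"]["level1"] == 0.0
        assert p["recurrence"]["level0"] == 100.0

    def test_rows_sum_to_hundred_within_rounding(self, exact_cohort):
        for factor in ("age", "sex", "diameter", "tnm", "chemo"):
            p = proportions(crosstab(exact_cohort, factor))
            for arm in p.values():
                assert abs(arm["level1"] + arm["level0"] - 100.0) <= 0.01


class TestChiSquare:
    def test_identical_row_proportions_give_zero(self):
        stat, p = chi_square(ContingencyTable2x2(20, 10, 40, 20))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_age_table_closed_form(self):
        # n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) = 86*928^2/(56*30*51*35)
        stat, p = chi_square(ContingencyTable2x2(44, 12, 7, 23))
        assert stat == pytest.approx(86 * 928**2 / (56 * 30 * 51 * 35), rel=1e-12)
        assert stat == pytest.approx(24.70, abs=0.01)
        assert p < 1e-5

    def test_invariant_under_row_and_column_swap(self):
        t = ContingencyTable2x2(44, 12, 7, 23)
        swapped_rows = ContingencyTable2x2(7, 23, 44, 12)
        swapped_cols = ContingencyTable2x2(12, 44, 23, 7)
        assert chi_square(t)[0] == pytest.approx(chi_square(swapped_rows)[0])
        assert chi_square(t)[0] == pytest.approx(chi_square(swapped_cols)[0])

    def test_matches_scipy_general_pearson(self):
        from scipy.stats import chi2_contingency

        t = ContingencyTable2x2(44, 12, 7, 23)
        ref = chi2_contingency(t.as_array(), correction=False)
        assert chi_square(t)[0] == pytest.approx(ref.statistic, rel=1e-12)

    def test_location_2x3_uses_two_df(self, exact_cohort):
        stat, p = chi_square(crosstab_location(exact_cohort))
        from scipy.stats import chi2

        assert p == pytest.approx(float(chi2.sf(stat, df=2)), rel=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square(ContingencyTable2x2(0, 10, 0, 20))


class TestOddsRatio:
    def test_proportional_rows_give_unity(self):
        oratio, _ = odds_ratio(ContingencyTable2x2(20, 10, 40, 20))
        assert oratio == pytest.approx(1.0)

    def test_age_table_direct_arithmetic(self):
        oratio, (lo, hi) = odds_ratio(ContingencyTable2x2(44, 12, 7, 23))
        assert oratio == pytest.approx((44 * 23) / (12 * 7), rel=1e-12)
        assert lo <= oratio <= hi

    def test_double_swap_invariance(self):
        a = odds_ratio(ContingencyTable2x2(44, 12, 7, 23))[0]
        b = odds_ratio(ContingencyTable2x2(23, 7, 12, 44))[0]
        assert a == pytest.approx(b)

    def test_haldane_correction_on_zero_cell(self):
        oratio, _ = odds_ratio(ContingencyTable2x2(10, 0, 5, 5))
        assert np.isfinite(oratio)
        assert oratio == pytest.approx((10.5 * 5.5) / (0.5 * 5.5), rel=1e-12)


class TestLogistic:
    def test_single_factor_coefficient_equals_log_odds_ratio(self, rng):
        for _ in range(20):
            t = rng.integers(3, 40, size=4)
            X = np.concatenate([
                np.ones(t[0]), np.zeros(t[1]), np.ones(t[2]), np.zeros(t[3]),
            ])
            y = np.concatenate([
                np.ones(t[0] + t[1]), np.zeros(t[2] + t[3]),
            ])
            res = logistic_fit_xy(X, y)[0]
            expected = np.log((t[0] * t[3]) / (t[1] * t[2]))
            assert res.coefficient == pytest.approx(expected, abs=1e-6)

    def test_null_factor_has_near_zero_coefficient(self):
        # identical prevalence in both arms
        X = np.array([1.0, 0.0] * 200)
        y = np.array([1.0] * 200 + [0.0] * 200)
        res = logistic_fit_xy(X, y)[0]
        assert abs(res.coefficient) < 1e-6

    def test_parameter_recovery_on_simulated_cohort(self):
        X, y = simulate_logistic_cohort(2000, [1.0, 0.8, -0.9], seed=0)
        res = logistic_fit_xy(X, y)
        for r, truth in zip(res, (1.0, 0.8, -0.9)):
            assert abs(r.coefficient - truth) <= 0.15

    def test_perfect_separation_detected_and_penalized_fallback(self):
        X = np.array([1.0] * 20 + [0.0] * 20)
        y = X.copy()
        with pytest.raises(PerfectSeparationError, match="penalized"):
            logistic_fit_xy(X, y)
        res = logistic_fit_xy(X, y, penalized=True)
        assert np.isfinite(res[0].coefficient)

    def test_record_interface_codes_at_risk_levels(self, exact_cohort):
        res = logistic_fit(exact_cohort, ["age"])
        t = crosstab(exact_cohort, "age")
        assert res[0].coefficient == pytest.approx(
            np.log(odds_ratio(t)[0]), abs=1e-6
        )

    def test_too_few_outcomes_rejected(self):
        with pytest.raises(ValueError):
            logistic_fit_xy(np.ones(5), np.array([1, 0, 0, 0, 0.0]))


class TestAnalyze:
    def test_full_screen_significance_pattern(self, exact_cohort):
        results = {r.factor: r for r in analyze(exact_cohort)}
        # age, diameter, tnm, chemo associated; sex not
        for f in ("age", "diameter", "tnm", "chemo"):
            assert results[f].p_value < 0.05
        assert results["sex"].p_value > 0.05
        for r in results.values():
            assert r.ci95[0] <= r.odds_ratio <= r.ci95[1]
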