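"""Cohort statistics: count distributions, independence, enrichment, hinge fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lamincurv import (
    Channel,
    CurvatureRegime,
    RuptureRecord,
    count_distribution,
    estimate_critical_rate,
    holm_adjust,
    independence_test,
    multisite_prediction,
    regime_enrichment,
)


def cohort(n_sites_list, **kw):
    return [RuptureRecord(cell_id=f"c{i}", n_sites=n, **kw) for i, n in enumerate(n_sites_list)]


def geometric_counts(rng, n, p1):
    """Site counts under P(N >= k) = p1**k, capped at 3."""
    draws = rng.random((n, 3))
    return (np.cumprod(draws < p1, axis=1) > 0).sum(axis=1)


class TestCountDistribution:
    def test_counting_oracle(self):
        d = count_distribution(cohort([0] * 7 + [1] * 2 + [2]))
        assert d.ruptured == pytest.approx(0.3)
        assert d.one == pytest.approx(0.2)
        assert d.two == pytest.approx(0.1)
        assert d.three_plus == 0.0

    def test_all_unruptured(self):
        d = count_distribution(cohort([0] * 5))
        assert d.zero == 1.0 and d.ruptured == 0.0

    def test_all_three_plus(self):
        d = count_distribution(cohort([3, 4, 5]))
        assert d.three_plus == 1.0

    def test_fractions_sum_to_one(self, rng):
        d = count_distribution(cohort(list(rng.integers(0, 6, 57))))
        assert d.zero + d.one + d.two + d.three_plus == pytest.approx(1.0, abs=1e-12)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            count_distribution([])


class TestMultisitePrediction:
    @pytest.mark.parametrize("p1, k, expected", [(0.3, 2, 0.09), (0.3, 1, 0.3), (0.5, 3, 0.125)])
    def test_power_law(self, p1, k, expected):
        assert multisite_prediction(p1, k) == pytest.approx(expected)

    def test_domain(self):
        with pytest.raises(ValueError):
            multisite_prediction(1.2, 2)
        with pytest.raises(ValueError):
            multisite_prediction(0.5, 0)

    @settings(derandomize=True, max_examples=100)
    @given(p1=st.floats(0.0, 0.999), k=st.integers(1, 6))
    def test_recursion_and_monotonicity(self, p1, k):
        assert multisite_prediction(p1, k + 1) == pytest.approx(
            p1 * multisite_prediction(p1, k), rel=1e-12
        )
        if p1 < 1:
            assert multisite_prediction(p1, k + 1) <= multisite_prediction(p1, k)


class TestIndependenceTest:
    def test_null_cohorts_rarely_rejected(self, rng):
        """Cohorts simulated from the independence model keep p > 0.05 >= 90%."""
        p1 = 0.3
        keep = 0
        for _ in range(100):
            records = cohort(list(geometric_counts(rng, 100, p1)))
            if independence_test(records, p1).p_value > 0.05:
                keep += 1
        assert keep >= 90

    def test_extreme_misfit_rejected(self):
        # every ruptured cell jumps straight to 3+ sites: impossible under p^k
        records = cohort([0] * 70 + [3] * 30)
        res = independence_test(records, 0.3)
        assert res.p_value < 0.01

    def test_conforming_degenerate_p_zero(self):
        res = independence_test(cohort([0] * 40), 0.0)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_nonconforming_degenerate_p_zero(self):
        res = independence_test(cohort([0] * 39 + [2]), 0.0)
        assert res.p_value == 0.0

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            independence_test(cohort([0] * 10), 0.3)

    def test_large_cohort_uses_chi_square(self, rng):
        records = cohort(list(geometric_counts(rng, 1000, 0.3)))
        res = independence_test(records, 0.3)
        assert res.method == "chi_square"
        assert res.p_value > 0.001

    def test_expected_counts_follow_model(self, rng):
        records = cohort(list(geometric_counts(rng, 150, 0.5)))
        res = independence_test(records, 0.5)
        # classes {0,1,2,3+} with n=150, p=0.5: expected 75, 37.5, 18.75, 18.75
        np.testing.assert_allclose(res.expected, [75, 37.5, 18.75, 18.75])


class TestHolmAdjust:
    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        p = [0.01, 0.04, 0.03, 0.2, 0.5]
        expected = multipletests(p, method="holm")[1]
        np.testing.assert_allclose(holm_adjust(p), expected)


class TestRegimeEnrichment:
    thresholds = (0.3, 0.6)

    def test_null_sampling_gives_unit_enrichment(self, rng):
        perimeter = rng.uniform(0.0, 0.9, 20000)
        ruptures = rng.choice(perimeter, 5000)
        enr = regime_enrichment(ruptures, perimeter, self.thresholds)
        for reg in CurvatureRegime.LOW, CurvatureRegime.MEDIUM, CurvatureRegime.HIGH:
            assert enr[reg].enrichment == pytest.approx(1.0, abs=0.1)

    def test_concentrated_ruptures(self):
        perimeter = [0.1] * 90 + [0.9] * 10  # high regime occupies 10% of perimeter
        enr = regime_enrichment([0.9] * 25, perimeter, self.thresholds)
        assert enr[CurvatureRegime.HIGH].enrichment == pytest.approx(10.0)
        assert enr[CurvatureRegime.LOW].enrichment == 0.0
        assert enr[CurvatureRegime.HIGH].median_curvature == pytest.approx(0.9)

    def test_no_ruptures(self):
        enr = regime_enrichment([], [0.1, 0.5, 0.9], self.thresholds)
        assert all(e.enrichment == 0.0 for e in enr.values())

    def test_empty_regime_flagged_not_thrown(self):
        enr = regime_enrichment([0.1], [0.1, 0.2], self.thresholds)
        assert enr[CurvatureRegime.HIGH].undefined
        assert np.isnan(enr[CurvatureRegime.HIGH].enrichment)

    def test_perimeter_duplication_invariance(self, rng):
        perimeter = list(rng.uniform(0, 1, 300))
        ruptures = list(rng.uniform(0, 1, 50))
        once = regime_enrichment(ruptures, perimeter, self.thresholds)
        twice = regime_enrichment(ruptures, perimeter * 2, self.thresholds)
        for reg in once:
            assert twice[reg].enrichment == pytest.approx(once[reg].enrichment)


class TestEstimateCriticalRate:
    rates = np.linspace(0.05, 1.0, 30)

    def test_noiseless_hinge_roundtrip(self):
        phis = 1.0 * np.maximum(0.0, self.rates - 0.2)
        fit = estimate_critical_rate(np.column_stack([self.rates, phis]))
        assert fit.critical_rate == pytest.approx(0.2, abs=1e-6)
        assert fit.slope_c == pytest.approx(1.0, rel=1e-6)

    def test_proportional_data_through_origin(self):
        fit = estimate_critical_rate(
            np.column_stack([self.rates, 0.8 * self.rates]), Channel.LAMIN_B
        )
        assert fit.critical_rate == pytest.approx(0.0, abs=1e-9)
        assert fit.slope_c == pytest.approx(0.8, rel=1e-9)

    def test_noisy_recovery(self, rng):
        phis = np.maximum(0.0, self.rates - 0.2) + rng.normal(0, 0.05, len(self.rates))
        fit = estimate_critical_rate(np.column_stack([self.rates, phis]))
        assert fit.critical_rate == pytest.approx(0.2, abs=0.05)

    def test_no_dilution_flagged(self):
        fit = estimate_critical_rate(np.column_stack([self.rates, -0.01 * self.rates]))
        assert "no dilution detected" in fit.flags
        assert fit.critical_rate == pytest.approx(self.rates.max())

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            estimate_critical_rate([(0.1, 0.0), (0.2, 0.0), (0.3, 0.1)])

    def test_predict_is_zero_below_knee(self):
        phis = np.maximum(0.0, self.rates - 0.2)
        fit = estimate_critical_rate(np.column_stack([self.rates, phis]))
        assert fit.predict(0.1) == 0.0
        assert fit.predict(0.7) == pytest.approx(0.5, rel=1e-6)
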