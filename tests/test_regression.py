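import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import ribodrop as rd
from ribodrop.binning import DensityVector
from ribodrop.regression import goodness_of_fit, slope_t_test, standard_error

from conftest import brute_force_wls


def make_density(Y, weights=None, bin_size=50):
    Y = np.asarray(Y, float)
    n = len(Y)
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    return DensityVector(X=np.arange(1, n + 1), Y=Y, weights=w,
                         included=(Y > 0) & (w > 0), bin_size_nt=bin_size)


class TestFitDropoff:
    def test_noiseless_exponential_recovered_to_machine_precision(self):
        b = np.arange(1, 201)
        density = make_density(100 * np.exp(-0.01 * b))
        est = rd.fit_dropoff(density)
        assert est.r_b == pytest.approx(0.01, abs=1e-12)
        assert est.rmse == pytest.approx(0.0, abs=1e-12)
        assert est.r_squared == pytest.approx(1.0, abs=1e-12)
        assert est.A == pytest.approx(100.0, rel=1e-9)

    def test_flat_density_gives_zero_rate_and_half_p(self):
        est = rd.fit_dropoff(make_density(np.full(10, 5.0)))
        assert est.r_b == 0.0
        assert est.t_score == 0.0
        assert est.p_value == 0.5
        assert est.degenerate

    def test_fixed_7_bin_fixture_matches_normal_equations_oracle(self):
        Y = np.array([8.1, 6.6, 5.9, 4.4, 4.1, 3.0, 2.9])
        w = np.array([1.0, 1.0, 0.9, 0.8, 0.5, 0.3, 0.2])
        density = make_density(Y, w)
        est = rd.fit_dropoff(density)
        slope, intercept = brute_force_wls(density.X, np.log(Y), w)
        assert est.r_b == pytest.approx(-slope, rel=1e-12)
        assert est.A == pytest.approx(np.exp(intercept), rel=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(3, 10).flatmap(lambda n: st.tuples(
        st.lists(st.floats(0.05, 1e4), min_size=n, max_size=n),
        st.lists(st.floats(0.01, 1.0), min_size=n, max_size=n))))
    def test_oracle_equivalence_on_small_inputs(self, data):
        Y, w = np.array(data[0]), np.array(data[1])
        density = make_density(Y, w)
        slope, _ = brute_force_wls(density.X, np.log(Y), w)
        est = rd.fit_dropoff(density)
        assert est.r_b == pytest.approx(-slope, rel=1e-10, abs=1e-12)

    def test_fewer_than_three_bins_fatal(self):
        with pytest.raises(ValueError, match=">= 3 usable bins"):
            rd.fit_dropoff(make_density([1.0, 2.0]))

    def test_excluded_bins_do_not_influence_fit(self):
        b = np.arange(1, 31)
        Y = 10 * np.exp(-0.02 * b)
        density = make_density(Y)
        corrupted = Y.copy()
        corrupted[5] = 500.0     # a spike in a bin we then exclude
        d2 = make_density(corrupted)
        d2.included[5] = False
        est = rd.fit_dropoff(d2)
        # slope still reflects the clean decay, not the excluded spike
        assert est.r_b == pytest.approx(0.02, abs=1e-10)


class TestStandardError:
    def test_perfect_fit_gives_zero(self):
        assert standard_error(np.zeros(5), np.arange(5.0)) == 0.0

    def test_textbook_ols_example(self):
        # y = 1,2,2,3 at x = 1..4: slope 0.6, residuals from the OLS line
        x = np.array([1.0, 2, 3, 4])
        y = np.array([1.0, 2, 2, 3])
        slope, intercept = brute_force_wls(x, y, np.ones(4))
        resid = y - (intercept + slope * x)
        expected = np.sqrt((resid ** 2).sum() / 2) / np.sqrt(((x - x.mean()) ** 2).sum())
        assert standard_error(resid, x) == pytest.approx(expected, rel=1e-12)

    def test_equal_weights_reduce_to_unweighted(self):
        rng = np.random.default_rng(0)
        x = np.arange(10.0)
        resid = rng.normal(size=10)
        for c in (0.2, 1.0, 7.0):
            assert standard_error(resid, x, np.full(10, c)) == pytest.approx(
                standard_error(resid, x), rel=1e-12)

    def test_degenerate_design_fatal(self):
        with pytest.raises(ValueError, match="x-variance"):
            standard_error(np.zeros(4), np.full(4, 2.0))


class TestConfidenceInterval:
    def test_zero_se_collapses_interval(self):
        margin, ci = rd.confidence_interval(0.01, 0.0, 50)
        assert margin == 0.0
        assert ci == (0.01, 0.01)

    def test_critical_value_matches_t_table(self):
        # t(100) upper 0.975 quantile from a standard table
        margin, _ = rd.confidence_interval(0.0, 1.0, 102, alpha=0.05)
        assert margin == pytest.approx(1.984, abs=5e-4)

    def test_normal_limit(self):
        margin, _ = rd.confidence_interval(0.0, 1.0, 100_000, alpha=0.05)
        assert margin == pytest.approx(1.96, rel=5e-3)

    def test_interval_centred_on_estimate(self):
        margin, ci = rd.confidence_interval(0.0073, 0.0003, 120)
        assert ci[0] == pytest.approx(0.0073 - margin)
        assert ci[1] == pytest.approx(0.0073 + margin)


class TestSlopeTTest:
    def test_strong_decay_is_significant_for_realistic_bin_counts(self):
        # a rate 8.5 standard errors above zero is overwhelming evidence
        for n in (11, 20, 50, 100, 200, 400, 1000):
            t, p = slope_t_test(0.0051, 0.0006, n)
            assert t == pytest.approx(8.5)
            assert p < 1e-5

    def test_zero_rate_gives_half(self):
        assert slope_t_test(0.0, 0.001, 20) == (0.0, 0.5)

    def test_moderate_decay_upper_tail(self):
        # t = 0.0057/0.0021 = 2.714; the upper tail at large N approaches
        # the normal value ~0.0033
        t, p = slope_t_test(0.0057, 0.0021, 5000)
        assert p == pytest.approx(stats.norm.sf(0.0057 / 0.0021), rel=1e-2)
        assert 0.003 < p < 0.004

    def test_degenerate_perfect_fit_reports_zero_p(self):
        t, p = slope_t_test(0.01, 0.0, 20)
        assert np.isinf(t) and p == 0.0


class TestGoodnessOfFit:
    def test_perfect_fit(self):
        y = np.array([1.0, 2, 3, 4])
        rmse, r2 = goodness_of_fit(y, y)
        assert rmse == 0.0 and r2 == 1.0

    def test_mean_only_model_has_zero_r2(self):
        y = np.array([1.0, 2, 3, 4])
        rmse, r2 = goodness_of_fit(y, np.full(4, y.mean()))
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_five_point_fixture_matches_direct_arithmetic(self):
        y = np.array([0.1, 0.5, 0.2, 0.9, 0.4])
        yhat = np.array([0.2, 0.4, 0.3, 0.8, 0.5])
        w = np.array([1.0, 0.5, 1.0, 0.25, 1.0])
        rmse, r2 = goodness_of_fit(y, yhat, w)
        assert rmse == pytest.approx(np.sqrt(np.mean((y - yhat) ** 2)), rel=1e-12)
        ybar = (w * y).sum() / w.sum()
        expected_r2 = 1 - (w * (y - yhat) ** 2).sum() / (w * (y - ybar) ** 2).sum()
        assert r2 == pytest.approx(expected_r2, rel=1e-12)


class TestPerCodonRate:
    @pytest.mark.parametrize("r_b,expected", [
        (0.0051, 0.0003), (0.0102, 0.0006), (0.0073, 0.0004), (0.0, 0.0),
    ])
    def test_published_conversions_at_bin_50(self, r_b, expected):
        assert round(rd.per_codon_rate(r_b, 50), 4) == expected

    def test_rate_at_or_above_one_fatal(self):
        with pytest.raises(ValueError):
            rd.per_codon_rate(1.0, 50)

    @settings(derandomize=True, max_examples=100)
    @given(r_b=st.floats(1e-6, 0.99), bin_size=st.integers(3, 300))
    def test_inverse_consistency(self, r_b, bin_size):
        r_c = rd.per_codon_rate(r_b, bin_size)
        back = 1 - (1 - r_c) ** (bin_size / 3)
        assert back == pytest.approx(r_b, abs=1e-12, rel=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(r_b=st.floats(1e-4, 0.9), bin_size=st.integers(4, 300))
    def test_monotone_in_rate_and_bin_size(self, r_b, bin_size):
        assert rd.per_codon_rate(r_b * 1.05, bin_size) > rd.per_codon_rate(r_b, bin_size)
        assert rd.per_codon_rate(r_b, bin_size - 1) > rd.per_codon_rate(r_b, bin_size)


def _estimate(r_b, se, n=100):
    return rd.DropoffEstimate(
        r_b=r_b, r_c=rd.per_codon_rate(r_b, 50), A=1.0, bin_size_nt=50, se=se,
        margin_of_error=0.0, ci=(r_b, r_b), t_score=0.0, p_value=0.5,
        rmse=0.0, r_squared=0.0, n_bins_used=n)


class TestWelchCompare:
    def test_statistic_definition_is_exact(self):
        res = rd.welch_compare(_estimate(0.0057, 0.0021), _estimate(0.0079, 0.0027))
        expected_t = (0.0057 - 0.0079) / np.sqrt(0.0021 ** 2 + 0.0027 ** 2)
        assert res.t_score == pytest.approx(expected_t, rel=1e-12)
        assert res.t_score == pytest.approx(-0.643, abs=5e-4)
        assert res.p_value == pytest.approx(0.2602, abs=1e-3)

    def test_second_published_pair(self):
        res = rd.welch_compare(_estimate(0.0053, 0.0019), _estimate(0.0077, 0.0027))
        assert res.p_value == pytest.approx(0.2338, abs=1e-3)

    def test_identical_estimates(self):
        res = rd.welch_compare(_estimate(0.005, 0.001), _estimate(0.005, 0.001),
                               tail="two_sided")
        assert res.t_score == 0.0 and res.p_value == 1.0

    def test_large_effect_is_significant(self):
        res = rd.welch_compare(_estimate(0.01, 0.001), _estimate(0.002, 0.001))
        assert res.p_value < 0.001

    def test_two_sided_doubles_one_sided(self):
        one = rd.welch_compare(_estimate(0.006, 0.002), _estimate(0.004, 0.002))
        two = rd.welch_compare(_estimate(0.006, 0.002), _estimate(0.004, 0.002),
                               tail="two_sided")
        assert two.p_value == pytest.approx(2 * one.p_value)

    def test_zero_se_rejected(self):
        with pytest.raises(ValueError):
            rd.welch_compare(_estimate(0.01, 0.0), _estimate(0.01, 0.001))


class TestSurvivalProbability:
    def test_short_cds_worked_example(self):
        assert round(rd.survival_probability(1e-4, 100), 2) == 0.99

    def test_longest_cds_worked_example(self):
        # (1 - 1e-4)^4911 = 0.61194
        assert rd.survival_probability(1e-4, 4911) == pytest.approx(0.6119, abs=5e-4)

    def test_no_dropoff_means_certain_arrival(self):
        assert rd.survival_probability(0.0, 12345) == 1.0

    @settings(derandomize=True, max_examples=100)
    @given(r_c=st.floats(1e-8, 1e-3), L=st.integers(1, 10_000))
    def test_exponential_mode_within_taylor_bound(self, r_c, L):
        exact = rd.survival_probability(r_c, L, mode="exact")
        approx = rd.survival_probability(r_c, L, mode="exponential")
        # L * 1e-15 covers the rounding of the float power itself
        assert abs(exact - approx) <= r_c ** 2 * L + L * 1e-15
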