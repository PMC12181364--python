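"""Spearman correlation, Bland-Altman workflow, and Shieh's exact agreement test."""

import numpy as np
import pytest
from scipy import stats as sps

from sweclip.agreement import (PairedSeries, bland_altman, compare_methods,
                               proportional_bias_regression, shieh_agreement_test,
                               spearman_correlation)


def paired(a, b, unit="kPa"):
    return PairedSeries(np.asarray(a, dtype=float), np.asarray(b, dtype=float), unit)


class TestSpearman:
    def test_perfect_monotone(self):
        a = np.array([1.0, 2.0, 5.0, 9.0])
        rho, p = spearman_correlation(paired(a, np.exp(a)))
        assert rho == 1.0
        rho_dec, _ = spearman_correlation(paired(a, -a))
        assert rho_dec == -1.0

    def test_tied_ranks_hand_value(self):
        rho, _ = spearman_correlation(paired([1, 2, 2, 3], [1, 3, 2, 4]))
        assert rho == pytest.approx(0.948683, abs=1e-6)

    def test_exact_permutation_p_small_n(self):
        # for n=4 and a perfect ordering: 2 of 24 permutations reach |rho|=1
        rho, p = spearman_correlation(paired([1, 2, 3, 4], [2, 4, 6, 9]))
        assert rho == 1.0
        assert p == pytest.approx(2 / 24)

    def test_t_approximation_matches_scipy_large_n(self, rng):
        a = rng.normal(size=40)
        b = a + rng.normal(scale=0.7, size=40)
        rho, p = spearman_correlation(paired(a, b))
        rho_sp, p_sp = sps.spearmanr(a, b)
        assert rho == pytest.approx(rho_sp, abs=1e-12)
        assert p == pytest.approx(p_sp, rel=1e-6)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            spearman_correlation(paired([1, 1, 1, 1], [1, 2, 3, 4]))


class TestBlandAltman:
    def test_constant_offset(self):
        res = bland_altman(paired([1, 2, 3], [3, 4, 5]))
        assert res.bias == -2.0
        assert res.sd_diff == 0.0
        assert res.loa == (-2.0, -2.0)
        assert res.pct_within == 100.0
        assert res.reg_slope is None  # regression undefined at sd = 0

    def test_three_point_hand_example(self):
        # differences (-1, 0, 1): bias 0, sd 1, LoA +-1.96, t-CI +-4.3027/sqrt(3)
        res = bland_altman(paired([0, 2, 4], [1, 2, 3]))
        assert res.bias == 0.0
        assert res.sd_diff == pytest.approx(1.0)
        assert res.loa == (pytest.approx(-1.96), pytest.approx(1.96))
        assert res.loa_width == pytest.approx(2 * 1.96)
        assert res.bias_ci[0] == pytest.approx(-2.4841377, abs=1e-6)
        assert res.bias_ci[1] == pytest.approx(2.4841377, abs=1e-6)

    def test_coverage_of_loa_on_normal_differences(self, rng):
        b = rng.normal(50, 5, size=10_000)
        d = rng.normal(0, 1, size=10_000)
        res = bland_altman(paired(b + d, b))
        assert 94.5 <= res.pct_within <= 95.5

    def test_log_branch_equals_raw_on_logged_inputs(self, rng):
        a = rng.lognormal(3.0, 0.3, size=30)
        b = a * rng.lognormal(0.02, 0.05, size=30)
        res_log = bland_altman(paired(a, b), log_transform=True)
        res_manual = bland_altman(paired(np.log(a), np.log(b)))
        assert res_log.bias == pytest.approx(res_manual.bias, rel=1e-12)
        assert res_log.loa == pytest.approx(res_manual.loa, rel=1e-12)
        assert res_log.log_transformed

    def test_log_requires_positive(self):
        with pytest.raises(ValueError, match="positive"):
            bland_altman(paired([1, 2, 3], [0, 1, 2]), log_transform=True)

    def test_loa_width_identity(self, rng):
        a = rng.normal(30, 4, 25)
        b = a + rng.normal(1, 2, 25)
        res = bland_altman(paired(a, b))
        assert res.loa_width == pytest.approx(2 * 1.96 * res.sd_diff, rel=1e-12)
        assert res.loa[0] <= res.bias <= res.loa[1]
        assert res.bias_ci[0] <= res.bias <= res.bias_ci[1]


class TestProportionalBias:
    def test_closed_form_three_points(self):
        res = proportional_bias_regression([1, 2, 3], [1, 3, 2])
        assert res.slope == pytest.approx(0.5)
        assert res.intercept == pytest.approx(1.0)

    def test_perfect_proportional_fit(self):
        means = np.array([1.0, 2.0, 3.0, 4.0])
        res = proportional_bias_regression(means, 0.1 * means)
        assert res.slope == pytest.approx(0.1)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.p == 0.0 and res.exact_fit

    def test_constant_differences(self):
        res = proportional_bias_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert res.slope == 0.0 and res.F == 0.0 and res.p == 1.0

    def test_constant_means_error(self):
        with pytest.raises(ValueError):
            proportional_bias_regression([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_slope_recovery_under_noise(self, rng):
        means = rng.uniform(10, 60, 200)
        diffs = -1.75 + 0.063 * means + rng.normal(0, 0.5, 200)
        res = proportional_bias_regression(means, diffs)
        assert res.slope == pytest.approx(0.063, abs=0.015)
        assert res.p < 1e-6


class TestShieh:
    def test_tight_differences_interchangeable(self, rng):
        d = rng.normal(0, 0.1, size=50)
        res = shieh_agreement_test(d, (-1.0, 1.0), alpha=0.05)
        assert res.reject_h0
        assert res.bound_low <= res.bound_high
        # same data against margins narrower than the population LoA
        res2 = shieh_agreement_test(d, (-0.05, 0.05), alpha=0.05)
        assert not res2.reject_h0

    def test_asymptotic_bounds_reach_population_range(self, rng):
        d = rng.normal(0.0, 1.0, size=100_000)
        res = shieh_agreement_test(d, (-3.0, 3.0))
        assert res.bound_low == pytest.approx(-1.959964, abs=0.02)
        assert res.bound_high == pytest.approx(1.959964, abs=0.02)

    def test_bounds_match_parametric_bootstrap(self, rng):
        """Exact noncentral-t bounds agree with a simulated quantile oracle."""
        n = 50
        gamma = sps.norm.ppf(0.975)
        draws = rng.standard_normal((100_000, n))
        t_stat = (draws.mean(axis=1) + gamma) / (draws.std(axis=1, ddof=1) / np.sqrt(n))
        q_boot = np.quantile(t_stat, 0.95)
        d = rng.normal(0.3, 1.2, size=n)
        res = shieh_agreement_test(d, (-5.0, 5.0))
        boot_high = d.mean() + q_boot * d.std(ddof=1) / np.sqrt(n)
        assert abs(res.bound_high - boot_high) <= 0.01 * d.std(ddof=1)

    def test_degenerate_zero_sd(self):
        res = shieh_agreement_test([0.5, 0.5, 0.5, 0.5], (-1.0, 1.0))
        assert res.bound_low == res.bound_high == 0.5
        assert res.reject_h0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            shieh_agreement_test([0.0, 0.1], (-1, 1))
        with pytest.raises(ValueError):
            shieh_agreement_test([0.0, 0.1, 0.2], (1, -1))
        with pytest.raises(ValueError):
            shieh_agreement_test([0.0, 0.1, 0.2], (-1, 1), alpha=0.6)


class TestCompareMethods:
    def test_self_agreement(self):
        import pandas as pd
        s = pd.Series([10.0, 20.0, 30.0, 40.0], index=list("abcd"))
        rep = compare_methods(s, s, delta=(-1.0, 1.0))
        assert rep.spearman_rho == 1.0
        assert rep.bland_altman_raw.bias == 0.0
        assert rep.bland_altman_raw.loa == (0.0, 0.0)
        assert rep.shieh_raw.reject_h0

    def test_known_bias_recovered(self, rng):
        """Paired data with the geometry of a typical validation study: the
        fitted bias lands within 2 SEM of the generating offset."""
        import pandas as pd
        n, bias, sd = 206, 0.747, 2.208
        b = rng.uniform(10, 80, size=n)
        a = b + rng.normal(bias, sd, size=n)
        idx = [f"clip{i:03d}" for i in range(n)]
        rep = compare_methods(pd.Series(a, index=idx), pd.Series(b, index=idx))
        assert rep.bland_altman_raw.bias == pytest.approx(bias, abs=2 * sd / np.sqrt(n))
        assert rep.bland_altman_raw.loa_width == pytest.approx(
            2 * 1.96 * rep.bland_altman_raw.sd_diff)

    def test_unmatched_ids_warn_and_exclude(self):
        import pandas as pd
        a = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        b = pd.Series([1.0, 2.0, 3.0, 9.0], index=list("abce"))
        with pytest.warns(UserWarning, match="unmatched"):
            rep = compare_methods(a, b)
        assert rep.n == 3
        assert rep.unmatched_a == ["d"] and rep.unmatched_b == ["e"]

    def test_mismatched_lengths_error(self):
        with pytest.raises(ValueError):
            compare_methods(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0]))

    def test_report_serializes(self, rng):
        import json
        import pandas as pd
        idx = list("abcdef")
        a = pd.Series(rng.uniform(10, 50, 6), index=idx)
        b = a * 1.02
        rep = compare_methods(a, b, delta=(-5, 5), delta_log=(-0.2, 0.2))
        json.dumps(rep.to_dict())  # must be JSON-ready
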