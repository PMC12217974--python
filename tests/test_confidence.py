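"""F-distribution chi-square threshold and profile-likelihood limits."""

import numpy as np
import pytest
from scipy import special

import turnofit as tf


def f_quantile_by_beta_inversion(level, d1, d2):
    """Independent F quantile: bisection on the regularized incomplete
    beta form of the F CDF, avoiding the library quantile routine."""
    def cdf(x):
        return special.betainc(d1 / 2.0, d2 / 2.0, d1 * x / (d1 * x + d2))
    lo, hi = 0.0, 1e6
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if cdf(mid) < level:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestChi2Threshold:
    def test_matches_f_quantile_oracle(self):
        # chi2_min 100, 62 points, 2 free parameters, level 0.99
        f99 = f_quantile_by_beta_inversion(0.99, 2, 60)
        expected = 100.0 * (1.0 + (2.0 / 60.0) * f99)
        assert tf.chi2_threshold(100.0, 62, 2, 0.99) == pytest.approx(
            expected, rel=1e-6)

    def test_tends_to_chi2_min_as_level_vanishes(self):
        for level in (1e-3, 1e-6, 1e-9):
            t = tf.chi2_threshold(50.0, 30, 2, level)
            assert t >= 50.0
            assert t == pytest.approx(50.0, rel=10 * np.sqrt(level))

    def test_strictly_increasing_in_level(self):
        levels = np.linspace(0.05, 0.999, 25)
        thresholds = [tf.chi2_threshold(100.0, 62, 2, lv) for lv in levels]
        assert np.all(np.diff(thresholds) > 0)

    @pytest.mark.parametrize("n, p, level",
                             [(5, 5, 0.99), (5, 0, 0.99), (10, 2, 1.5)])
    def test_invalid_degrees_of_freedom_or_level(self, n, p, level):
        with pytest.raises(ValueError):
            tf.chi2_threshold(10.0, n, p, level)


class TestLimitsFromProfile:
    def _profile(self, grid, chi2, threshold, chi2_min=None):
        return tf.ConfidenceProfile(
            parameter="k_rel", grid=grid, chi2=chi2,
            chi2_min=chi2_min if chi2_min is not None else float(np.min(chi2)),
            threshold=threshold, lower=None, upper=None)

    def test_quadratic_profile_closed_form(self):
        # chi2(theta) = chi2_min + c (log10 theta - log10 theta_hat)^2
        # crosses T at log10 theta_hat +/- sqrt((T - chi2_min)/c)
        grid = np.logspace(-2.5, 0.5, 31)
        c, chi2_min, T, log_hat = 40.0, 12.0, 19.0, -1.0
        chi2 = chi2_min + c * (np.log10(grid) - log_hat) ** 2
        lower, upper = tf.limits_from_profile(self._profile(grid, chi2, T), T)
        half = np.sqrt((T - chi2_min) / c)
        assert np.log10(lower) == pytest.approx(log_hat - half, abs=1e-3)
        assert np.log10(upper) == pytest.approx(log_hat + half, abs=1e-3)

    def test_single_point_below_threshold(self):
        grid = np.logspace(-1, 1, 11)
        chi2 = np.full(11, 100.0)
        chi2[5] = 1.0
        lower, upper = tf.limits_from_profile(
            self._profile(grid, chi2, 5.0), 5.0)
        assert lower is not None and upper is not None
        assert lower <= grid[5] <= upper
        assert grid[4] < lower and upper < grid[6]

    def test_monotone_profile_has_unbounded_upper(self):
        grid = np.logspace(-1, 1, 11)
        chi2 = np.linspace(1.0, 4.0, 11)  # never reaches the threshold
        lower, upper = tf.limits_from_profile(
            self._profile(grid, chi2, 10.0), 10.0)
        assert upper is None

    def test_too_few_points_rejected(self):
        prof = self._profile(np.array([0.1, 1.0]), np.array([1.0, 2.0]), 5.0)
        with pytest.raises(ValueError):
            tf.limits_from_profile(prof, 5.0)


class TestProfileParameter:
    @pytest.fixture(scope="class")
    def mm2_profile(self, mm2, mm2_noisy, mm2_fit):
        return tf.profile_parameter([mm2_noisy], ("k_cat", "k_rel"),
                                    mm2_fit, "k_rel")

    def test_profile_minimum_at_global_estimate(self, mm2_fit, mm2_profile):
        assert np.nanmin(mm2_profile.chi2) == pytest.approx(
            mm2_fit.chi2_min, abs=1e-6 * (1.0 + mm2_fit.chi2_min))
        i_min = np.nanargmin(mm2_profile.chi2)
        est = mm2_fit.estimates.k_rel
        # minimum within one grid step of the estimate
        step = np.diff(np.log10(mm2_profile.grid)).max()
        assert abs(np.log10(mm2_profile.grid[i_min]) - np.log10(est)) <= step

    def test_profile_chi2_never_below_minimum(self, mm2_fit, mm2_profile):
        ok = np.isfinite(mm2_profile.chi2)
        assert np.all(mm2_profile.chi2[ok] >= mm2_fit.chi2_min - 1e-6)

    def test_limits_bracket_generating_value(self, mm2_profile):
        # coverage spot-check against the generator truth k_rel = 0.053
        assert mm2_profile.lower is not None
        assert mm2_profile.upper is not None
        assert mm2_profile.lower <= 0.053 <= mm2_profile.upper

    def test_interval_width_nondecreasing_in_level(self, mm2, mm2_noisy,
                                                   mm2_fit, mm2_profile):
        widths = []
        for level in (0.5, 0.9, 0.99):
            t = tf.chi2_threshold(mm2_fit.chi2_min, mm2_fit.n_points,
                                  mm2_fit.n_free, level)
            lo, hi = tf.limits_from_profile(mm2_profile, t)
            assert lo is not None and hi is not None
            widths.append(np.log10(hi) - np.log10(lo))
        assert np.all(np.diff(widths) >= -1e-12)

    def test_noise_free_profile_rises_monotonically_from_truth(self, mm2):
        rates, design = mm2
        model = tf.observed_product(tf.simulate(rates, design))
        ds = tf.TimecourseDataset("2mm", design.timepoints, model,
                                  sigma=np.full_like(model, 0.5),
                                  design=design)
        fit = tf.fit_global([ds], float_params=("k_cat", "k_rel"),
                            init=rates, n_starts=1)
        grid = 0.053 * np.logspace(-0.6, 0.6, 9)
        prof = tf.profile_parameter([ds], ("k_cat", "k_rel"), fit, "k_rel",
                                    grid=grid)
        i_min = np.nanargmin(prof.chi2)
        assert np.all(np.diff(prof.chi2[i_min:]) > -1e-9)
        assert np.all(np.diff(prof.chi2[:i_min + 1]) < 1e-9)

    def test_interval_shrinks_with_noise(self, mm2, mm2_profile):
        # a five-fold quieter dataset gives a tighter interval than the
        # default-noise one (collapse toward the truth as noise -> 0)
        rates, design = mm2
        quiet = tf.generate_timecourse(rates, design,
                                       tf.NoiseModel(0.1, 0.004, seed=1),
                                       condition="2mm")
        fit = tf.fit_global([quiet], float_params=("k_cat", "k_rel"),
                            init=rates, n_starts=1)
        prof = tf.profile_parameter([quiet], ("k_cat", "k_rel"), fit,
                                    "k_rel")
        assert prof.lower is not None and prof.upper is not None
        width_quiet = np.log10(prof.upper) - np.log10(prof.lower)
        width_default = (np.log10(mm2_profile.upper)
                         - np.log10(mm2_profile.lower))
        assert width_quiet < width_default

    def test_profiled_parameter_must_float(self, mm2_noisy, mm2_fit):
        with pytest.raises(ValueError):
            tf.profile_parameter([mm2_noisy], ("k_cat", "k_rel"), mm2_fit,
                                 "k_on")
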