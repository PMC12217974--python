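"""Profile-likelihood confidence limits for fitted rate constants.

One rate constant is held fixed at each point of a grid spanning the
global estimate while all other floating constants are re-fit; the
resulting chi-square profile is compared against a threshold derived
from the F-distribution,

    threshold = chi2_min * (1 + (p / (n - p)) * F_level(p, n - p)),

with n data points and p floating parameters.  The grid values whose
profile chi-square crosses the threshold give the lower and upper
confidence limits (interpolated in log parameter space); a side whose
profile never crosses within the grid is reported as unbounded (None).

The reported limits correspond to the confidence ``level`` passed to the
threshold.  The convention followed here labels limits by the F-quantile
level directly (default 0.99); whether such a threshold is read as "99%"
or, more loosely, "95% confidence limits" varies in the kinetics
literature, so the level is always an explicit argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fitting import FitResult, fit_global

__all__ = [
    "ConfidenceProfile",
    "chi2_threshold",
    "profile_parameter",
    "limits_from_profile",
]


@dataclass(frozen=True)
class ConfidenceProfile:
    """Chi-square profile of one rate constant.

    ``grid`` holds the fixed parameter values, ``chi2`` the re-optimised
    chi-square at each (NaN where a refit failed).  ``lower``/``upper``
    are the threshold crossings, or None where the profile never crosses
    inside the grid (unbounded).
    """

    parameter: str
    grid: np.ndarray
    chi2: np.ndarray
    chi2_min: float
    threshold: float
    lower: float | None
    upper: float | None

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        c = np.asarray(self.chi2, dtype=float)
        if g.shape != c.shape or g.ndim != 1:
            raise ValueError("grid and chi2 must be 1-D arrays of equal length")
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "chi2", c)


def chi2_threshold(chi2_min: float, n_points: int, n_free: int,
                   level: float = 0.99) -> float:
    """F-distribution chi-square threshold for confidence contours.

    Monotonically increasing in ``level`` and tending to ``chi2_min`` as
    level -> 0.
    """
    if n_free < 1 or n_points <= n_free:
        raise ValueError("need n_points > n_free >= 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if chi2_min < 0:
        raise ValueError("chi2_min must be >= 0")
    dof = n_points - n_free
    f_quantile = stats.f.ppf(level, n_free, dof)
    return chi2_min * (1.0 + (n_free / dof) * f_quantile)


def _default_grid(center: float, n_grid: int, span_decades: float) -> np.ndarray:
    log_c = np.log10(center)
    return np.logspace(log_c - span_decades, log_c + span_decades, n_grid)


def _profile_chi2(datasets, other_floats, name, grid, best: FitResult,
                  bounds, max_nfev):
    """Walk the grid outward from the estimate, warm-starting each refit."""
    center_idx = int(np.argmin(np.abs(np.log10(grid)
                                      - np.log10(getattr(best.estimates, name)))))
    chi2 = np.full(grid.size, np.nan)

    def refit(fixed_value, warm):
        init = warm.replace(**{name: float(fixed_value)})
        res = fit_global(
            datasets, float_params=other_floats, init=init, bounds=bounds,
            n_starts=1, max_nfev=max_nfev,
        )
        return res.chi2_min, res.estimates

    for indices in (range(center_idx, grid.size), range(center_idx - 1, -1, -1)):
        warm = best.estimates
        for i in indices:
            try:
                chi2[i], warm = refit(grid[i], warm)
            except Exception:
                pass  # failed grid point stays NaN; profiling continues
    return chi2


def profile_parameter(
    datasets,
    float_params,
    best: FitResult,
    name: str,
    grid=None,
    n_grid: int = 21,
    span_decades: float = 1.5,
    level: float = 0.99,
    bounds=None,
    max_nfev: int | None = None,
) -> ConfidenceProfile:
    """Profile one floating rate constant and locate its confidence limits.

    At each grid value ``name`` is locked there and the remaining
    ``float_params`` are re-fit, warm-started from the neighbouring grid
    point.  The default grid is 21 points log-spaced over +/-1.5 decades
    around the global estimate, extended once by the same span on a side
    whose threshold crossing falls in the outer 10% of the grid (so a
    wide interval is not an artefact of grid truncation).
    """
    float_params = tuple(float_params)
    if name not in float_params:
        raise ValueError(f"{name!r} is not a floating parameter of this fit")
    other_floats = tuple(p for p in float_params if p != name)
    if not other_floats:
        raise ValueError("profiling needs at least one other floating parameter")
    if bounds is None:
        from .fitting import DEFAULT_BOUNDS
        bounds = DEFAULT_BOUNDS

    estimate = getattr(best.estimates, name)
    if grid is None:
        grid = _default_grid(estimate, n_grid, span_decades)
        refinable = True
    else:
        grid = np.sort(np.asarray(grid, dtype=float))
        refinable = False
    if grid.size < 3:
        raise ValueError("profile grid needs at least 3 points")

    threshold = chi2_threshold(best.chi2_min, best.n_points, best.n_free, level)
    chi2 = _profile_chi2(datasets, other_floats, name, grid, best, bounds,
                         max_nfev)
    lower, upper = _crossings(grid, chi2, threshold)

    if refinable:
        log_g = np.log10(grid)
        span = log_g[-1] - log_g[0]
        extend_lo = lower is not None and np.log10(lower) < log_g[0] + 0.1 * span
        extend_hi = upper is not None and np.log10(upper) > log_g[-1] - 0.1 * span
        if extend_lo or extend_hi:
            lo_d = span_decades + (span_decades if extend_lo else 0.0)
            hi_d = span_decades + (span_decades if extend_hi else 0.0)
            n_extra = n_grid + (n_grid // 2) * (int(extend_lo) + int(extend_hi))
            grid = np.logspace(np.log10(estimate) - lo_d,
                               np.log10(estimate) + hi_d, n_extra)
            chi2 = _profile_chi2(datasets, other_floats, name, grid, best,
                                 bounds, max_nfev)
            lower, upper = _crossings(grid, chi2, threshold)

    return ConfidenceProfile(
        parameter=name, grid=grid, chi2=chi2, chi2_min=best.chi2_min,
        threshold=threshold, lower=lower, upper=upper,
    )


def _crossings(grid, chi2, threshold):
    """Threshold crossings, interpolated in log10(parameter).

    Interpolation is linear in sqrt(chi2 - chi2_grid_min) rather than in
    chi2 itself: near its minimum the profile is locally quadratic in
    log-parameter, so the square root is locally linear and the crossing
    is recovered exactly for a quadratic profile even on a coarse grid
    (plain linear interpolation of a quadratic severely underestimates
    the crossing distance).
    """
    valid = np.isfinite(chi2)
    if not np.any(valid):
        return None, None
    below = valid & (chi2 <= threshold)
    if not np.any(below):
        return None, None
    inside = np.flatnonzero(below)
    first, last = inside[0], inside[-1]
    log_g = np.log10(grid)
    ref = np.nanmin(np.where(valid, chi2, np.nan))
    root = np.sqrt(np.maximum(chi2 - ref, 0.0))
    root_t = np.sqrt(max(threshold - ref, 0.0))

    def interp(i_out, i_in):
        r_out, r_in = root[i_out], root[i_in]
        if not np.isfinite(r_out) or r_out == r_in:
            return float(grid[i_in])
        frac = (root_t - r_in) / (r_out - r_in)
        return float(10.0 ** (log_g[i_in] + frac * (log_g[i_out] - log_g[i_in])))

    lower = None if first == 0 else interp(first - 1, first)
    upper = None if last == grid.size - 1 else interp(last + 1, last)
    return lower, upper


def limits_from_profile(profile: ConfidenceProfile,
                        threshold: float | None = None):
    """Lower/upper threshold crossings of a profile (None = unbounded)."""
    if profile.grid.size < 3:
        raise ValueError("profile needs at least 3 points")
    if threshold is None:
        threshold = profile.threshold
    return _crossings(profile.grid, profile.chi2, threshold)
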