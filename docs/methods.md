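# Methods

## The turnover model

The package models one catalytic cycle of an RNA-guided nuclease as

    E + S <=> ES -> EP <=> E + P

with mass-action kinetics over five species (E free enzyme, S substrate,
ES pre-cleavage complex, EP product-bound complex, P released product)
and five rate constants:

| constant   | step            | units        | preset default | why |
|------------|-----------------|--------------|----------------|-----|
| `k_on`     | E + S -> ES     | nM⁻¹ min⁻¹   | 1              | binding is not resolved by turnover data; only the ratio matters |
| `k_off`    | ES -> E + S     | min⁻¹        | 1              | locked with `k_on` to give a binding Kd of 1 nM |
| `k_cat`    | ES -> EP        | min⁻¹        | per condition  | cleavage; 60 min⁻¹ for the full-length guide is locked because it is too fast for the sampling used |
| `k_rel`    | EP -> E + P     | min⁻¹        | per condition  | product release; the constant that distinguishes the guide conditions |
| `k_rebind` | E + P -> EP     | nM⁻¹ min⁻¹   | 1 (= `k_on`)   | product rebinding; see below |

Assumptions: a single cleavage step converts substrate to product (no
nicked intermediate is modelled), the enzyme is not consumed, and both
conservation laws (total enzyme E+ES+EP, total DNA S+ES+EP+P) hold
exactly in the rate law. The observable is EP + P — the quench
deproteinises the samples, so gels report enzyme-bound and released
product together.

**Product rebinding.** The reverse of the release step has no published
value. The default sets `k_rebind = k_on`: binding of cut and uncut DNA
is taken to be limited by the same diffusional encounter, so the release
constant alone sets the product-binding equilibrium. This is the
mechanism by which accumulating product sequesters enzyme (as EP) and
slows turnover late in the reaction. `k_rebind` is an ordinary
parameter: it can be floated, bounded, or profiled with
`profile_parameter` to measure how sensitive any fit is to this choice.

**Locked binding.** When the binding step is locked, both `k_on` and
`k_off` are held, which pins the ratio Kd = 1 nM. Different absolute
values with the same ratio change the timecourses only on time scales
shorter than the first sampling interval.

## Simulation

`simulate` integrates the five-species system with SciPy's LSODA
(stiff-switching) using an analytic Jacobian, relative tolerance 1e-8
and absolute tolerance 1e-10 nM. The full-length-guide preset is stiff
— cleavage at 60 min⁻¹ against release at 0.00085 min⁻¹ is ~4.8 decades
of separation — and integrates without step failure over 0–360 min.
Concentrations within roundoff below zero are clipped to zero; larger
undershoot, solver failure, or conservation drift above 1e-6 relative
raises an error naming the failing time rather than returning a
trajectory that cannot be trusted.

## Synthetic data

`generate_timecourse` emulates the turnover assay: 20 nM active enzyme,
100 nM substrate (5:1 excess), sampled on a grid with dense early points
(0, 0.02, 0.05, 0.1, 0.2, 0.5, 1, 2 min — these make the burst amplitude
and `k_cat` identifiable) and 15-min spacing out to 360 min (these
constrain the slow release phase). Noise is Gaussian with standard
deviation `sigma_abs + sigma_rel * model`, defaults 0.5 nM + 2%,
truncated at zero. Truncation rather than resampling preserves alignment
of the random stream across parameter sets sharing a seed. The defaults
are assumptions about plausible densitometry error, not measured values;
with them, the published constants are recoverable to ~5% (median over
seeds) for the mismatch guide.

What the generator does *not* emulate: plasmid topology (supercoiled /
nicked / linear bands are collapsed into one product concentration),
correlated lane-to-lane gel errors, loading and background-subtraction
artifacts, and any day effect across replicates. Recovery tests on these
data therefore demonstrate the identifiability and correctness of the
fitting machinery under the stated noise model — not the accuracy of the
published constants for real gels.

The endpoint release assay (`generate_release_assay`) treats each
labelled DNA end as released by a single first-order process,
fraction = 1 − e^(−k·t), with noise clipped to [0, 1].

## Global fitting

`chi_square` simulates every dataset under its own design ("each
experiment modelled exactly as performed") and sums squared residuals
weighted by the stored per-point sigmas; datasets without sigmas
contribute unweighted residuals and trigger a warning.

`fit_global` minimises this objective with Levenberg–Marquardt (lmfit)
over **log10-transformed** rate constants: the constants are positive
and span ~5 decades, so the log parameterisation enforces positivity
and conditions the search. Default box bounds are [1e-6, 1e4] per
constant. A deterministic multi-start (the initialisation plus ×10
up/down and alternating perturbations, 5 starts by default) reduces the
risk of local minima; the best local minimum is returned with an honest
convergence flag, and locked parameters pass through bit-identical.
Standard errors are mapped back from log space as
se(k) = k·ln(10)·se(log10 k).

The burst fit is a separate nonlinear least-squares fit of
Y = A·(1 − e^(−k_fast·t)) + k_slow·t, initialised with A from the last
point, k_slow from the slope of the last third, and k_fast from the
reciprocal of the first nonzero time. All three parameters are bounded
below by zero. On simulated single-turnover data the amplitude titrates
the active enzyme (A ≈ E0); this fit is descriptive, not mechanistic.

## Confidence limits

`profile_parameter` implements confidence contours: one constant is
fixed at each point of a grid (default 21 points, log-spaced ±1.5
decades around the estimate) while the remaining floating constants are
re-fit, warm-starting each refit from its neighbour's solution for
stability. The threshold is

    threshold = chi2_min · (1 + (p/(n−p)) · F_level(p, n−p))

with n data points and p floating parameters. `level` defaults to 0.99;
it is always explicit because thresholds of this form are variously
described as 99% or, more loosely, 95% limits in the kinetics
literature.

**Crossing interpolation.** Limits are the crossings of the profile with
the threshold. Near its minimum the profile is locally quadratic in
log-parameter, so the crossings are interpolated linearly in
√(χ² − χ²_min) against log10 θ — exact for a quadratic profile, whereas
linear interpolation of χ² itself on a coarse log grid underestimates
interval widths severely (in calibration runs here, enough to halve the
empirical coverage of a nominal 0.99 interval). A side with no crossing
inside the grid is reported as unbounded (`None`); a finite crossing in
the outer 10% of the default grid triggers one automatic extension of
the grid on that side.

On noise-free data the profile rises monotonically from the generating
value and the interval collapses toward it; interval width is
non-decreasing in `level` by quantile monotonicity.

## Quantification arithmetic

Percent cleaved of a plasmid lane is 100·linear/(linear + nicked +
supercoiled); fraction released is released/(released + bound); fold
changes are plain ratios. All are scale-invariant in the band
intensities; all-zero denominators are errors, not NaNs.

## Problem sizes

The shipped defaults (32-point grids, single datasets per condition,
21-point profiles) keep a full fit ~1 s and a profile a few seconds on
one core; the test suite and the acceptance script each run in well
under a minute. Larger grids, replicate designs (`n_replicates`), and
joint multi-dataset fits use the same code paths.

## Known limitations

- Single-step cleavage: nicked-intermediate chemistry of plasmid
  substrates is out of scope, so the model cannot describe the nicked
  band kinetics separately.
- `k_rebind` is an assumption (see above), not a fitted constant, unless
  the user floats it; fits with very different assumed `k_rebind` values
  should be compared via its profile.
- The noise model is independent Gaussian; real densitometry errors are
  likely correlated within a gel.
- Asymptotic standard errors from the covariance are crude for strongly
  correlated parameters; the profile-likelihood limits are the intended
  uncertainty statement.
- The 0.99-level threshold convention multiplies χ²_min (an F-ratio
  convention); an additive Δχ² convention would give different limits
  for poorly fitting data.
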