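"""Seeded synthetic turnover datasets under the published rate constants.

No raw densitometry data accompany the turnover assays, so every fitting
and profiling stage of this package is exercised against data generated
here: the mass-action scheme is simulated under one of the published
parameter presets and Gaussian measurement noise with an additive plus
proportional standard deviation is applied, emulating gel-band
quantification error.

The three presets correspond to the guide-RNA conditions of the turnover
assay (20 nM active enzyme, 100 nM plasmid substrate, 5:1 molar excess):

========  ==========================  ===============  ==============
preset    condition                   k_cat (min^-1)   k_rel (min^-1)
========  ==========================  ===============  ==============
``20nt``  full-length guide           60 (locked)      0.00085
``15nt``  truncated 15-nt guide       0.109            0.005
``2mm``   2 terminal mismatches       0.723            0.053
========  ==========================  ===============  ==============

Binding is locked at Kd = 1 nM (k_on = 1 nM^-1 min^-1, k_off = 1 min^-1)
and product rebinding defaults to the substrate on-rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import AssayDesign, RateParameters, observed_product, simulate

__all__ = [
    "NoiseModel",
    "TimecourseDataset",
    "PRESET_NAMES",
    "DEFAULT_TIMEPOINTS",
    "preset",
    "generate_timecourse",
    "generate_release_assay",
]

#: Default sampling grid (min): dense early points resolve the burst phase
#: (and hence the amplitude and k_cat), the 15-min spacing out to 6 h
#: constrains the slow linear phase set by k_rel.
DEFAULT_TIMEPOINTS = np.concatenate(
    [[0.0, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0, 2.0], np.arange(15.0, 361.0, 15.0)]
)

PRESET_NAMES = ("20nt", "15nt", "2mm")

_PRESET_RATES = {
    "20nt": dict(k_cat=60.0, k_rel=0.00085, locked_extra={"k_cat"}),
    "15nt": dict(k_cat=0.109, k_rel=0.005, locked_extra=set()),
    "2mm": dict(k_cat=0.723, k_rel=0.053, locked_extra=set()),
}


@dataclass(frozen=True)
class NoiseModel:
    """Additive plus proportional Gaussian measurement noise.

    A point with noise-free model value m is observed as
    Normal(m, sigma) truncated at 0, with
    sigma = ``sigma_abs`` + ``sigma_rel`` * m.  Defaults (0.5 nM, 2%)
    are a plausible gel-densitometry error at this dynamic range; they
    are assumptions of this package, not measured values.
    """

    sigma_abs: float = 0.5
    sigma_rel: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.sigma_abs < 0 or self.sigma_rel < 0:
            raise ValueError("sigma_abs and sigma_rel must be >= 0")

    def sigma(self, model: np.ndarray) -> np.ndarray:
        return self.sigma_abs + self.sigma_rel * np.asarray(model, dtype=float)

    @property
    def noise_free(self) -> bool:
        return self.sigma_abs == 0 and self.sigma_rel == 0


@dataclass(frozen=True)
class TimecourseDataset:
    """Observed (or simulated) product concentrations versus time.

    ``sigma`` is the per-point measurement standard deviation (nM) used
    to weight residuals, or None for unweighted data.  ``design`` records
    how the assay was performed and is required for simulation-based
    fitting.
    """

    condition: str
    times: np.ndarray
    product: np.ndarray
    sigma: np.ndarray | None = None
    design: AssayDesign | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.product, dtype=float)
        if t.shape != p.shape or t.ndim != 1:
            raise ValueError("times and product must be 1-D arrays of equal length")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "product", p)
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            if s.shape != t.shape:
                raise ValueError("sigma must match times in length")
            if np.any(s <= 0):
                raise ValueError("sigma must be > 0 for every point")
            object.__setattr__(self, "sigma", s)
        if self.design is not None:
            grid = self.design.timepoints
            if not np.all(np.isin(t, grid)):
                raise ValueError("dataset times must lie on the design's grid")

    @property
    def n_points(self) -> int:
        return int(self.times.size)


def preset(name: str) -> tuple[RateParameters, AssayDesign]:
    """Published rate constants and assay design for a guide condition.

    Raises ``KeyError`` for an unknown name.
    """
    try:
        spec = _PRESET_RATES[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; expected one of {PRESET_NAMES}"
        ) from None
    rates = RateParameters(
        k_on=1.0,
        k_off=1.0,
        k_cat=spec["k_cat"],
        k_rel=spec["k_rel"],
        k_rebind=1.0,
        locked=frozenset({"k_on", "k_off", "k_rebind"}) | spec["locked_extra"],
    )
    design = AssayDesign(e0=20.0, s0=100.0, timepoints=DEFAULT_TIMEPOINTS.copy())
    return rates, design


def generate_timecourse(
    rates: RateParameters,
    design: AssayDesign,
    noise: NoiseModel,
    condition: str = "synthetic",
) -> TimecourseDataset:
    """Simulate the scheme and apply seeded measurement noise.

    Each of the design's ``n_replicates`` contributes one noisy point per
    timepoint.  Observations are truncated at 0 (concentrations cannot be
    negative); truncation rather than resampling keeps the random stream
    aligned across parameter sets sharing a seed.  A fully zero noise
    model returns the noise-free series with ``sigma=None``.
    """
    model = observed_product(simulate(rates, design))
    reps = design.n_replicates
    times = np.repeat(design.timepoints, reps)
    model_rep = np.repeat(model, reps)

    if noise.noise_free:
        return TimecourseDataset(
            condition=condition, times=times, product=model_rep.copy(),
            sigma=None, design=design,
        )

    sigma = noise.sigma(model_rep)
    if np.any(sigma <= 0):
        raise ValueError(
            "noise model yields sigma = 0 at some points; use sigma_abs > 0"
        )
    rng = np.random.default_rng(noise.seed)
    observed = np.maximum(rng.normal(model_rep, sigma), 0.0)
    return TimecourseDataset(
        condition=condition, times=times, product=observed, sigma=sigma,
        design=design,
    )


def generate_release_assay(
    k_rel_distal: float,
    k_rel_proximal: float,
    t: float,
    noise: NoiseModel | None = None,
) -> tuple[float, float]:
    """Endpoint fractions released for the two labelled DNA ends.

    Emulates the two-fluorophore native-gel endpoint assay: each end is
    released as a first-order process, so the noise-free fraction at time
    t is 1 - exp(-k t).  Noise (with sigma in fraction units) is applied
    and the result clipped to [0, 1].
    """
    if k_rel_distal < 0 or k_rel_proximal < 0:
        raise ValueError("release rate constants must be >= 0")
    if t < 0:
        raise ValueError("t must be >= 0")
    fractions = 1.0 - np.exp(-np.array([k_rel_distal, k_rel_proximal]) * t)
    if noise is not None and not noise.noise_free:
        rng = np.random.default_rng(noise.seed)
        fractions = rng.normal(fractions, noise.sigma(fractions))
    fractions = np.clip(fractions, 0.0, 1.0)
    return float(fractions[0]), float(fractions[1])
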