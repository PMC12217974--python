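"""YAML configuration for presets, assay design, noise and fitting.

Every default in the package can be overridden from a single config
file.  Sections (all optional):

.. code-block:: yaml

    presets:
      2mm: {k_on: 1.0, k_off: 1.0, k_cat: 0.723, k_rel: 0.053,
            k_rebind: 1.0, locked: [k_on, k_off, k_rebind]}
    design:
      e0: 20.0          # nM active enzyme
      s0: 100.0         # nM substrate
      timepoints: [0, 0.02, ...]   # min; omit for the default grid
      n_replicates: 1
    noise:
      sigma_abs: 0.5    # nM
      sigma_rel: 0.02
    fit:
      float: [k_cat, k_rel]
      bounds: [1.0e-6, 1.0e4]
      n_starts: 5
    profile:
      level: 0.99
      n_grid: 21
      span_decades: 1.5
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .datasets import DEFAULT_TIMEPOINTS, NoiseModel, preset
from .model import AssayDesign, RateParameters

__all__ = ["load_config", "rates_from_config", "design_from_config",
           "noise_from_config"]

_DEFAULTS = {
    "presets": {},
    "design": {},
    "noise": {},
    "fit": {"float": ["k_cat", "k_rel"], "bounds": [1e-6, 1e4], "n_starts": 5},
    "profile": {"level": 0.99, "n_grid": 21, "span_decades": 1.5},
}


def load_config(path=None) -> dict:
    """Load a YAML config, merged over the package defaults."""
    config = {k: (dict(v) if isinstance(v, dict) else list(v))
              for k, v in _DEFAULTS.items()}
    if path is None:
        return config
    with open(Path(path), "r", encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"{path}: config must be a mapping")
    for key, value in user.items():
        if key in config and isinstance(config[key], dict) and isinstance(value, dict):
            config[key].update(value)
        else:
            config[key] = value
    return config


def rates_from_config(config: dict, preset_name: str) -> RateParameters:
    """Preset rate constants with any config overrides applied."""
    rates, _ = preset(preset_name)
    override = config.get("presets", {}).get(preset_name)
    if override:
        override = dict(override)
        locked = override.pop("locked", None)
        if locked is not None:
            override["locked"] = frozenset(locked)
        rates = rates.replace(**override)
    return rates


def design_from_config(config: dict, preset_name: str | None = None) -> AssayDesign:
    section = config.get("design", {})
    if preset_name is not None:
        _, design = preset(preset_name)
    else:
        design = AssayDesign(e0=20.0, s0=100.0,
                             timepoints=DEFAULT_TIMEPOINTS.copy())
    timepoints = section.get("timepoints")
    return AssayDesign(
        e0=float(section.get("e0", design.e0)),
        s0=float(section.get("s0", design.s0)),
        timepoints=(np.asarray(timepoints, dtype=float)
                    if timepoints is not None else design.timepoints),
        n_replicates=int(section.get("n_replicates", design.n_replicates)),
    )


def noise_from_config(config: dict, seed: int = 0) -> NoiseModel:
    section = config.get("noise", {})
    return NoiseModel(
        sigma_abs=float(section.get("sigma_abs", 0.5)),
        sigma_rel=float(section.get("sigma_rel", 0.02)),
        seed=seed,
    )
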