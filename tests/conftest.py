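"""Shared fixtures: presets, seeded noisy datasets and cached global fits.

Fits are session-scoped because each one integrates the ODE system a few
hundred times; every test that needs a fitted 2 mm dataset shares the
same seeded realisation.
"""

import numpy as np
import pytest

import turnofit as tf

SEED = 1


@pytest.fixture(scope="session")
def mm2():
    rates, design = tf.preset("2mm")
    return rates, design


@pytest.fixture(scope="session")
def mm2_noisy(mm2):
    rates, design = mm2
    return tf.generate_timecourse(rates, design, tf.NoiseModel(seed=SEED),
                                  condition="2mm")


@pytest.fixture(scope="session")
def mm2_fit(mm2, mm2_noisy):
    rates, _ = mm2
    return tf.fit_global([mm2_noisy], float_params=("k_cat", "k_rel"),
                         init=rates)


@pytest.fixture(scope="session")
def mm2_noise_free(mm2):
    rates, design = mm2
    return tf.generate_timecourse(rates, design, tf.NoiseModel(0.0, 0.0, 0),
                                  condition="2mm")


@pytest.fixture(scope="session")
def traj_20nt():
    rates, design = tf.preset("20nt")
    return tf.simulate(rates, design)


@pytest.fixture
def short_design():
    """Small grid for cheap fitting tests."""
    tp = np.concatenate([[0.0, 0.1, 0.5, 1.0, 2.0, 5.0],
                         np.arange(15.0, 121.0, 15.0)])
    return tf.AssayDesign(e0=20.0, s0=100.0, timepoints=tp)
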