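"""Shared fixtures: deterministic simulation configs for both regimes."""

from dataclasses import replace

import numpy as np
import pytest

from mrsidh.synthetic_data import (
    MetabolitePeak,
    SimulationConfig,
    config_for_regime,
)


@pytest.fixture
def clean_config():
    """Factory for noise-free, jitter-free, unit-scale configs.

    With all nuisance terms off, simulated spectra are deterministic
    sums of Lorentzians — the setting in which closed-form oracles apply.
    """

    def make(regime="3T-original", seed=0, **overrides):
        base = dict(
            noise_sd=0.0,
            baseline_amplitude=0.0,
            ppm_jitter_sd=0.0,
            global_scale_range=(1.0, 1.0),
            seed=seed,
        )
        base.update(overrides)
        cfg = config_for_regime(regime, **base)
        # strip biological amplitude variability too
        basis = tuple(replace(p, amplitude_cv=0.0) for p in cfg.basis)
        return replace(cfg, basis=basis)

    return make


@pytest.fixture
def single_peak_config(clean_config):
    """Noiseless config containing only a unit-amplitude choline peak."""

    def make(regime="3T-original", position=3.22, amplitude=1.0, fwhm_hz=5.0):
        basis = (
            MetabolitePeak(
                "Cho",
                position,
                amplitude,
                fwhm_hz=fwhm_hz,
                amplitude_cv=0.0,
            ),
        )
        return replace(clean_config(regime), basis=basis)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
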