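import numpy as np
import pandas as pd
import pytest

from rtwave import DesignConfig, WaveParams, dispersion_curve


@pytest.fixture
def wave():
    return WaveParams(sigma0=200.0, amplitude=100.0, wavelength=5.0)


@pytest.fixture
def design():
    return DesignConfig()


@pytest.fixture
def make_profile():
    """Build a noise-free dispersion profile straight from a wave envelope."""

    def _make(w: WaveParams, d_min=-15, d_max=15, include_zero=False,
              noise_sd=0.0, seed=0):
        d = np.array([x for x in range(d_min, d_max + 1)
                      if x != 0 or include_zero])
        sd = np.asarray(dispersion_curve(d, w), dtype=float)
        if noise_sd > 0:
            sd = sd + np.random.default_rng(seed).normal(0, noise_sd, d.size)
        return pd.DataFrame({
            "differential": d,
            "count": 100,
            "mean_rt": 1000.0,
            "sd_rt": sd,
        })

    return _make


@pytest.fixture
def trial_table():
    """Small hand-checkable trial table (free entry, no differential yet)."""
    return pd.DataFrame({
        "participant": ["p1", "p1", "p2", "p2", "p3", "p3"],
        "actual_n": [45, 45, 50, 50, 48, 52],
        "estimate_or_target": [43, 50, 50, 47, 48, 55],
        "rt_ms": [800.0, 900.0, 1000.0, 1100.0, 950.0, 1050.0],
        "correct": pd.array([True, False, True, True, False, True],
                            dtype="boolean"),
    })
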