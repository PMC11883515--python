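import dataclasses

import numpy as np
import pandas as pd
import pytest

from reefphys.synthetic import SyntheticConfig


@pytest.fixture
def noiseless_config() -> SyntheticConfig:
    """Zero-noise generator: every estimator should recover its parameter."""
    return SyntheticConfig(
        seed=0,
        individual_cv=0.0,
        o2_noise_sd=0.0,
        epoc_tau=0.0,
        background_slope_pre=0.0,
        background_slope_post=0.0,
        ct_limit_sd=0.0,
        duration_h=10.0,
        n_fish_per_cell=3,
    )


@pytest.fixture
def short_config() -> SyntheticConfig:
    """Small, fast, realistic-noise generator for integration-style tests."""
    return SyntheticConfig(seed=0, duration_h=8.0, n_fish_per_cell=4)


def make_mo2_series(mo2_values, start_times=None) -> pd.DataFrame:
    """Build a per-cycle MO2 table directly (bypassing trace simulation)."""
    mo2_values = np.asarray(mo2_values, dtype=float)
    if start_times is None:
        start_times = np.arange(len(mo2_values)) * 10.0
    return pd.DataFrame(
        {
            "cycle_index": np.arange(len(mo2_values)),
            "cycle_start_time": np.asarray(start_times, dtype=float),
            "mo2": mo2_values,
            "slope_r2": 1.0,
            "flagged": False,
        }
    )


def replace(cfg, **kw):
    return dataclasses.replace(cfg, **kw)
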