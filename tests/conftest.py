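import logging

import numpy as np
import pandas as pd
import pytest

import rootzone as rz

logging.getLogger("rootzone").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def seasonal_forcing():
    """30-year seasonal forcing with S0 = 200 mm (shared, read-only)."""
    cfg = rz.SimConfig(s0_true=200.0, years=30, seed=42, **rz.SEASONAL)
    return cfg, rz.generate_forcing(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_forcing_frame(et, p_in):
    """Minimal forcing table with a precomputed liquid-input column."""
    et = np.asarray(et, dtype=float)
    n = len(et)
    return pd.DataFrame(
        {
            "day_index": np.arange(n),
            "precip": np.asarray(p_in, dtype=float),
            "temp": np.full(n, 10.0),
            "et": et,
            "p_in": np.asarray(p_in, dtype=float),
            "netrad": np.ones(n),
            "swrad": np.ones(n),
        }
    )
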