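import logging

import numpy as np
import pandas as pd
import pytest

from sphase import SimConfig, simulate_time_course, EventTable

logging.getLogger("sphase").setLevel(logging.ERROR)


def ideal_config(**overrides) -> SimConfig:
    """Noise-free, zero-pulse, no-division, no-residual oracle world."""
    base = dict(dapi_cv=0.0, label_cv=0.0, pulse_len=0.0,
                divide_labeled=False, residual_rate=0.0, slow_fraction=0.0,
                debris_fraction=0.0, noncycling_fraction=0.0,
                n_cells=50_000, chase_times=(0.0,), seed=7)
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def ideal_t0_table() -> EventTable:
    cfg = ideal_config(n_cells=100_000)
    return simulate_time_course(cfg).entries[0]


@pytest.fixture(scope="session")
def noisy_t0_table() -> EventTable:
    """Realistic 0 h sample: measurement noise, debris, 30-min pulse."""
    cfg = SimConfig(n_cells=40_000, chase_times=(0.0,), seed=13)
    return simulate_time_course(cfg).entries[0]


def point_mass_table(dna, label, time_h=0.0, replicate="1") -> EventTable:
    """Tiny synthetic table of exact point-mass clusters (no noise)."""
    df = pd.DataFrame({"dapi": np.asarray(dna, float),
                       "label": np.asarray(label, float)})
    return EventTable(df, sample="pm", time_h=time_h, replicate=replicate)
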