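import numpy as np
import pandas as pd
import pytest

from lumipower.metrics import DaySeries
from lumipower.synth import DiurnalSpec, GenerativeSpec, generate_day_metrics, generate_epoch_series


@pytest.fixture(scope="session")
def square_day():
    """One clean day at 1-min epochs: 500 lx 08:00-18:00, 0.05 lx elsewhere."""
    n = 1440
    times = np.arange(n) / 60.0
    values = np.where((times >= 8) & (times < 18), 500.0, 0.05)
    return DaySeries(times_h=times, values=values, valid=np.ones(n, bool), delta_h=1 / 60)


@pytest.fixture(scope="session")
def effect_table():
    """Day-level metric table with a clear condition effect (fast tier)."""
    spec = GenerativeSpec(
        n_participants=13, days_per_condition=3, alpha=0.0, beta=np.sqrt(2.0),
        sigma_b=1.0, sigma=1.0, seed=101,
    )
    return generate_day_metrics(spec, metric="m")


@pytest.fixture(scope="session")
def tiny_epoch_table():
    """Small raw epoch table (2-min epochs to keep it light)."""
    spec = DiurnalSpec(epoch_s=120.0, lognormal_noise_sd=0.1)
    return generate_epoch_series(spec, n_participants=3, days_per_condition=2, seed=7)
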