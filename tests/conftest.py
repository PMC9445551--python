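import numpy as np
import pytest

from wspsignal.events import EventTable, concatenate
from wspsignal.simulate import generate_adrs, generate_background


def make_cohort(n, rate, n_adr=0, adr_mean=0.25, adr_sd=0.05, seed=0):
    """Simulated unit-period cohort: exponential background AEs plus
    optional normally-timed ADR records."""
    rng = np.random.default_rng(seed)
    table = generate_background(n, rate, rng)
    if n_adr:
        table = concatenate([table, generate_adrs(n_adr, adr_mean, adr_sd, rng)])
    return table


@pytest.fixture
def null_cohort():
    """Constant-hazard cohort: 2,500 subjects, 10% background rate."""
    return make_cohort(2500, 0.10, seed=42)


@pytest.fixture
def toy_table():
    return EventTable(
        times=np.array([0.1, 0.5, 1.0, 1.0, 0.8]),
        events=np.array([1, 1, 0, 0, 1]),
        window_end=1.0,
    )
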