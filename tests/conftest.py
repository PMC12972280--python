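import numpy as np
import pytest

from survscan import SimConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cohort(seed=1, n=60, hr=1.5, true_cutoff_pct=0.5, **kwargs):
    """Small synthetic cohort for unit tests."""
    return simulate_cohort(SimConfig(n=n, hr=hr, true_cutoff_pct=true_cutoff_pct,
                                     seed=seed, **kwargs))


def random_survival(rng, n, tie_free=True, p_event=0.6):
    """Random censored survival data (optionally tie-free) for oracle checks."""
    time = rng.exponential(10.0, n)
    if not tie_free:
        time = np.ceil(time)
    event = (rng.random(n) < p_event).astype(int)
    group = rng.integers(0, 2, n)
    return time, event, group


@pytest.fixture
def cohort_factory():
    return make_cohort
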