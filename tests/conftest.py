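import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pupilfield as pf

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def region_map():
    return pf.build_region_map()


@pytest.fixture(scope="session")
def kernels():
    return pf.default_kernels()


@pytest.fixture(scope="session")
def equal_kernels():
    """Light and dark kernels with identical gain (for worked examples)."""
    return pf.default_kernels(light_gain=1.0, dark_gain=1.0)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic experiment shared across tests."""
    return pf.simulate_cohort(seed=11, n_participants=6, n_trials=3)


@pytest.fixture(scope="session")
def small_summaries(small_cohort):
    return pf.summarize_cohort(small_cohort)


def impulse_events(region_map, impulses, n_times=200, rate=25.0):
    """EventMatrix with the given {(frame, region): amplitude} impulses."""
    values = np.zeros((n_times, region_map.n_regions))
    for (k, r), a in impulses.items():
        values[k, r] = a
    times = (np.arange(n_times) + 1) / rate
    return pf.EventMatrix(times=times, values=values,
                          region_ids=region_map.region_ids, rate=rate)


@pytest.fixture(scope="session")
def make_impulse_events(region_map):
    def _make(impulses, n_times=200):
        return impulse_events(region_map, impulses, n_times=n_times)
    return _make
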