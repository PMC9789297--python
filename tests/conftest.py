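import numpy as np
import pytest

from abrlab.containers import AverageResponse
from abrlab.simulate import SimCohortSpec, one_cycle_sine, simulate_cohort


@pytest.fixture(scope="session")
def tiny_spec() -> SimCohortSpec:
    """Small noise-free cohort spec shared across unit tests."""
    return SimCohortSpec(
        n_F=2, n_M=2, n_epochs=4, epoch_noise_sd=0.0,
        stimuli=(("click", "white"),), seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return simulate_cohort(tiny_spec)


@pytest.fixture()
def abr_template():
    """Factory for a two-wave template response with a latency shift."""
    fs = 16_384.0
    t = -5.0 + np.arange(int(45e-3 * fs)) / fs * 1e3

    def make(shift_ms: float = 0.0, noise_sd: float = 0.0, seed: int = 0):
        values = one_cycle_sine(t, 3.0 + shift_ms, 1.0, 1.0) + one_cycle_sine(
            t, 6.5 + shift_ms, 2.0, 2.0
        )
        if noise_sd:
            rng = np.random.default_rng(seed)
            values = values + rng.normal(0.0, noise_sd, t.size)
        return AverageResponse(fs=fs, values=values, t0=-5e-3)

    return make
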