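import numpy as np
import pytest

from hrvdyn.preprocess import UniformSeries
from hrvdyn.synthesize import TrueParams, simulate_cohort


@pytest.fixture(scope="session")
def latent_cohort():
    """Small latent cohort shared across model-stage tests."""
    params = TrueParams(n_subjects=20)
    return simulate_cohort(params, seed=101, fidelity="latent")


@pytest.fixture(scope="session")
def observed_cohort():
    """Small observed-fidelity cohort (beats + events) for pipeline tests."""
    params = TrueParams(n_subjects=6)
    return simulate_cohort(params, seed=202, fidelity="observed")


def make_sinusoid_4hz(
    amp: float, freq: float, duration: float = 300.0, mean: float = 0.8
) -> UniformSeries:
    t = np.arange(0, duration, 0.25)
    values = mean + amp * np.sin(2 * np.pi * freq * t)
    return UniformSeries(values, np.zeros(t.size, dtype=bool), fs=4)
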