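import numpy as np
import pytest

from mskpinn.dynamics import ElbowModel, Trial
from mskpinn.synthetic import generate_verification_set


@pytest.fixture(scope="session")
def elbow():
    return ElbowModel()


@pytest.fixture(scope="session")
def smooth_trial():
    """Small analytic trial (no ODE solve) for cell/loss unit tests."""
    n = 60
    t = np.linspace(0.0, 1.2, n)
    emg = 0.5 + 0.4 * np.column_stack([np.sin(2 * np.pi * t), -np.sin(2 * np.pi * t)])
    q = 1.2 + 0.3 * np.sin(2 * np.pi * t + 0.3)
    return Trial(t=t, emg=emg, q=q)


@pytest.fixture(scope="session")
def case1_trials(elbow):
    """Case-1 verification set (sigma = 0.1), fixed seed; generated once."""
    return generate_verification_set(1, model=elbow, seed=7)


@pytest.fixture(scope="session")
def noiseless_trials(elbow):
    """Noise-free counterpart of the verification trials."""
    from mskpinn.synthetic import NoiseCase

    return generate_verification_set(NoiseCase(1, 0.0), model=elbow, seed=7)
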