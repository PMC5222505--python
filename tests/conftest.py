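import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import wienerstc as w

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def worked():
    """The 4-sample hand-derivable fixture: s=[1,2,3,4], r=[0,0,1,2], tau=1.

    All expected matrices below were derived by hand from the defining
    sums over t = 2..4 (1-based).
    """
    return {
        "stimulus": w.StimulusEnsemble(np.array([1.0, 2.0, 3.0, 4.0])),
        "spikes": w.ResponseSet(np.array([0.0, 0.0, 1.0, 2.0]), mode=w.MODE_SPIKES),
        "lags": w.LagWindow(1),
        "C": np.array([[41 / 3, 10.0], [10.0, 22 / 3]]),
        "S": np.array([[29 / 3, 20 / 3], [20 / 3, 14 / 3]]),
        "a": np.array([11 / 3, 8 / 3]),
        "n_r": 3.0,
        "C0": np.array([[4.0, 10 / 3], [10 / 3, 8 / 3]]),
        "A": np.array([[121 / 9, 88 / 9], [88 / 9, 64 / 9]]),
        "C1": np.array([[-85 / 9, -58 / 9], [-58 / 9, -40 / 9]]),
    }


def random_spike_instance(seed, T=400, D=1, tau=3, rate=0.3):
    """Small random stimulus/spike pair guaranteed to contain spikes."""
    rng = np.random.default_rng(seed)
    stim = w.gaussian_white_stimulus(T, D, 1.0, 1.0, seed=seed)
    spikes = rng.poisson(rate, size=T).astype(float)
    if spikes[tau:].sum() == 0:  # pragma: no cover - rate*T makes this moot
        spikes[tau] = 1.0
    return stim, spikes, w.LagWindow(tau)
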