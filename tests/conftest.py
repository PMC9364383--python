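import numpy as np
import pytest

from coxsvb import SurvivalDataset, VariationalParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_dataset():
    """Three subjects, one censored, a single covariate."""
    return SurvivalDataset(
        times=np.array([1.0, 2.0, 3.0]),
        events=np.array([1, 0, 1]),
        design=np.array([[0.5], [-1.0], [2.0]]),
    )


def random_survival(rng, n, p, censor_frac=0.3, beta=None):
    """Small random right-censored dataset for unit tests."""
    design = rng.standard_normal((n, p))
    eta = design @ (beta if beta is not None else np.zeros(p))
    times = rng.exponential(scale=np.exp(-eta))
    events = (rng.random(n) > censor_frac).astype(int)
    if events.sum() == 0:
        events[0] = 1
    return SurvivalDataset(times=times, events=events, design=design)


def random_params(rng, p, mu_scale=1.0):
    return VariationalParams(
        mu=mu_scale * rng.standard_normal(p),
        sigma=rng.uniform(0.05, 1.0, size=p),
        gamma=rng.uniform(0.05, 0.95, size=p),
    )
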