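import numpy as np
import pytest

from slhte import TrialSimConfig, default_schema, simulate_trial


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def signal_trial():
    """A moderate-size trial whose responder status is predictable from
    baseline covariates (strong baseline-HbA1c and glucose effects)."""
    cfg = TrialSimConfig(
        n_patients=300, seed=11,
        beta_main={"hba1c_baseline": -0.6, "fpg": -0.15, "bmi": -0.03},
        sigma=0.5,
    )
    return simulate_trial(cfg)


def make_xy(n: int, p: int, seed: int, signal: float = 2.0):
    """Plain planted-logistic-signal design for learner unit tests:
    y ~ Bernoulli(sigmoid(signal * x0))."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    prob = 1.0 / (1.0 + np.exp(-signal * X[:, 0]))
    y = (rng.random(n) < prob).astype(int)
    return X, y
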