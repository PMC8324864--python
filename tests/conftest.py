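import numpy as np
import pytest

from dgevolve import DeficitParams, GameSpec, ReproductionParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def dg12():
    """One dictator, one recipient: R = 10, equitable offer 0.5."""
    return GameSpec(k=1, n=2)


@pytest.fixture
def dg12_nonoise():
    return GameSpec(k=1, n=2, endowment_sd=0.0)


@pytest.fixture
def repro270(dg12):
    """Standard reproduction parameters at tau0 = 270 (I_o = 1350, omega = 810)."""
    return ReproductionParams.from_tau0(270, dg12)


@pytest.fixture
def no_cost():
    return DeficitParams(time_cost=0.0, cutoff=0.9)


def brute_force_step_moments(spec: GameSpec, offer: float) -> tuple[float, float]:
    """Independent oracle: mean and variance of the one-step payoff.

    Enumerates the two roles directly: dictator with weight k/n keeps
    R(1-p); recipient with weight (n-k)/n receives k p R / (n-k).
    """
    k, n, r = spec.k, spec.n, spec.base_endowment
    outcomes = [r * (1 - offer), k * offer * r / (n - k)]
    weights = [k / n, (n - k) / n]
    mean = sum(w * o for w, o in zip(weights, outcomes))
    var = sum(w * (o - mean) ** 2 for w, o in zip(weights, outcomes))
    return mean, var


ALL_SMALL_GAMES = [(k, n) for n in range(2, 7) for k in range(1, n)]
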