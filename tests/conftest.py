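import numpy as np
import pytest

from hgtosc import (
    FourierSeries,
    ModelParams,
    OscillatorySpec,
    PopulationState,
)


@pytest.fixture
def ref_params() -> ModelParams:
    """Reference single-allele parameter set: r_A=1.8, r_B=1, a=0.1, gamma=0."""
    return ModelParams.symmetric(r_A=1.8, r_B=1.0, a=0.1, gamma=0.0)


def single_harmonic_spec(c1: float, c2: float, omega: float = 5.0, g: float = 0.5) -> OscillatorySpec:
    """gamma~ = g sin(tau), r~_A = c1 cos(tau), r~_B = c2 cos(tau)."""
    return OscillatorySpec(
        omega=omega,
        r_tilde_A=FourierSeries.cosine(c1),
        r_tilde_B=FourierSeries.cosine(c2),
        gamma_tilde=FourierSeries.sine(g),
    )


@pytest.fixture
def blue_spec() -> OscillatorySpec:
    """Oscillation giving (xi, kappa) = (-0.01, -0.08): coexistence without synergy."""
    return single_harmonic_spec(-1.6, -0.2)


@pytest.fixture
def orange_spec() -> OscillatorySpec:
    """Oscillation giving (xi, kappa) = (0.08, -0.08): synergetic pure competition."""
    return single_harmonic_spec(-1.6, 1.6)


@pytest.fixture
def green_spec() -> OscillatorySpec:
    """Oscillation giving (xi, kappa) = (0.11, -0.11): mutualistic coexistence."""
    return single_harmonic_spec(-2.2, 2.2)


@pytest.fixture
def default_init() -> PopulationState:
    return PopulationState(p_A=0.5, N=10.0)


def random_params(rng: np.random.Generator, equal_a: bool = False, gamma: float = 0.0) -> ModelParams:
    """Random physical parameter draw for property tests."""
    r_A, r_B = rng.uniform(0.5, 2.5, size=2)
    if equal_a:
        return ModelParams.symmetric(r_A, r_B, a=rng.uniform(0.05, 0.3), gamma=gamma)
    a = rng.uniform(0.05, 0.3, size=4)
    return ModelParams(
        r_A=r_A, r_B=r_B, a_11=a[0], a_12=a[1], a_21=a[2], a_22=a[3], gamma=gamma
    )
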