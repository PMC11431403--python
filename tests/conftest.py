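import numpy as np
import pytest

from tetdimer import DimerParams, get_preset


@pytest.fixture(scope="session")
def tet_params() -> DimerParams:
    return get_preset("tet").params


@pytest.fixture(scope="session")
def near_tet_params() -> DimerParams:
    return get_preset("near_tet").params


@pytest.fixture(scope="session")
def away_params() -> DimerParams:
    return get_preset("away").params


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_params(rng: np.random.Generator) -> DimerParams:
    """A generic finite parameter set with positive frequencies."""
    return DimerParams(
        E_D=rng.uniform(-2, 2), E_A=rng.uniform(-2, 2),
        k_z=rng.uniform(-3, 3), k_x=rng.uniform(-3, 3),
        eps_x=rng.uniform(-1, 1),
        Omega_z=rng.uniform(0.3, 3), Omega_x=rng.uniform(0.3, 3),
        gamma_z=rng.uniform(0, 1), gamma_x=rng.uniform(0, 1),
    )


def random_state(rng: np.random.Generator):
    """A normalised random electronic state with random mode coordinates."""
    from tetdimer import SystemState

    theta = rng.uniform(0, np.pi / 2)
    a, b = rng.uniform(0, 2 * np.pi, 2)
    return SystemState(
        phi_D=np.cos(theta) * np.exp(1j * a),
        phi_A=np.sin(theta) * np.exp(1j * b),
        u_z=rng.uniform(-2, 2), u_x=rng.uniform(-2, 2),
        p_z=rng.uniform(-2, 2), p_x=rng.uniform(-2, 2),
    )
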