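import numpy as np
import pytest

from motordcm.generative import DCMParameters
from motordcm.network import NetworkSpec, motor_network_preset, winning_model_preset
from motordcm.paradigm import build_paradigm


@pytest.fixture(scope="session")
def default_design():
    """The study's default tapping design (30 blocks, 663 s, dt = TR/16)."""
    return build_paradigm(seed=1)


@pytest.fixture(scope="session")
def full_net():
    return motor_network_preset()


@pytest.fixture(scope="session")
def winning_net():
    return winning_model_preset()


def two_region_spec() -> NetworkSpec:
    """Minimal network: task drives X, one free coupling X -> Y."""
    A_mask = np.array([[True, False], [True, True]])
    C_mask = np.zeros((2, 3), dtype=bool)
    C_mask[0, 0] = True
    return NetworkSpec(
        regions=("X", "Y"),
        coords={"X": (0.0, 0.0, 0.0), "Y": (0.0, 0.0, 0.0)},
        A_mask=A_mask,
        B_masks={"complexity": np.zeros((2, 2), bool), "speed": np.zeros((2, 2), bool)},
        C_mask=C_mask,
    )


def two_region_params(a_yx=0.3, c=0.15, noise_sd=0.0) -> DCMParameters:
    A = np.array([[-0.5, 0.0], [a_yx, -0.5]])
    C = np.zeros((2, 3))
    C[0, 0] = c
    return DCMParameters(
        A=A,
        B={"complexity": np.zeros((2, 2)), "speed": np.zeros((2, 2))},
        C=C,
        noise_sd=noise_sd,
    )


@pytest.fixture()
def toy_spec():
    return two_region_spec()


@pytest.fixture()
def toy_params():
    return two_region_params()
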