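import numpy as np
import pytest

from ratenet import (
    ADAPTATION,
    SYNAPTIC,
    ConnectivitySpec,
    TransferParams,
    UnitParams,
    build_connectivity,
    radius_to_J,
)

# Table-style network constants used throughout the suite
CE, CI, G_RATIO = 80, 20, 4.1


@pytest.fixture(scope="session")
def tf_default() -> TransferParams:
    return TransferParams(gamma=-0.5, phi_max=2.0)


@pytest.fixture(scope="session")
def synaptic_params() -> UnitParams:
    return UnitParams(tau_m=1.0, mechanism=SYNAPTIC, tau_s=5.0)


@pytest.fixture(scope="session")
def adaptive_params() -> UnitParams:
    return UnitParams(tau_m=1.0, mechanism=ADAPTATION, tau_w=5.0, g_w=0.5)


def ei_spec(N: int, radius: float, seed: int) -> ConnectivitySpec:
    """E-I spec with the standard in-degrees scaled to a bulk radius."""
    return ConnectivitySpec(
        N=N, C_E=CE, C_I=CI, J=radius_to_J(radius, CE, CI, G_RATIO),
        g=G_RATIO, seed=seed,
    )


@pytest.fixture(scope="session")
def small_network():
    """N=200 subcritical synaptic-radius-0.8 connectivity."""
    return build_connectivity(ei_spec(200, 0.8, seed=42))


@pytest.fixture()
def rng() -> np.random.Generator:
    """Fresh deterministic generator per test (results order-independent)."""
    return np.random.default_rng(20251001)
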