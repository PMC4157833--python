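import numpy as np
import pytest

from deadhesion import BondField, DimensionlessParams, PrestretchField


@pytest.fixture(scope="session")
def uniform_bonds() -> BondField:
    return BondField.uniform()


@pytest.fixture(scope="session")
def linear_prestretch() -> PrestretchField:
    return PrestretchField.linear(0.01)


@pytest.fixture(scope="session")
def base_params() -> DimensionlessParams:
    """Baseline run conditions: moderate stiffness, unit breakage rate,
    internal relaxation ten times faster than breakage (sigmoidal regime)."""
    return DimensionlessParams(
        stiffness_ratio=10.0, breakage_rate=1.0, viscosity=0.1
    )


def closed_form_displacement(x: np.ndarray, beta: float, rho: float, s: float) -> np.ndarray:
    """Constant-coefficient equilibrium solution for uniform bonds and a
    linear antisymmetric pre-stretch of pre-strain ``s``:
    u(x) = -s sinh(kx) / (k cosh(k/2)), k = sqrt(beta * rho)."""
    k = np.sqrt(beta * rho)
    return -s * np.sinh(k * x) / (k * np.cosh(k / 2.0))
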