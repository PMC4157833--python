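"""Static pre-stressed configuration of the attached cell.

Before de-adhesion starts, the pre-stretched cell is bonded to the
substrate and sits in mechanical equilibrium: the elastic stress of the
rod balances the distributed bond tractions.  In scaled variables the
displacement ``u(x)`` away from the stretched, just-attached state obeys

    u'' - beta * rho(x) * u = -u0''(x),      x in [-1/2, 1/2],

with stress-free ends ``(u + u0)'(+-1/2) = 0``, where ``u0`` is the
imposed pre-stretch field, ``rho`` the scaled bond density and ``beta``
the stiffness ratio.  The solver uses second-order central finite
differences with ghost-node boundary rows and a tridiagonal solve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from .params import (
    BondField,
    DimensionlessParams,
    InvalidParameterError,
    PrestretchField,
)

__all__ = [
    "DisplacementProfile",
    "solve_equilibrium",
    "contractile_force",
    "equilibrated_length",
    "profile_to_frame",
]

#: below this value of ``beta * max(rho) * h**2`` (the bond term
#: relative to the discrete second-derivative scale) the operator is
#: treated as the pure-Neumann (free rod) case and the centre node is
#: pinned to remove the rigid-translation nullspace.
_NULLSPACE_THRESHOLD = 1e-13


@dataclass(frozen=True)
class DisplacementProfile:
    """Cell displacement at one instant, with derived stress measures.

    ``per_bond_force`` is the scaled force carried by one bond,
    ``beta * u`` (traction per unit length divided by the local bond
    density), set to zero where the density vanishes.  Sign convention:
    negative values pull the substrate inward (contraction).
    """

    grid: np.ndarray
    displacement: np.ndarray
    strain: np.ndarray
    per_bond_force: np.ndarray

    def __post_init__(self) -> None:
        for name in ("grid", "displacement", "strain", "per_bond_force"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not np.all(np.isfinite(self.displacement)):
            raise InvalidParameterError("displacement must be finite everywhere")


def _second_derivative(values: np.ndarray, x: np.ndarray) -> np.ndarray:
    return np.gradient(np.gradient(values, x), x)


def _resample(field, grid):
    if field.grid.shape == grid.shape and np.allclose(field.grid, grid):
        return field
    return field.resample(grid)


def solve_equilibrium(
    params: DimensionlessParams,
    bonds: BondField,
    prestretch: PrestretchField,
    n_grid: int = 1001,
) -> DisplacementProfile:
    """Solve the static force balance of the attached, pre-stressed cell.

    Bonds and pre-stretch defined on other grids are resampled onto the
    uniform solver grid by linear interpolation.  When the bond term
    vanishes entirely (``stiffness_ratio * rho == 0``) the operator has a
    rigid-translation nullspace; the centre node is then pinned to zero,
    which is the physically symmetric choice.
    """
    if n_grid < 3:
        raise InvalidParameterError("n_grid must be >= 3")
    x = np.linspace(-0.5, 0.5, n_grid)
    h = x[1] - x[0]
    rho = _resample(bonds, x).density
    u0 = _resample(prestretch, x).displacement
    u0p = np.gradient(u0, x)
    u0pp = np.gradient(u0p, x)

    beta = params.stiffness_ratio
    diag = -2.0 / h**2 - beta * rho
    lower = np.full(n_grid, 1.0 / h**2)
    upper = np.full(n_grid, 1.0 / h**2)
    rhs = -u0pp.copy()
    # ghost-node elimination of the stress-free ends: u'(+-1/2) = -u0'
    upper_row0 = 2.0 / h**2
    lower_rowN = 2.0 / h**2
    rhs[0] += -2.0 * u0p[0] / h
    rhs[-1] += 2.0 * u0p[-1] / h

    ab = np.zeros((3, n_grid))
    ab[0, 1:] = upper[:-1]
    ab[0, 1] = upper_row0
    ab[1, :] = diag
    ab[2, :-1] = lower[1:]
    ab[2, -2] = lower_rowN

    if beta * float(np.max(rho, initial=0.0)) * h**2 <= _NULLSPACE_THRESHOLD:
        centre = (n_grid - 1) // 2
        ab[1, centre] = 1.0
        if centre + 1 < n_grid:
            ab[0, centre + 1] = 0.0
        if centre - 1 >= 0:
            ab[2, centre - 1] = 0.0
        rhs[centre] = 0.0

    u = solve_banded((1, 1), ab, rhs)
    strain = np.gradient(u, x)
    per_bond_force = np.where(rho > 0, beta * u, 0.0)
    return DisplacementProfile(x, u, strain, per_bond_force)


def contractile_force(
    profile: DisplacementProfile,
    params: DimensionlessParams,
    bonds: BondField,
    asymmetry_tolerance: float = 1e-6,
) -> float:
    """Total scaled traction transmitted over one half of the cell.

    For a symmetric configuration the two halves carry equal and
    opposite traction; the magnitude of the right-half integral
    ``-int_0^{1/2} beta rho u dx`` is returned.  A relative mismatch
    between the halves beyond ``asymmetry_tolerance`` is flagged with a
    warning but the right-half value is still returned.
    """
    x = profile.grid
    rho = _resample(bonds, x).density
    traction = params.stiffness_ratio * rho * profile.displacement
    right = -np.trapezoid(np.where(x >= 0, traction, 0.0), x)
    left = np.trapezoid(np.where(x <= 0, traction, 0.0), x)
    scale = max(abs(right), abs(left), 1e-300)
    if abs(right - left) / scale > asymmetry_tolerance:
        warnings.warn(
            f"asymmetric traction: right-half {right:.6g} vs left-half {left:.6g}",
            stacklevel=2,
        )
    return float(right)


def equilibrated_length(
    profile: DisplacementProfile, prestretch: PrestretchField
) -> float:
    """End-to-end scaled length of the attached configuration.

    The stretched, just-attached cell has unit length; the equilibrium
    length is ``1 + u(+1/2) - u(-1/2)`` and lies between the rest length
    ``1 - span(u0)`` (no substrate resistance) and 1 (rigid pinning).
    """
    return float(1.0 + profile.displacement[-1] - profile.displacement[0])


def profile_to_frame(profile: DisplacementProfile):
    """Export a profile as a pandas DataFrame (CSV-ready columns)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "x_scaled": profile.grid,
            "displacement": profile.displacement,
            "strain": profile.strain,
            "per_bond_force": profile.per_bond_force,
        }
    )
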