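"""Physical and dimensionless parameter types for the de-adhesion model.

The cell is a one-dimensional Kelvin--Voigt rod of spread length ``L``
(elastic modulus ``E_c``, viscous modulus ``eta_c``, cross-section
``height x width``) coupled to an elastic half-space substrate through a
continuum density of breakable bonds.  Each bond acts as a linear spring
whose stiffness is set by the substrate: a point force spread over a
circle of the bond-contact diameter ``a`` on a half-space of Young's
modulus ``E_s`` gives an effective spring constant proportional to
``a * E_s``.

All model dynamics run in scaled variables: positions live on the closed
interval [-1/2, +1/2] in units of the spread cell length, displacements
are scaled the same way, and time is measured in units of a reference
time metric (default 1 s).  The three control parameters that emerge are

* ``stiffness_ratio``  -- scaled effective substrate-to-cell stiffness,
  ``k_bond * rho0 * L**2 / (E_c * h * b)``;
* ``breakage_rate``    -- scaled first-order bond-severing rate;
* ``viscosity``        -- scaled internal relaxation time
  ``(eta_c / E_c) / T``.

A fourth constant, ``force_coupling``, multiplies the scaled per-bond
force inside the exponential of the Bell bond-rupture law; zero recovers
force-independent kinetics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import yaml

__all__ = [
    "InvalidParameterError",
    "ConfigError",
    "CellProperties",
    "SubstrateProperties",
    "BondField",
    "PrestretchField",
    "DimensionlessParams",
    "effective_bond_substrate_stiffness",
    "nondimensionalize",
    "redimensionalize",
    "params_from_dict",
    "load_config",
    "DEFAULT_POISSON_RATIO",
]


class InvalidParameterError(ValueError):
    """A physical or dimensionless parameter violates its invariants."""


class ConfigError(ValueError):
    """A configuration mapping failed strict validation."""


DEFAULT_POISSON_RATIO = 0.5


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (math.isfinite(value) and value > 0):
            raise InvalidParameterError(f"{name} must be finite and > 0, got {value!r}")


@dataclass(frozen=True)
class CellProperties:
    """Viscoelastic rod description of the cell.

    Parameters
    ----------
    elastic_modulus : float
        Elastic modulus of the cell, Pa.
    viscous_modulus : float
        Viscous modulus of the cell, Pa s.
    height, width : float
        Cross-section of the rod, m.
    rest_length : float
        Length of the relaxed (fully rounded) cell, m; also the length
        metric of the scaled model.
    """

    elastic_modulus: float
    viscous_modulus: float
    height: float
    width: float
    rest_length: float

    def __post_init__(self) -> None:
        _require_positive(
            elastic_modulus=self.elastic_modulus,
            viscous_modulus=self.viscous_modulus,
            height=self.height,
            width=self.width,
            rest_length=self.rest_length,
        )

    @property
    def relaxation_time(self) -> float:
        """Internal Kelvin--Voigt relaxation time ``eta_c / E_c`` (s)."""
        return self.viscous_modulus / self.elastic_modulus


@dataclass(frozen=True)
class SubstrateProperties:
    """Elastic half-space substrate contacted through discrete bonds."""

    youngs_modulus: float
    bond_contact_diameter: float = 25e-9
    poisson_ratio: float = DEFAULT_POISSON_RATIO

    def __post_init__(self) -> None:
        _require_positive(
            youngs_modulus=self.youngs_modulus,
            bond_contact_diameter=self.bond_contact_diameter,
        )
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise InvalidParameterError(
                f"poisson_ratio must lie in [0, 0.5], got {self.poisson_ratio!r}"
            )


@dataclass(frozen=True)
class DimensionlessParams:
    """Scaled control parameters of the de-adhesion model."""

    stiffness_ratio: float
    breakage_rate: float
    viscosity: float
    force_coupling: float = 0.0

    def __post_init__(self) -> None:
        _require_positive(stiffness_ratio=self.stiffness_ratio, viscosity=self.viscosity)
        if not (math.isfinite(self.breakage_rate) and self.breakage_rate >= 0):
            raise InvalidParameterError(
                f"breakage_rate must be finite and >= 0, got {self.breakage_rate!r}"
            )
        if not (math.isfinite(self.force_coupling) and self.force_coupling >= 0):
            raise InvalidParameterError(
                f"force_coupling must be finite and >= 0, got {self.force_coupling!r}"
            )

    def replace(self, **changes: float) -> "DimensionlessParams":
        return replace(self, **changes)


def _validate_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise InvalidParameterError("grid must be a 1-D array with >= 2 nodes")
    if not np.all(np.diff(grid) > 0):
        raise InvalidParameterError("grid must be strictly increasing")
    return grid


@dataclass(frozen=True)
class BondField:
    """Scaled bond density per scaled length on the cell domain."""

    grid: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        grid = _validate_grid(self.grid)
        density = np.asarray(self.density, dtype=float)
        if density.shape != grid.shape:
            raise InvalidParameterError("density and grid must have the same shape")
        if np.any(density < 0) or not np.all(np.isfinite(density)):
            raise InvalidParameterError("bond density must be finite and >= 0 everywhere")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "density", density)

    @property
    def total_bonds(self) -> float:
        """Trapezoidal integral of the density over the domain."""
        return float(np.trapezoid(self.density, self.grid))

    def resample(self, grid: np.ndarray) -> "BondField":
        grid = _validate_grid(grid)
        return BondField(grid, np.interp(grid, self.grid, self.density))

    # ---- named builders (Fig. 4c-style distribution comparisons) -------

    @classmethod
    def uniform(cls, total: float = 1.0, n: int = 201) -> "BondField":
        grid = np.linspace(-0.5, 0.5, n)
        return cls(grid, np.full(n, float(total)))

    @classmethod
    def peripheral_belt(
        cls, total: float = 1.0, belt_fraction: float = 0.2, n: int = 201
    ) -> "BondField":
        """Bonds confined to two smooth belts at the cell ends.

        ``belt_fraction`` is the fraction of the cell length occupied by
        each belt; the profile is a raised-cosine bump so that the
        density is continuous, and it is rescaled to conserve ``total``.
        """
        if not 0 < belt_fraction <= 0.5:
            raise InvalidParameterError("belt_fraction must lie in (0, 0.5]")
        grid = np.linspace(-0.5, 0.5, n)
        w = belt_fraction
        d = np.zeros(n)
        for edge in (-0.5, 0.5):
            s = np.abs(grid - edge)
            inside = s < w
            d[inside] += 0.5 * (1 + np.cos(np.pi * s[inside] / w))
        return cls(grid, d * (total / np.trapezoid(d, grid)))

    @classmethod
    def edge_concentrated(
        cls, total: float = 1.0, width: float = 0.05, n: int = 201
    ) -> "BondField":
        """Narrow Gaussian bond clusters at the two cell ends."""
        if not 0 < width <= 0.5:
            raise InvalidParameterError("width must lie in (0, 0.5]")
        grid = np.linspace(-0.5, 0.5, n)
        d = np.exp(-0.5 * ((grid + 0.5) / width) ** 2) + np.exp(
            -0.5 * ((grid - 0.5) / width) ** 2
        )
        return cls(grid, d * (total / np.trapezoid(d, grid)))


_BOND_BUILDERS: dict[str, Callable[..., BondField]] = {
    "uniform": BondField.uniform,
    "peripheral_belt": BondField.peripheral_belt,
    "edge_concentrated": BondField.edge_concentrated,
}


@dataclass(frozen=True)
class PrestretchField:
    """Imposed pre-stretch displacement field (contractility surrogate).

    The default builder is a pure linear contraction profile,
    antisymmetric about the cell centre, with displacement
    ``+edge_magnitude`` at the right end.
    """

    grid: np.ndarray
    displacement: np.ndarray

    def __post_init__(self) -> None:
        grid = _validate_grid(self.grid)
        displacement = np.asarray(self.displacement, dtype=float)
        if displacement.shape != grid.shape:
            raise InvalidParameterError("displacement and grid must have the same shape")
        if not np.all(np.isfinite(displacement)):
            raise InvalidParameterError("pre-stretch displacement must be finite")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "displacement", displacement)

    @property
    def edge_magnitude(self) -> float:
        return float(self.displacement[-1])

    @property
    def span(self) -> float:
        """Total imposed extension ``u0(+1/2) - u0(-1/2)``."""
        return float(self.displacement[-1] - self.displacement[0])

    def resample(self, grid: np.ndarray) -> "PrestretchField":
        grid = _validate_grid(grid)
        return PrestretchField(grid, np.interp(grid, self.grid, self.displacement))

    def scaled(self, factor: float) -> "PrestretchField":
        return PrestretchField(self.grid, self.displacement * factor)

    @classmethod
    def linear(cls, edge_magnitude: float = 0.01, n: int = 201) -> "PrestretchField":
        if edge_magnitude < 0:
            raise InvalidParameterError("edge_magnitude must be >= 0")
        grid = np.linspace(-0.5, 0.5, n)
        return cls(grid, 2.0 * edge_magnitude * grid)


def effective_bond_substrate_stiffness(
    substrate: SubstrateProperties, prefactor: float | None = None
) -> float:
    """Spring constant (N/m) of a single bond anchored in the substrate.

    A point force spread over a circle of the bond-contact diameter on an
    elastic half-space displaces the contact in proportion to the force;
    the resulting stiffness is linear in both the contact diameter and
    the substrate Young's modulus,

        ``k_bond = C * a * E_s``,  ``C = pi / (1 - nu**2)`` by default.

    Any constant prefactor only rescales the swept dimensionless
    stiffness ratio, so ``C`` is exposed for callers who prefer a
    different half-space convention.
    """
    if prefactor is None:
        prefactor = math.pi / (1.0 - substrate.poisson_ratio**2)
    if prefactor <= 0:
        raise InvalidParameterError("prefactor must be > 0")
    return prefactor * substrate.bond_contact_diameter * substrate.youngs_modulus


def nondimensionalize(
    cell: CellProperties,
    substrate: SubstrateProperties,
    bond_density_per_length: float,
    breakage_rate: float,
    force_scale: float,
    time_metric: float = 1.0,
    prefactor: float | None = None,
) -> DimensionlessParams:
    """Map physical inputs onto the scaled model parameters.

    Parameters
    ----------
    bond_density_per_length : float
        Linear density of cell-substrate bonds along the cell, 1/m.
    breakage_rate : float
        First-order bond-severing rate, 1/s.
    force_scale : float
        Bell force scale ``f0 = k_B T / x_beta`` of a single bond, N.
        The scaled force coupling is the ratio of the model's per-bond
        force unit ``E_c h b / (rho L)`` to ``f0``.
    time_metric : float
        Reference time T (s) used to scale rates and the viscosity.
    """
    _require_positive(
        bond_density_per_length=bond_density_per_length,
        force_scale=force_scale,
        time_metric=time_metric,
    )
    if breakage_rate < 0 or not math.isfinite(breakage_rate):
        raise InvalidParameterError("breakage_rate must be finite and >= 0")
    k_bond = effective_bond_substrate_stiffness(substrate, prefactor=prefactor)
    section = cell.elastic_modulus * cell.height * cell.width
    stiffness_ratio = (
        k_bond * bond_density_per_length * cell.rest_length**2 / section
    )
    return DimensionlessParams(
        stiffness_ratio=stiffness_ratio,
        breakage_rate=breakage_rate * time_metric,
        viscosity=cell.relaxation_time / time_metric,
        force_coupling=section / (bond_density_per_length * cell.rest_length * force_scale),
    )


def redimensionalize(
    params: DimensionlessParams,
    cell: CellProperties,
    substrate: SubstrateProperties,
    time_metric: float = 1.0,
    prefactor: float | None = None,
) -> dict[str, float]:
    """Invert :func:`nondimensionalize` given the same cell/substrate.

    Returns the physical ``bond_density_per_length``, ``breakage_rate``
    and ``force_scale`` that reproduce ``params``.
    """
    k_bond = effective_bond_substrate_stiffness(substrate, prefactor=prefactor)
    section = cell.elastic_modulus * cell.height * cell.width
    rho = params.stiffness_ratio * section / (k_bond * cell.rest_length**2)
    return {
        "bond_density_per_length": rho,
        "breakage_rate": params.breakage_rate / time_metric,
        "force_scale": section / (rho * cell.rest_length * params.force_coupling)
        if params.force_coupling > 0
        else math.inf,
    }


# --------------------------------------------------------------------------
# strict configuration handling


_PARAM_KEYS = {"stiffness_ratio", "breakage_rate", "viscosity", "force_coupling"}


def params_from_dict(mapping: dict) -> DimensionlessParams:
    """Build :class:`DimensionlessParams` from a mapping, fail-fast.

    Unknown keys are an error so that typos in configuration files do
    not silently fall back to defaults.
    """
    unknown = set(mapping) - _PARAM_KEYS
    if unknown:
        raise ConfigError(
            f"unknown parameter keys: {sorted(unknown)}; expected a subset of "
            f"{sorted(_PARAM_KEYS)}"
        )
    missing = {"stiffness_ratio", "breakage_rate", "viscosity"} - set(mapping)
    if missing:
        raise ConfigError(f"missing required parameter keys: {sorted(missing)}")
    try:
        return DimensionlessParams(**{k: float(v) for k, v in mapping.items()})
    except (TypeError, ValueError) as exc:
        if isinstance(exc, InvalidParameterError):
            raise
        raise ConfigError(f"non-numeric parameter value: {exc}") from exc


def bond_field_from_config(mapping: dict, n: int = 201) -> BondField:
    """Build a named bond distribution from ``{"kind": ..., **kwargs}``."""
    mapping = dict(mapping)
    kind = mapping.pop("kind", "uniform")
    if kind not in _BOND_BUILDERS:
        raise ConfigError(
            f"unknown bond distribution {kind!r}; choose from {sorted(_BOND_BUILDERS)}"
        )
    builder = _BOND_BUILDERS[kind]
    allowed = {
        "uniform": {"total"},
        "peripheral_belt": {"total", "belt_fraction"},
        "edge_concentrated": {"total", "width"},
    }[kind]
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown keys for {kind!r} distribution: {sorted(unknown)}")
    return builder(n=n, **{k: float(v) for k, v in mapping.items()})


def load_config(path: str | Path) -> dict:
    """Load a JSON (canonical) or YAML configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ConfigError(f"configuration root must be a mapping, got {type(data).__name__}")
    return data
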