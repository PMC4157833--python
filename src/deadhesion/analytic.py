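"""Approximate closed-form de-adhesion timescales (force-independent model).

For uniform bond density the static displacement of the attached cell
has the constant-coefficient closed form ``u(x) = -s sinh(kx)/(k
cosh(k/2))`` with ``k**2 = beta * rho`` and pre-strain ``s``.  Its
end-to-end contraction is governed by

    g(k) = 2 tanh(k/2) / k,        g(0) = 1,  g(k) ~ 2/k for large k,

so the normalized retraction under slow bond decay ("quasistatic"
regime: the cell tracks its equilibrium while ``k(t) = k0
exp(-gamma t / 2)`` shrinks) is

    ell(t) = (g(k(t)) - g(k0)) / (1 - g(k0)).

Inverting the threshold crossings of ``ell`` gives the bond-decay
contribution to ``tau1`` (half-saturation) and ``tau2`` (0.5-to-0.9
interval, rescaled by ``ln 9``); for ``k0 >= 8`` the large-``k``
asymptote yields the explicit logarithmic form ``tau1 ~ (2/gamma)
ln(k0/4)``, i.e. a dependence on the logarithm of stiffness.  In the
opposite fast-breakage regime the bonds vanish before the cell moves
and the retraction is the free Kelvin--Voigt relaxation, giving the
stiffness-independent limits ``tau1 = eta ln 2`` and ``tau2 = eta ln 5
/ ln 9``.

The two contributions act in series (bonds must decay, then the rod
must relax), so the estimates combine them additively with the
quasistatic term attenuated by ``exp(-(gamma*eta)**2)``, which removes
it smoothly once breakage outpaces relaxation.  The ``validity`` flag
marks the parameter regions where either mechanism clearly dominates
(``gamma*eta <= 0.1`` or ``>= 3``); in between both matter comparably
and the composite estimate is only indicative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .params import DimensionlessParams, InvalidParameterError

__all__ = [
    "RegimeEstimate",
    "NoEstimateError",
    "tau1_estimate",
    "tau2_estimate",
    "log_stiffness_sensitivity",
    "QUASISTATIC_MAX",
    "FAST_BREAKAGE_MIN",
    "CLOSED_FORM_MIN_K0",
]

#: gamma*eta at or below which bond decay dominates (quasistatic regime)
QUASISTATIC_MAX = 0.1
#: gamma*eta at or above which relaxation dominates (fast-breakage regime)
FAST_BREAKAGE_MIN = 3.0
#: k0 = sqrt(beta*rho) above which the explicit logarithmic closed form
#: replaces the implicit threshold equation
CLOSED_FORM_MIN_K0 = 8.0

_LN9 = math.log(9.0)


class NoEstimateError(RuntimeError):
    """Root bracketing for the implicit threshold equation failed."""


@dataclass(frozen=True)
class RegimeEstimate:
    """An analytic timescale with its provenance.

    ``regime_label`` names the dominant mechanism the expression
    captures; ``validity`` is False between the regimes, where no
    printed expression applies cleanly, and the label then carries a
    nearest-regime hint.
    """

    tau: float
    regime_label: str
    validity: bool


def _g(k: float) -> float:
    """End-to-end contraction factor 2 tanh(k/2)/k, series-safe at 0."""
    if k < 1e-6:
        return 1.0 - k * k / 12.0
    return 2.0 * math.tanh(0.5 * k) / k


def _invert_g(target: float, k_hi: float) -> float:
    """Solve g(k) = target for k in (0, k_hi]; g decreases in k."""
    if target >= 1.0:
        return 0.0
    lo = 1e-12
    if _g(k_hi) > target:  # pragma: no cover - defensive; g(k0) < target always
        raise NoEstimateError(f"target {target} not bracketed on (0, {k_hi}]")
    return brentq(lambda k: _g(k) - target, lo, k_hi, xtol=1e-14, rtol=1e-14)


def _quasistatic_crossing_k(params: DimensionlessParams, level: float) -> float:
    """k at which the quasistatic retraction reaches ``level``."""
    k0 = math.sqrt(params.stiffness_ratio)
    g0 = _g(k0)
    return _invert_g(g0 + level * (1.0 - g0), k0)


def _check_force_independent(params: DimensionlessParams) -> None:
    if params.force_coupling != 0:
        raise InvalidParameterError(
            "analytic estimates are derived for the force-independent model "
            "(force_coupling = 0)"
        )


def _regime(params: DimensionlessParams) -> tuple[str, bool]:
    z = params.breakage_rate * params.viscosity
    if z <= QUASISTATIC_MAX:
        return "quasistatic", True
    if z >= FAST_BREAKAGE_MIN:
        return "fast_breakage", True
    return "intermediate (nearest: quasistatic)" if z < 1 else (
        "intermediate (nearest: fast_breakage)"
    ), False


def _blend_weight(params: DimensionlessParams) -> float:
    z = params.breakage_rate * params.viscosity
    return math.exp(-min(z * z, 745.0))


def tau1_estimate(
    params: DimensionlessParams, method: str = "auto"
) -> RegimeEstimate:
    """Analytic half-saturation time of the de-adhesion curve.

    ``method`` selects the quasistatic branch: ``"closed_form"`` forces
    the explicit logarithmic expression ``(2/gamma) ln(k0/g*)`` (the
    large-``k0`` asymptote), ``"implicit"`` forces the bracketed root
    solve of the threshold equation, ``"auto"`` picks the closed form
    for ``k0 >= 8``.
    """
    _check_force_independent(params)
    if method not in ("auto", "closed_form", "implicit"):
        raise InvalidParameterError("method must be auto, closed_form or implicit")
    gamma = params.breakage_rate
    eta = params.viscosity
    relax = eta * math.log(2.0)
    if gamma == 0:
        return RegimeEstimate(math.inf, "no breakage (tau diverges)", False)

    k0 = math.sqrt(params.stiffness_ratio)
    if method == "closed_form" or (method == "auto" and k0 >= CLOSED_FORM_MIN_K0):
        # g ~ 2/k asymptote: crossing at g* = g0 + (1 - g0)/2 ~ 1/2
        g0 = 2.0 / k0
        g_star = g0 + 0.5 * (1.0 - g0)
        k_star = 2.0 / g_star
        label = "quasistatic/closed_form"
    else:
        k_star = _quasistatic_crossing_k(params, 0.5)
        label = "quasistatic/implicit"
    tau_qs = (2.0 / gamma) * math.log(k0 / k_star) if k_star < k0 else 0.0
    tau_qs = max(tau_qs, 0.0)

    w = _blend_weight(params)
    regime, valid = _regime(params)
    if regime == "fast_breakage":
        label = "fast_breakage"
    elif not valid:
        label = regime
    return RegimeEstimate(relax + w * tau_qs, label, valid)


def tau2_estimate(
    params: DimensionlessParams, method: str = "auto"
) -> RegimeEstimate:
    """Analytic sigmoid-width timescale (0.5-to-0.9 interval / ln 9).

    In the fast-breakage limit this reduces to the explicit,
    stiffness-independent expression ``eta ln 5 / ln 9``: the curve is
    a single exponential with the cell's internal relaxation time.
    ``method="closed_form"`` returns that explicit limit directly; the
    quasistatic contribution has no useful explicit form because the
    0.9-crossing always falls in the small-``k`` tail, so ``"auto"``
    and ``"implicit"`` both solve the threshold equation for it.
    """
    _check_force_independent(params)
    if method not in ("auto", "closed_form", "implicit"):
        raise InvalidParameterError("method must be auto, closed_form or implicit")
    gamma = params.breakage_rate
    eta = params.viscosity
    relax = eta * math.log(5.0) / _LN9
    if gamma == 0:
        return RegimeEstimate(math.inf, "no breakage (tau diverges)", False)

    if method == "closed_form":
        regime, _ = _regime(params)
        return RegimeEstimate(relax, "fast_breakage/closed_form", regime == "fast_breakage")

    k0 = math.sqrt(params.stiffness_ratio)
    k_half = _quasistatic_crossing_k(params, 0.5)
    k_ninety = _quasistatic_crossing_k(params, 0.9)
    label = "quasistatic/implicit"
    tau_qs = (2.0 / (gamma * _LN9)) * math.log(max(k_half, 1e-300) / max(k_ninety, 1e-300))
    tau_qs = max(tau_qs, 0.0)

    w = _blend_weight(params)
    regime, valid = _regime(params)
    if regime == "fast_breakage":
        label = "fast_breakage"
    elif not valid:
        label = regime
    return RegimeEstimate(relax + w * tau_qs, label, valid)


def log_stiffness_sensitivity(
    stiffness_lo: float, stiffness_hi: float, params: DimensionlessParams
) -> float:
    """Fractional change of tau1 between two stiffness ratios.

    Returns ``(tau1(lo) - tau1(hi)) / tau1(lo)`` from the analytic
    estimate.  Because tau1 grows only with the logarithm of the
    stiffness ratio in the quasistatic regime, even large stiffness
    changes produce modest fractional changes; the sign is negative for
    ``hi > lo`` (stiffer substrates de-adhere more slowly in the
    force-independent model).
    """
    if stiffness_lo <= 0 or stiffness_hi <= 0:
        raise InvalidParameterError("stiffness ratios must be > 0")
    est_lo = tau1_estimate(params.replace(stiffness_ratio=stiffness_lo))
    est_hi = tau1_estimate(params.replace(stiffness_ratio=stiffness_hi))
    if not (est_lo.validity and est_hi.validity):
        return math.nan
    return (est_lo.tau - est_hi.tau) / est_lo.tau
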