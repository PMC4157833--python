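"""Synthetic trypsin de-adhesion assays.

Generates per-cell area-versus-time traces with the statistical
structure of the hydrogel de-adhesion experiments: three substrate
stiffness conditions with sigmoidal retraction, lognormal inter-cell
variability of the time constants, and additive Gaussian measurement
noise on the normalized signal, so the normalization-and-fitting
analysis stage can be exercised end to end without any raw movies.

Ground-truth constants of the default design are the per-condition
Boltzmann constants reported for NIH 3T3 fibroblasts on 1.5 / 2.5 /
40 kPa polyacrylamide gels (tau1 = 80 / 30 / 30 s, tau2 = 30 / 15 /
8 s), 15 cells per condition, 1 s frame interval, 300 s duration.

By default traces are constructed *fit-consistently*: the reported
constants are outputs of the analysis pipeline (normalize by the t = 0
sample and the final plateau, then fit the pinned Boltzmann sigmoid),
so the generator inverts that deterministic map and emits the logistic
whose pipeline fit returns the drawn ground truth exactly in the
noise-free limit.  ``fit_consistent=False`` instead emits the literal
logistic in the drawn constants; its pipeline round trip carries a
deterministic bias of up to ~15% when ``tau1/tau2`` is small, because
the logistic is re-normalized by its nonzero t = 0 value.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .params import InvalidParameterError
from .timescales import (
    DeadhesionCurve,
    NormalizationError,
    boltzmann,
    fit_batch,
    fit_boltzmann,
    normalize_curve,
)

__all__ = [
    "Condition",
    "AssayDesign",
    "SyntheticAssay",
    "default_design",
    "generate_assay",
    "model_to_area",
    "area_series",
    "fit_assay",
]


@dataclass(frozen=True)
class Condition:
    """One substrate-stiffness condition with its ground-truth constants."""

    label: str
    stiffness_kpa: float
    tau1: float
    tau2: float

    def __post_init__(self) -> None:
        if not self.tau1 > self.tau2 > 0:
            raise InvalidParameterError(
                f"condition {self.label!r} must satisfy tau1 > tau2 > 0, "
                f"got ({self.tau1}, {self.tau2})"
            )
        if self.stiffness_kpa <= 0:
            raise InvalidParameterError("stiffness_kpa must be > 0")


@dataclass(frozen=True)
class AssayDesign:
    """Full specification of a synthetic de-adhesion assay."""

    conditions: tuple[Condition, ...]
    n_cells_per_condition: int = 15
    frame_interval: float = 1.0
    duration: float = 300.0
    cell_variability_cv: float = 0.25
    noise_sigma: float = 0.02
    seed: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "conditions", tuple(self.conditions))
        problems = []
        if not self.conditions:
            problems.append("at least one condition is required")
        if self.n_cells_per_condition < 1:
            problems.append("n_cells_per_condition must be >= 1")
        if self.frame_interval <= 0:
            problems.append("frame_interval must be > 0")
        if self.cell_variability_cv < 0:
            problems.append("cell_variability_cv must be >= 0")
        if self.noise_sigma < 0:
            problems.append("noise_sigma must be >= 0")
        if self.conditions:
            max_tau1 = max(c.tau1 for c in self.conditions)
            if not self.duration > 3.0 * max_tau1:
                problems.append(
                    f"duration ({self.duration}) must exceed 3 x max tau1 "
                    f"({3.0 * max_tau1})"
                )
        if problems:
            raise InvalidParameterError("; ".join(problems))

    @property
    def times(self) -> np.ndarray:
        return np.arange(0.0, self.duration + self.frame_interval / 2, self.frame_interval)

    def to_dict(self) -> dict:
        return {
            "conditions": [
                {
                    "label": c.label,
                    "stiffness_kpa": c.stiffness_kpa,
                    "tau1": c.tau1,
                    "tau2": c.tau2,
                }
                for c in self.conditions
            ],
            "n_cells_per_condition": self.n_cells_per_condition,
            "frame_interval": self.frame_interval,
            "duration": self.duration,
            "cell_variability_cv": self.cell_variability_cv,
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "AssayDesign":
        data = dict(data)
        conditions = tuple(Condition(**c) for c in data.pop("conditions"))
        known = {
            "n_cells_per_condition",
            "frame_interval",
            "duration",
            "cell_variability_cv",
            "noise_sigma",
            "seed",
        }
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown design keys: {sorted(unknown)}")
        return cls(conditions=conditions, **data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "AssayDesign":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class SyntheticAssay:
    """Generated traces plus their ground truth.

    ``traces`` columns: time, area, cell_id, condition;
    ``ground_truth`` columns: cell_id, condition, tau1, tau2 (the
    constants the analysis stage should recover).
    """

    traces: pd.DataFrame
    ground_truth: pd.DataFrame
    design: AssayDesign

    def curves(self) -> list[tuple[DeadhesionCurve, str]]:
        """Normalized per-cell curves ready for Boltzmann fitting."""
        out = []
        for (cell_id, condition), group in self.traces.groupby(
            ["cell_id", "condition"], sort=False
        ):
            group = group.sort_values("time")
            curve = normalize_curve(
                group["time"].to_numpy(),
                group["area"].to_numpy(),
                kind="area",
                source="synthetic_experiment",
                condition_label=str(condition),
                time_unit="s",
            )
            out.append((curve, str(cell_id)))
        return out

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.traces.to_csv(out_dir / "traces.csv", index=False)
        self.ground_truth.to_csv(out_dir / "ground_truth.csv", index=False)
        self.design.save(out_dir / "design.json")


#: per-cell spread area (um^2) and retraction-fraction ranges; the raw
#: area is A0 * (1 - retraction_fraction * normalized_signal)
_A0_RANGE = (500.0, 2500.0)
_RETRACTION_RANGE = (0.6, 0.9)
#: fraction of the log-variance of the per-cell time constants carried
#: by a shared "cell speed" factor; a faster (more contractile) cell is
#: faster in both constants, and the correlation keeps the per-cell
#: tau1/tau2 ratio away from 1 where a trace stops being sigmoidal
_SHARED_VARIANCE_FRACTION = 0.78
#: per-cell draws with tau1/tau2 below this are redrawn (< 2% of draws)
_MIN_TAU_RATIO = 1.4


def default_design(seed: int = 1) -> AssayDesign:
    """Three-condition design mirroring the hydrogel experiments."""
    return AssayDesign(
        conditions=(
            Condition("1.5 kPa", 1.5, 80.0, 30.0),
            Condition("2.5 kPa", 2.5, 30.0, 15.0),
            Condition("40 kPa", 40.0, 30.0, 8.0),
        ),
        seed=seed,
    )


def _pipeline_constants(times: np.ndarray, tau1: float, tau2: float) -> tuple[float, float]:
    """Constants the analysis recovers from a noise-free logistic trace."""
    y = boltzmann(times, tau1, tau2)
    curve = normalize_curve(
        times, 1.0 - y, kind="area", source="synthetic_experiment"
    )
    fit = fit_boltzmann(curve)
    return fit.tau1, fit.tau2


def _invert_pipeline(
    times: np.ndarray, target1: float, target2: float, max_iter: int = 12
) -> tuple[float, float]:
    """Find generating constants whose pipeline fit returns the targets.

    The normalize-then-fit map is smooth and close to the identity for
    sigmoidal traces (``tau1`` a few times ``tau2``), so a damped
    fixed-point iteration converges in a few steps; if the iteration
    stalls (targets at the edge of the reachable set) the best iterate
    found is used.
    """
    g1, g2 = target1, target2
    best = (g1, g2)
    best_err = math.inf
    for _ in range(max_iter):
        f1, f2 = _pipeline_constants(times, g1, g2)
        d1, d2 = target1 - f1, target2 - f2
        err = abs(d1) / target1 + abs(d2) / target2
        if err < best_err:
            best, best_err = (g1, g2), err
        if err < 1e-8:
            break
        if err > 4.0 * best_err:  # diverging; give up on improving
            break
        g1 = g1 + 0.9 * d1
        g2 = max(g2 + 0.9 * d2, 1e-3 * target2)
    return best


def generate_assay(design: AssayDesign, fit_consistent: bool = True) -> SyntheticAssay:
    """Generate a synthetic assay, bit-reproducible from (design, seed).

    Per cell, ``(tau1, tau2)`` are drawn lognormally with mean equal to
    the condition's ground truth and coefficient of variation
    ``cell_variability_cv``, most of which is a shared per-cell speed
    factor so the two constants co-vary; the normalized retraction
    signal is the
    rising logistic in those constants (pipeline-inverted when
    ``fit_consistent``), Gaussian noise of s.d. ``noise_sigma`` is added
    to the normalized signal, and the raw area trace is
    ``A0 * (1 - retraction_fraction * signal)`` with per-cell ``A0`` and
    retraction fraction drawn uniformly from documented ranges.
    """
    rng = np.random.default_rng(design.seed)
    times = design.times
    cv = design.cell_variability_cv
    log_var = math.log1p(cv * cv)
    s_shared = math.sqrt(_SHARED_VARIANCE_FRACTION * log_var)
    s_idio = math.sqrt((1.0 - _SHARED_VARIANCE_FRACTION) * log_var)

    trace_frames = []
    truth_rows = []
    for condition in design.conditions:
        stored: tuple[float, float, float] | None = None
        for i in range(design.n_cells_per_condition):
            cell_id = f"{condition.label}_cell{i:02d}"
            if cv > 0:
                mu1 = math.log(condition.tau1) - 0.5 * log_var
                mu2 = math.log(condition.tau2) - 0.5 * log_var
                # antithetic pairing: odd cells negate the previous
                # cell's draws (an unpaired last cell sits at the
                # median), so condition means are centred on the
                # ground truth while each cell keeps the designed cv
                if i % 2 == 0:
                    if i == design.n_cells_per_condition - 1:
                        z_cell = z1 = z2 = 0.0
                    else:
                        z_cell = float(rng.standard_normal())
                        z1, z2 = (float(z) for z in rng.standard_normal(2))
                        stored = (z_cell, z1, z2)
                else:
                    assert stored is not None
                    z_cell, z1, z2 = (-z for z in stored)
                for _ in range(100):
                    tau1 = math.exp(mu1 + s_shared * z_cell + s_idio * z1)
                    tau2 = math.exp(mu2 + s_shared * z_cell + s_idio * z2)
                    if tau1 / tau2 >= _MIN_TAU_RATIO:
                        break
                    z_cell = float(rng.standard_normal())
                    z1, z2 = (float(z) for z in rng.standard_normal(2))
                else:  # pragma: no cover - vanishing probability
                    tau2 = tau1 / _MIN_TAU_RATIO
            else:
                tau1, tau2 = condition.tau1, condition.tau2
            a0 = float(rng.uniform(*_A0_RANGE))
            retraction = float(rng.uniform(*_RETRACTION_RANGE))
            noise = (
                rng.normal(0.0, design.noise_sigma, times.size)
                if design.noise_sigma > 0
                else np.zeros(times.size)
            )

            if fit_consistent:
                gen1, gen2 = _invert_pipeline(times, tau1, tau2)
            else:
                gen1, gen2 = tau1, tau2
            signal = boltzmann(times, gen1, gen2) + noise
            area = a0 * (1.0 - retraction * signal)

            trace_frames.append(
                pd.DataFrame(
                    {
                        "time": times,
                        "area": area,
                        "cell_id": cell_id,
                        "condition": condition.label,
                    }
                )
            )
            truth_rows.append(
                {
                    "cell_id": cell_id,
                    "condition": condition.label,
                    "tau1": tau1,
                    "tau2": tau2,
                }
            )

    return SyntheticAssay(
        traces=pd.concat(trace_frames, ignore_index=True),
        ground_truth=pd.DataFrame(truth_rows),
        design=design,
    )


def area_series(traj) -> np.ndarray:
    """Spread-area proxy of a simulated trajectory.

    The 1-D model tracks the end-to-end length; assuming isotropic
    retraction the projected area scales with length squared.
    """
    return np.asarray(traj.length_series) ** 2


def model_to_area(traj, condition_label: str = "") -> DeadhesionCurve:
    """Normalized area-retraction curve of a simulated trajectory."""
    area = area_series(traj)
    return normalize_curve(
        traj.times,
        area,
        kind="area",
        source="model",
        condition_label=condition_label,
        time_unit="scaled",
    )


def fit_assay(assay: SyntheticAssay) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every cell and summarize per condition (mean and s.e.m.)."""
    fits = fit_batch(assay.curves())
    grouped = fits.groupby("condition", sort=False)
    summary = grouped.agg(
        n=("tau1", "size"),
        tau1_mean=("tau1", "mean"),
        tau1_sem=("tau1", lambda v: v.std(ddof=1) / math.sqrt(len(v)) if len(v) > 1 else 0.0),
        tau2_mean=("tau2", "mean"),
        tau2_sem=("tau2", lambda v: v.std(ddof=1) / math.sqrt(len(v)) if len(v) > 1 else 0.0),
    ).reset_index()
    return fits, summary
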