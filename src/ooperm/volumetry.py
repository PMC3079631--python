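"""Slope-based permeability estimators on volume trajectories.

Pf from hypotonic swelling, Ps from isotonic solute substitution, and the
early-window linear Lp estimate under a hypertonic impermeant step.  All
slopes come from ordinary least squares on the requested time window; a
two-point mode is kept for oracle tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from .constants import DEFAULT_CONSTANTS, MOSM_TO_OSMOL_PER_CM3, UM_TO_CM, PhysicalConstants
from .model import BathSolution, OocyteGeometry, VolumeTrajectory

__all__ = [
    "SlopeWindow",
    "PermeabilityResult",
    "BatchSummary",
    "compute_pf",
    "compute_ps",
    "estimate_lp_linear",
    "summarize_batch",
    "PF_WINDOW",
    "PS_WINDOW",
]

#: Default Pf window: first 20 s of hypotonic swelling.
PF_WINDOW_END = 20.0 / 60.0
#: Default Ps window: first 1 min of isotonic substitution.
PS_WINDOW_END = 1.0


@dataclass(frozen=True)
class SlopeWindow:
    """Half-open time window [t_start, t_end] (minutes) for a linear fit."""

    t_start: float
    t_end: float
    fit_kind: Literal["ols", "two_point"] = "ols"

    def __post_init__(self) -> None:
        if self.t_start < 0 or self.t_end <= self.t_start:
            raise ValueError("require t_end > t_start >= 0")

    def select(self, traj: VolumeTrajectory) -> np.ndarray:
        mask = (traj.times >= self.t_start - 1e-12) & (
            traj.times <= self.t_end + 1e-12
        )
        idx = np.flatnonzero(mask)
        if idx.size < 2:
            raise ValueError("window contains fewer than 2 samples")
        return idx


PF_WINDOW = SlopeWindow(0.0, PF_WINDOW_END)
PS_WINDOW = SlopeWindow(0.0, PS_WINDOW_END)


@dataclass
class PermeabilityResult:
    """A single permeability estimate with its fit diagnostics.

    ``value`` is in cm/min for Pf/Ps and um/(min*atm) for Lp.
    """

    value: float
    kind: Literal["Pf", "Ps", "Lp"]
    window: SlopeWindow
    slope: float  # d(rel_volume)/dt for Pf/Ps, dV/dt (cm^3/min) for Lp
    r_squared: float
    n_samples: int
    solute_id: str = ""
    oocyte_id: str = ""

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")


def _fit_slope(
    t: np.ndarray, y: np.ndarray, kind: str
) -> tuple[float, float]:
    """Return (slope, R^2) of y against t."""
    if kind == "two_point":
        slope = (y[-1] - y[0]) / (t[-1] - t[0])
        return slope, 1.0
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), r2


def compute_pf(
    traj: VolumeTrajectory,
    geom: OocyteGeometry,
    osm_in: float,
    osm_out: float,
    window: SlopeWindow = PF_WINDOW,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    solute_id: str = "water",
) -> PermeabilityResult:
    """Osmotic water permeability from the initial swelling slope:

        Pf = V0 * d(V/V0)/dt / (S * Vw * (Osm_in - Osm_out))

    ``osm_in``/``osm_out`` are internal/bath osmolarities in mOsm; the
    gradient is converted to mol/cm^3.  Swelling under a hypotonic bath
    (osm_in > osm_out) yields Pf > 0.  Uses the folded membrane area S.
    """
    if osm_in == osm_out:
        raise ValueError("osmotic gradient is zero")
    idx = window.select(traj)
    slope, r2 = _fit_slope(
        traj.times[idx], traj.rel_volumes[idx], window.fit_kind
    )
    d_osm = (osm_in - osm_out) * MOSM_TO_OSMOL_PER_CM3
    pf = traj.V0 * slope / (geom.S * constants.Vw * d_osm)
    if pf < -1e-12:
        warnings.warn(
            "negative Pf estimate: trajectory slope opposes the osmotic "
            "gradient (trace drift?)",
            stacklevel=2,
        )
    return PermeabilityResult(
        value=pf,
        kind="Pf",
        window=window,
        slope=slope,
        r_squared=r2,
        n_samples=idx.size,
        solute_id=solute_id,
    )


def compute_ps(
    traj: VolumeTrajectory,
    geom: OocyteGeometry,
    window: SlopeWindow = PS_WINDOW,
    solute_id: str = "",
) -> PermeabilityResult:
    """Solute permeability from isotonic-substitution swelling:

        Ps = d(V/V0)/dt / (S / V0)

    Reported in cm/min (tables conventionally print x10^-3 cm/min).
    """
    idx = window.select(traj)
    slope, r2 = _fit_slope(
        traj.times[idx], traj.rel_volumes[idx], window.fit_kind
    )
    ps = slope / (geom.S / traj.V0)
    return PermeabilityResult(
        value=ps,
        kind="Ps",
        window=window,
        slope=slope,
        r_squared=r2,
        n_samples=idx.size,
        solute_id=solute_id,
    )


def estimate_lp_linear(
    traj: VolumeTrajectory,
    geom: OocyteGeometry,
    bath: BathSolution,
    t_cutoff: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    osm_iso: float = 200.0,
    fit_kind: Literal["ols", "two_point"] = "ols",
) -> PermeabilityResult:
    """Early-window hydraulic conductivity under an impermeant hypertonic
    step, from the linear-fit slope of absolute volume over [0, t_cutoff]
    and the *initial* osmotic gradient:

        Lp = -dV/dt / (S * RT * (osm_bath - osm_iso))

    This is the secant estimate (the gradient decays as the cell
    shrinks); a model-based refit via :func:`ooperm.kkfit.fit_kk` is the
    bias-free alternative.  Returned in um/(min*atm); uses the folded
    area S.
    """
    if bath.conc_permeant > 0:
        raise ValueError("estimate_lp_linear requires an impermeant-only bath")
    if t_cutoff > traj.times[-1] + 1e-12:
        raise ValueError("t_cutoff lies beyond the trajectory")
    window = SlopeWindow(0.0, t_cutoff, fit_kind=fit_kind)
    idx = window.select(traj)
    slope_abs, r2 = _fit_slope(
        traj.times[idx], traj.rel_volumes[idx] * traj.V0, window.fit_kind
    )
    d_osm = (bath.osm_impermeant - osm_iso) * MOSM_TO_OSMOL_PER_CM3
    if d_osm <= 0:
        raise ValueError("bath must be hypertonic relative to osm_iso")
    lp_cm = -slope_abs / (geom.S * constants.RT * d_osm)
    if lp_cm < -1e-12:
        warnings.warn("negative Lp estimate: cell swelled under hypertonic bath")
    return PermeabilityResult(
        value=lp_cm / UM_TO_CM,
        kind="Lp",
        window=window,
        slope=slope_abs,
        r_squared=r2,
        n_samples=idx.size,
        solute_id=bath.permeant_id,
    )


@dataclass
class BatchSummary:
    mean: float
    sem: Optional[float]
    n: int
    control_mean: float
    fold_change: float


def summarize_batch(
    results: Sequence[PermeabilityResult | float],
    control_results: Sequence[PermeabilityResult | float],
) -> BatchSummary:
    """Mean, SEM (sd/sqrt(n), sample sd) and fold change vs control."""

    def values(seq: Sequence[PermeabilityResult | float]) -> np.ndarray:
        out = np.asarray(
            [r.value if isinstance(r, PermeabilityResult) else float(r) for r in seq]
        )
        if out.size == 0:
            raise ValueError("empty result list")
        return out

    vals = values(results)
    ctrl = values(control_results)
    control_mean = float(ctrl.mean())
    if control_mean == 0:
        raise ValueError("control mean is zero; fold change undefined")
    sem = (
        float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else None
    )
    return BatchSummary(
        mean=float(vals.mean()),
        sem=sem,
        n=int(vals.size),
        control_mean=control_mean,
        fold_change=float(vals.mean()) / control_mean,
    )
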