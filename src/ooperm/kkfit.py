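"""Nonlinear estimation of (Lp, Ps, sigma) from a shrink-swell trajectory
under a known hypertonic protocol.

Bounded trust-region least squares on relative volume, with a fixed
deterministic multistart grid; standard errors come from Gauss-Newton
curvature at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .model import (
    AreaBasis,
    BathSolution,
    KKParameters,
    OocyteGeometry,
    SimulationError,
    VolumeTrajectory,
    simulate,
)

__all__ = ["FitSpec", "FitResult", "FitError", "fit_kk", "profile_identifiability"]

PARAM_ORDER = ("Lp", "Ps", "sigma")

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "Lp": (0.0, 100.0),   # um/(min*atm)
    "Ps": (0.0, 1.0),     # cm/min
    "sigma": (0.0, 1.0),
}


class FitError(RuntimeError):
    """Raised when no multistart converges or the problem is degenerate."""


@dataclass(frozen=True)
class FitSpec:
    """Which parameters are free, their bounds, and how starts are chosen.

    ``fixed`` supplies values for parameters not in ``free``.  If
    ``initial`` is given it is used as the first start; the remaining
    starts come from a fixed grid over the bounds, so fits are fully
    deterministic.
    """

    free: tuple[str, ...] = ("Lp", "Ps", "sigma")
    fixed: Mapping[str, float] = field(default_factory=dict)
    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    initial: Optional[Mapping[str, float]] = None
    n_multistarts: int = 8
    loss_rtol: float = 1e-12

    def __post_init__(self) -> None:
        if not self.free:
            raise ValueError("at least one parameter must be free")
        for p in self.free:
            if p not in PARAM_ORDER:
                raise ValueError(f"unknown parameter {p!r}")
        for p in PARAM_ORDER:
            if p not in self.free and p not in self.fixed:
                raise ValueError(f"parameter {p!r} is neither free nor fixed")
        if self.n_multistarts < 1:
            raise ValueError("n_multistarts must be >= 1")
        if self.initial is not None:
            for p in self.free:
                lo, hi = self.bounds[p]
                x0 = self.initial[p]
                if not lo <= x0 <= hi:
                    raise ValueError(f"initial guess for {p} outside bounds")


@dataclass
class FitResult:
    params: KKParameters
    residual_norm: float          # sqrt(sum of squared residuals)
    std_errors: dict[str, float]  # Gauss-Newton SEs for the free parameters
    converged: bool
    n_multistarts_converged: int
    n_samples: int
    free: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.residual_norm < 0:
            raise ValueError("residual_norm must be >= 0")


def _start_grid(spec: FitSpec) -> list[np.ndarray]:
    """Deterministic multistart grid: stratified fractions, permuted per
    dimension, squared for the scale parameters (Lp, Ps) to concentrate
    starts at the small-magnitude end of wide bounds."""
    n = spec.n_multistarts
    k = len(spec.free)
    fracs = (np.arange(n) + 0.5) / n
    starts = []
    for i in range(n):
        x = np.empty(k)
        for j, p in enumerate(spec.free):
            lo, hi = spec.bounds[p]
            f = fracs[(i + j * max(1, n // max(1, k))) % n]
            if p in ("Lp", "Ps"):
                f = f * f
            x[j] = lo + f * (hi - lo)
        starts.append(x)
    if spec.initial is not None:
        starts.insert(0, np.array([spec.initial[p] for p in spec.free]))
    return starts


def _assemble(spec: FitSpec, x: np.ndarray) -> KKParameters:
    vals = dict(spec.fixed)
    for p, v in zip(spec.free, x):
        vals[p] = float(v)
    return KKParameters(Lp=vals["Lp"], Ps=vals["Ps"], sigma=vals["sigma"])


def fit_kk(
    traj: VolumeTrajectory,
    geom: OocyteGeometry,
    bath: BathSolution,
    vb_fraction: float = 0.75,
    spec: FitSpec = FitSpec(),
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    osm_iso: float = 200.0,
    area_basis: AreaBasis = "apparent",
    solvent_drag: bool = True,
) -> FitResult:
    """Fit the Kedem-Katchalsky simulator to an observed relative-volume
    trajectory by bounded least squares (best of a fixed multistart set).

    Residuals are on relative volume (dimensionless), matching how
    trajectories are reported and equalising oocyte sizes.
    """
    if len(traj) < 5:
        raise FitError("trajectory must contain at least 5 samples")
    if "Lp" in spec.free and float(np.ptp(traj.rel_volumes)) < 1e-12:
        raise FitError("constant-volume trajectory cannot identify Lp")

    obs = traj.rel_volumes

    def residuals(x: np.ndarray) -> np.ndarray:
        params = _assemble(spec, x)
        try:
            sim = simulate(
                params,
                geom,
                bath,
                vb_fraction=vb_fraction,
                constants=constants,
                osm_iso=osm_iso,
                times=traj.times,
                area_basis=area_basis,
                solvent_drag=solvent_drag,
            )
        except SimulationError:
            return np.full(obs.shape, 1e3)
        return sim.rel_volumes - obs

    lo = np.array([spec.bounds[p][0] for p in spec.free])
    hi = np.array([spec.bounds[p][1] for p in spec.free])
    x_scale = np.array(
        [{"Lp": 1.0, "Ps": 1e-2, "sigma": 0.1}[p] for p in spec.free]
    )

    best = None
    n_converged = 0
    for x0 in _start_grid(spec):
        x0 = np.clip(x0, lo, hi)
        try:
            res = least_squares(
                residuals,
                x0,
                bounds=(lo, hi),
                method="trf",
                x_scale=x_scale,
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except Exception:
            continue
        if not res.success and res.status <= 0:
            continue
        n_converged += 1
        if best is None or res.cost < best.cost * (1 - spec.loss_rtol):
            best = res
    if best is None:
        raise FitError("no multistart converged")

    rss = 2.0 * best.cost
    dof = max(len(traj) - len(spec.free), 1)
    jtj = best.jac.T @ best.jac
    try:
        cov = np.linalg.pinv(jtj) * rss / dof
        ses = {
            p: float(np.sqrt(max(cov[j, j], 0.0)))
            for j, p in enumerate(spec.free)
        }
    except np.linalg.LinAlgError:
        ses = {p: float("nan") for p in spec.free}

    return FitResult(
        params=_assemble(spec, best.x),
        residual_norm=float(np.sqrt(rss)),
        std_errors=ses,
        converged=bool(best.success),
        n_multistarts_converged=n_converged,
        n_samples=len(traj),
        free=spec.free,
    )


def profile_identifiability(
    traj: VolumeTrajectory,
    geom: OocyteGeometry,
    bath: BathSolution,
    vb_fraction: float,
    spec: FitSpec,
    sigma_grid: Sequence[float],
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    osm_iso: float = 200.0,
    area_basis: AreaBasis = "apparent",
    flat_rtol: float = 1e-4,
) -> dict:
    """Residual norm as a function of sigma held fixed, with the other
    free parameters re-fitted at each grid point.

    Returns a dict with ``sigma``, ``residual_norm`` arrays and a
    ``flat`` flag marking profiles whose relative variation is below
    ``flat_rtol`` (sigma not identifiable from the data).
    """
    sigma_grid = list(sigma_grid)
    if not sigma_grid:
        raise ValueError("sigma grid is empty")
    free = tuple(p for p in spec.free if p != "sigma")
    if not free:
        raise ValueError("profiling sigma requires another free parameter")
    norms = []
    for s in sigma_grid:
        fixed = dict(spec.fixed)
        fixed["sigma"] = float(s)
        sub = FitSpec(
            free=free,
            fixed=fixed,
            bounds=spec.bounds,
            initial=None
            if spec.initial is None
            else {p: spec.initial[p] for p in free},
            n_multistarts=spec.n_multistarts,
        )
        result = fit_kk(
            traj,
            geom,
            bath,
            vb_fraction=vb_fraction,
            spec=sub,
            constants=constants,
            osm_iso=osm_iso,
            area_basis=area_basis,
        )
        norms.append(result.residual_norm)
    norms_arr = np.asarray(norms)
    span = float(norms_arr.max() - norms_arr.min())
    scale = float(norms_arr.max()) if norms_arr.max() > 0 else 1.0
    return {
        "sigma": np.asarray(sigma_grid, dtype=float),
        "residual_norm": norms_arr,
        "flat": span / scale < flat_rtol,
    }
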