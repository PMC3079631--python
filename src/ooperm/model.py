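"""Two-compartment osmometer model of the oocyte and the Kedem-Katchalsky
ODE system for coupled water/solute transport under step changes in bath
composition.

The cell is treated as a sphere with an osmotically inactive volume
``Vb = vb_fraction * V0``; internal concentrations are expressed on the
free-water basis ``Vw_free = V - Vb - Ns*vs``.  Volume flux (positive =
influx) is

    Jv = Lp * RT * [(C_imp_in - C_imp_out) + sigma * (Cs_in - Cs_out)]

and permeant solute flux, with the solvent-drag term of the
three-parameter formalism,

    dNs/dt = Ps * S * (Cs_out - Cs_in) + (1 - sigma) * Cbar * Jv * S

where ``Cbar`` is the arithmetic mean of internal and external permeant
concentrations.  A drag-free two-parameter variant is available for
sensitivity checks (``solvent_drag=False``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy.integrate import solve_ivp

from .constants import (
    DEFAULT_CONSTANTS,
    MOLAR_TO_MOL_PER_CM3,
    MOSM_TO_OSMOL_PER_CM3,
    UM_TO_CM,
    PhysicalConstants,
)

__all__ = [
    "OocyteGeometry",
    "BathSolution",
    "KKParameters",
    "OocyteState",
    "VolumeTrajectory",
    "SimulationError",
    "make_geometry",
    "kk_derivatives",
    "simulate",
    "bvh_equilibrium",
    "pf_from_lp",
]

PermeantId = Literal["glycerol", "propylene_glycol", "ethylene_glycol", "none"]
AreaBasis = Literal["apparent", "folded"]

#: Isotonic osmolarity of the standard incubation medium, mOsm.
ISOTONIC_MOSM = 200.0


class SimulationError(RuntimeError):
    """Raised when the ODE solver fails or the model state breaks down."""


@dataclass(frozen=True)
class OocyteGeometry:
    """Spherical oocyte geometry.

    ``S`` is the effective membrane area after accounting for folding,
    ``S = area_fold_factor * A_apparent``.
    """

    apparent_diameter: float  # cm
    V0: float  # cm^3
    A_apparent: float  # cm^2
    S: float  # cm^2

    def __post_init__(self) -> None:
        if self.apparent_diameter <= 0 or self.V0 <= 0 or self.A_apparent <= 0:
            raise ValueError("geometry dimensions must be strictly positive")
        if self.S < self.A_apparent:
            raise ValueError("folded area S must be >= apparent area")

    def area(self, basis: AreaBasis) -> float:
        """Membrane area on the requested basis, cm^2."""
        if basis == "apparent":
            return self.A_apparent
        if basis == "folded":
            return self.S
        raise ValueError(f"unknown area basis {basis!r}")


def make_geometry(
    apparent_diameter: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> OocyteGeometry:
    """Build sphere geometry from an apparent diameter in cm."""
    if apparent_diameter <= 0:
        raise ValueError("apparent_diameter must be > 0")
    d = apparent_diameter
    V0 = math.pi / 6.0 * d**3
    A = math.pi * d**2
    return OocyteGeometry(
        apparent_diameter=d,
        V0=V0,
        A_apparent=A,
        S=constants.area_fold_factor * A,
    )


@dataclass(frozen=True)
class BathSolution:
    """Extracellular solution: impermeant osmolarity plus at most one
    permeant solute.

    Parameters
    ----------
    osm_impermeant : float
        Osmolarity contributed by impermeant species, mOsm.
    conc_permeant : float
        Permeant solute concentration, mol/L.
    permeant_id : str
        One of ``glycerol``, ``propylene_glycol``, ``ethylene_glycol``
        or ``none``.
    pH_label : str, optional
        Metadata only; never enters the model.
    """

    osm_impermeant: float
    conc_permeant: float = 0.0
    permeant_id: PermeantId = "none"
    pH_label: str = ""

    def __post_init__(self) -> None:
        if self.osm_impermeant < 0:
            raise ValueError("osm_impermeant must be >= 0")
        if self.conc_permeant < 0:
            raise ValueError("conc_permeant must be >= 0")
        if (self.permeant_id == "none") != (self.conc_permeant == 0):
            raise ValueError(
                "permeant_id='none' if and only if conc_permeant == 0"
            )


@dataclass(frozen=True)
class KKParameters:
    """The Kedem-Katchalsky membrane triple.

    Lp in um/(min*atm), Ps in cm/min, sigma dimensionless in [0, 1].
    """

    Lp: float
    Ps: float = 0.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.Lp < 0:
            raise ValueError("Lp must be >= 0")
        if self.Ps < 0:
            raise ValueError("Ps must be >= 0")
        if not 0.0 <= self.sigma <= 1.0:
            raise ValueError("sigma must lie in [0, 1]")

    @property
    def Lp_cm(self) -> float:
        """Lp in cm/(min*atm)."""
        return self.Lp * UM_TO_CM


@dataclass
class OocyteState:
    """Instantaneous compartment state.

    Attributes
    ----------
    V : float
        Total cell volume, cm^3.
    Ns : float
        Internal permeant amount, mol.
    N_imp_osm : float
        Internal impermeant osmoles (constant during a protocol), osmol.
    Vb : float
        Osmotically inactive volume, cm^3.
    """

    V: float
    Ns: float
    N_imp_osm: float
    Vb: float

    def free_water(self, constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
        """Osmotically active (free) water volume, cm^3."""
        return self.V - self.Vb - self.Ns * constants.vs_permeant

    def validate(self, constants: PhysicalConstants = DEFAULT_CONSTANTS) -> None:
        if self.Ns < 0:
            raise ValueError("internal permeant amount must be >= 0")
        if self.V < self.Vb:
            raise ValueError("total volume fell below the inactive volume")
        if self.free_water(constants) <= 0:
            raise ValueError("free water volume must be strictly positive")


@dataclass
class VolumeTrajectory:
    """Observed or simulated relative-volume time series.

    ``times`` in minutes, strictly increasing, starting at 0;
    ``rel_volumes`` is V/V0.  ``permeant_mol`` is populated by the
    simulator only.
    """

    times: np.ndarray
    rel_volumes: np.ndarray
    V0: float
    permeant_mol: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rel_volumes = np.asarray(self.rel_volumes, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.rel_volumes.shape:
            raise ValueError("times and rel_volumes must be 1-D and equal length")
        if self.times.size < 1:
            raise ValueError("trajectory must contain at least one sample")
        if self.times[0] != 0.0:
            raise ValueError("first time point must be 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.rel_volumes <= 0):
            raise ValueError("relative volumes must be strictly positive")
        if abs(self.rel_volumes[0] - 1.0) > 0.1:
            raise ValueError("first relative volume must be ~1")
        if self.V0 <= 0:
            raise ValueError("V0 must be > 0")
        if self.permeant_mol is not None:
            self.permeant_mol = np.asarray(self.permeant_mol, dtype=float)
            if self.permeant_mol.shape != self.times.shape:
                raise ValueError("permeant_mol length mismatch")

    def __len__(self) -> int:
        return int(self.times.size)

    def restrict(self, t_max: float) -> "VolumeTrajectory":
        """Sub-trajectory with times <= t_max (t_max in minutes)."""
        mask = self.times <= t_max + 1e-12
        if mask.sum() < 2:
            raise ValueError("restriction leaves fewer than 2 samples")
        return VolumeTrajectory(
            times=self.times[mask],
            rel_volumes=self.rel_volumes[mask],
            V0=self.V0,
            permeant_mol=None if self.permeant_mol is None else self.permeant_mol[mask],
            label=self.label,
        )


def _fluxes(
    V: float,
    Ns: float,
    N_imp_osm: float,
    Vb: float,
    bath: BathSolution,
    params: KKParameters,
    area: float,
    constants: PhysicalConstants,
    solvent_drag: bool,
) -> tuple[float, float]:
    """Raw RHS shared by kk_derivatives and the solver."""
    vw_free = V - Vb - Ns * constants.vs_permeant
    # guard against transient solver excursions; real violations are
    # detected on the sampled output
    vw_free = max(vw_free, 1e-12)
    cs_in = Ns / vw_free
    c_imp_in = N_imp_osm / vw_free
    cs_out = bath.conc_permeant * MOLAR_TO_MOL_PER_CM3
    c_imp_out = bath.osm_impermeant * MOSM_TO_OSMOL_PER_CM3
    jv = params.Lp_cm * constants.RT * (
        (c_imp_in - c_imp_out) + params.sigma * (cs_in - cs_out)
    )
    dV = jv * area
    dNs = params.Ps * area * (cs_out - cs_in)
    if solvent_drag:
        dNs += (1.0 - params.sigma) * 0.5 * (cs_in + cs_out) * jv * area
    return dV, dNs


def kk_derivatives(
    state: OocyteState,
    bath: BathSolution,
    params: KKParameters,
    geom: OocyteGeometry,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    area_basis: AreaBasis = "apparent",
    solvent_drag: bool = True,
) -> tuple[float, float]:
    """Instantaneous (dV/dt, dNs/dt) in cm^3/min and mol/min.

    Positive dV/dt means water influx (swelling).  Internal impermeant
    osmoles never change.
    """
    state.validate(constants)
    return _fluxes(
        state.V,
        state.Ns,
        state.N_imp_osm,
        state.Vb,
        bath,
        params,
        geom.area(area_basis),
        constants,
        solvent_drag,
    )


def simulate(
    params: KKParameters,
    geom: OocyteGeometry,
    bath: BathSolution,
    vb_fraction: float = 0.75,
    duration: float = 10.0,
    sample_interval: float = 1.0 / 6.0,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    osm_iso: float = ISOTONIC_MOSM,
    times: Optional[np.ndarray] = None,
    area_basis: AreaBasis = "apparent",
    solvent_drag: bool = True,
    rtol: float = 1e-9,
    atol: Optional[tuple[float, float]] = None,
    method: str = "LSODA",
) -> VolumeTrajectory:
    """Integrate the Kedem-Katchalsky system from isotonic rest through a
    step change to ``bath``.

    The initial state is V = V0, Ns = 0 and internal impermeant osmoles
    fixed by the isotonic osmolarity acting on the initial free water:
    ``N_imp_osm = osm_iso * (V0 - Vb)``.

    Parameters
    ----------
    times : ndarray, optional
        Explicit sampling grid in minutes (must start at 0); overrides
        ``duration``/``sample_interval``.
    area_basis : {"apparent", "folded"}
        Membrane area used for both fluxes; see package notes on the
        folding convention.
    """
    if not 0.0 <= vb_fraction < 1.0:
        raise ValueError("vb_fraction must lie in [0, 1)")
    if osm_iso <= 0:
        raise ValueError("osm_iso must be > 0")
    if times is None:
        if duration <= 0 or sample_interval <= 0:
            raise ValueError("duration and sample_interval must be > 0")
        n = int(round(duration / sample_interval))
        times = np.linspace(0.0, n * sample_interval, n + 1)
    else:
        times = np.asarray(times, dtype=float)
        if times[0] != 0.0 or np.any(np.diff(times) <= 0):
            raise ValueError("times must start at 0 and increase strictly")

    V0 = geom.V0
    Vb = vb_fraction * V0
    N_imp = osm_iso * MOSM_TO_OSMOL_PER_CM3 * (V0 - Vb)
    area = geom.area(area_basis)

    def rhs(t: float, y: np.ndarray) -> list[float]:
        return list(
            _fluxes(y[0], y[1], N_imp, Vb, bath, params, area, constants, solvent_drag)
        )

    if atol is None:
        atol = (1e-12, 1e-16)  # V ~1e-3 cm^3, Ns ~1e-7 mol
    sol = solve_ivp(
        rhs,
        (0.0, float(times[-1])),
        [V0, 0.0],
        method=method,
        t_eval=times,
        rtol=rtol,
        atol=list(atol),
    )
    if not sol.success:
        raise SimulationError(f"ODE solver failed: {sol.message}")
    V = sol.y[0]
    Ns = sol.y[1]
    vw_free = V - Vb - Ns * constants.vs_permeant
    if np.any(vw_free <= 0):
        raise SimulationError(
            "free water volume became non-positive during integration"
        )
    if np.any(Ns < -1e-15):
        raise SimulationError("internal permeant amount became negative")
    return VolumeTrajectory(
        times=times,
        rel_volumes=V / V0,
        V0=V0,
        permeant_mol=np.maximum(Ns, 0.0),
    )


def bvh_equilibrium(vb_fraction: float, osm_iso: float, osm_hyper: float) -> float:
    """Boyle-van't Hoff equilibrium relative volume after an impermeant
    osmotic step from ``osm_iso`` to ``osm_hyper`` (both mOsm):

        V_eq/V0 = vb + (1 - vb) * osm_iso / osm_hyper
    """
    if not 0.0 <= vb_fraction < 1.0:
        raise ValueError("vb_fraction must lie in [0, 1)")
    if osm_iso <= 0 or osm_hyper < osm_iso:
        raise ValueError("require osm_hyper >= osm_iso > 0")
    return vb_fraction + (1.0 - vb_fraction) * osm_iso / osm_hyper


def pf_from_lp(
    Lp: float, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Osmotic water permeability Pf = Lp*RT/Vw, cm/min, from Lp in
    um/(min*atm)."""
    if Lp < 0:
        raise ValueError("Lp must be >= 0")
    return Lp * UM_TO_CM * constants.RT / constants.Vw


def lp_from_pf(Pf: float, constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Inverse of :func:`pf_from_lp`; returns Lp in um/(min*atm)."""
    if Pf < 0:
        raise ValueError("Pf must be >= 0")
    return Pf * constants.Vw / constants.RT / UM_TO_CM
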