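"""Radiolabeled-solute arithmetic: hypertonic intracellular concentration
from scintillation counts, isotonic tracer uptake rates, and the
model-predicted concentration bridge to the simulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .constants import CM3_TO_UL, DEFAULT_CONSTANTS, DPM_PER_UCI, PhysicalConstants
from .model import BathSolution, KKParameters, OocyteGeometry, simulate

__all__ = [
    "UptakeMeasurement",
    "IsotonicUptakeSpec",
    "intracellular_concentration",
    "isotonic_uptake_rate",
    "predicted_concentration_from_kk",
]


@dataclass(frozen=True)
class UptakeMeasurement:
    """Counts and calibration for one oocyte in a hypertonic uptake assay.

    ``cpm_t`` are the counts after exposure, ``cpm_t0`` the time-zero
    counts (externally bound background), ``cpm_per_ul`` the bath
    calibration, ``bath_conc`` the labeled-solute bath concentration in
    mol/L and ``V_final`` the final oocyte volume in ul.
    """

    cpm_t: float
    cpm_t0: float
    V_final: float
    cpm_per_ul: float = 73000.0
    bath_conc: float = 1.3

    def __post_init__(self) -> None:
        if self.cpm_t < 0 or self.cpm_t0 < 0:
            raise ValueError("cpm values must be >= 0")
        if self.cpm_per_ul <= 0:
            raise ValueError("cpm_per_ul must be > 0")
        if self.V_final <= 0:
            raise ValueError("V_final must be > 0")
        if self.bath_conc <= 0:
            raise ValueError("bath_conc must be > 0")


@dataclass(frozen=True)
class IsotonicUptakeSpec:
    """Tracer dilution scheme for isotonic uptake assays.

    hot_conc in uM, total_conc in mM, specific_activity in Ci/mmol,
    incubation in min.  counting_efficiency of 1 treats cpm as dpm.
    """

    hot_conc: float = 5.0
    total_conc: float = 1.0
    specific_activity: float = 20.0
    incubation: float = 1.0
    counting_efficiency: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "hot_conc",
            "total_conc",
            "specific_activity",
            "incubation",
            "counting_efficiency",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.total_conc * 1e3 < self.hot_conc:  # mM -> uM
            raise ValueError("total_conc must be >= hot_conc")


def intracellular_concentration(m: UptakeMeasurement) -> float:
    """Intracellular solute concentration in mol/L:

        ((cpm_t - cpm_t0) / cpm_per_ul) * bath_conc / V_final

    The net-count/calibration ratio gives the ul of bath equivalents
    taken up, times bath_conc gives umol, divided by the final volume in
    ul gives umol/ul = mol/L.  Negative net counts clamp to zero with a
    warning.
    """
    net = m.cpm_t - m.cpm_t0
    if net < 0:
        warnings.warn(
            "net counts negative (background exceeds signal); clamping to 0",
            stacklevel=2,
        )
        net = 0.0
    return (net / m.cpm_per_ul) * m.bath_conc / m.V_final


def isotonic_uptake_rate(net_cpm: float, spec: IsotonicUptakeSpec) -> float:
    """Total-solute uptake rate in pmol per oocyte per minute.

    Hot tracer moles from counts via 2.22e6 dpm/uCi and the specific
    activity; scaled by the cold dilution factor total/hot and divided
    by the incubation time.
    """
    if net_cpm < 0:
        warnings.warn("negative net cpm clamped to 0", stacklevel=2)
        net_cpm = 0.0
    dpm = net_cpm / spec.counting_efficiency
    uci = dpm / DPM_PER_UCI
    hot_mmol = uci / (spec.specific_activity * 1e6)  # 1 Ci = 1e6 uCi
    hot_pmol = hot_mmol * 1e9
    dilution = (spec.total_conc * 1e3) / spec.hot_conc  # mM -> uM
    return hot_pmol * dilution / spec.incubation


def predicted_concentration_from_kk(
    params: KKParameters,
    geom: OocyteGeometry,
    bath: BathSolution,
    vb_fraction: float = 0.75,
    t: float = 10.0,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    osm_iso: float = 200.0,
    area_basis: str = "apparent",
) -> float:
    """Model-predicted intracellular permeant concentration Ns(t)/V(t) in
    mol/L after ``t`` minutes in ``bath`` — the simulator-side analogue
    of :func:`intracellular_concentration`.

    Note the measured quantity divides by *total* volume; at long times
    this approaches the bath concentration only up to the free-water /
    total-volume distinction.
    """
    if t <= 0:
        raise ValueError("t must be > 0")
    traj = simulate(
        params,
        geom,
        bath,
        vb_fraction=vb_fraction,
        duration=t,
        sample_interval=t,
        constants=constants,
        osm_iso=osm_iso,
        area_basis=area_basis,  # type: ignore[arg-type]
    )
    ns = traj.permeant_mol[-1]
    v = traj.rel_volumes[-1] * traj.V0
    return (ns / v) * 1e3  # mol/cm^3 -> mol/L


def final_volume_ul(
    params: KKParameters,
    geom: OocyteGeometry,
    bath: BathSolution,
    vb_fraction: float = 0.75,
    t: float = 10.0,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    osm_iso: float = 200.0,
) -> float:
    """Final oocyte volume in ul after ``t`` min in ``bath``, for use as
    ``V_final`` in :class:`UptakeMeasurement`."""
    traj = simulate(
        params,
        geom,
        bath,
        vb_fraction=vb_fraction,
        duration=t,
        sample_interval=t,
        constants=constants,
        osm_iso=osm_iso,
    )
    return float(traj.rel_volumes[-1] * traj.V0 * CM3_TO_UL)
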