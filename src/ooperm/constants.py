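"""Physical constants and unit conversion factors.

Canonical internal units are cm, cm^3, min, atm, mol, K.  Hydraulic
conductivity is accepted and reported in um/(min*atm) at the API surface
(the conventional unit for oocyte volumetry) and converted internally.
"""

from __future__ import annotations

from dataclasses import dataclass

#: 1 mOsm = 1e-3 osmol/L = 1e-6 osmol/cm^3
MOSM_TO_OSMOL_PER_CM3 = 1e-6
#: 1 mol/L = 1e-3 mol/cm^3
MOLAR_TO_MOL_PER_CM3 = 1e-3
#: 1 um = 1e-4 cm
UM_TO_CM = 1e-4
#: disintegrations per minute per microcurie
DPM_PER_UCI = 2.22e6
#: 1 cm^3 = 1000 ul
CM3_TO_UL = 1e3


@dataclass(frozen=True)
class PhysicalConstants:
    """Membrane-transport constants.

    Parameters
    ----------
    Vw : float
        Partial molar volume of water, cm^3/mol.
    vs_permeant : float
        Partial molar volume of the permeant solute, cm^3/mol
        (default is ethylene glycol).
    R : float
        Gas constant, cm^3*atm/(mol*K).
    T : float
        Absolute temperature, K (room temperature, 20 C, by default).
    area_fold_factor : float
        Ratio of true to apparent membrane area due to membrane folding.
    """

    Vw: float = 18.0
    vs_permeant: float = 54.0
    R: float = 82.3
    T: float = 293.15
    area_fold_factor: float = 9.0

    def __post_init__(self) -> None:
        for name in ("Vw", "vs_permeant", "R", "T", "area_fold_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.area_fold_factor < 1:
            raise ValueError("area_fold_factor must be >= 1")

    @property
    def RT(self) -> float:
        """R*T in cm^3*atm/mol."""
        return self.R * self.T


DEFAULT_CONSTANTS = PhysicalConstants()
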