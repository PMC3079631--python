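"""Download-free generator of realistic experiment bundles: noisy volume
trajectories for batches of oocytes with lognormal parameter
variability, Poisson scintillation counts, and the packaged worked
fixtures.

A single global seed expands into counter-based per-oocyte substreams
(``default_rng([seed, index])``) so any subset of a batch is
reproducible on its own.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .constants import CM3_TO_UL, DEFAULT_CONSTANTS, PhysicalConstants
from .io import write_trajectory
from .model import (
    BathSolution,
    KKParameters,
    VolumeTrajectory,
    make_geometry,
    simulate,
)

__all__ = [
    "Protocol",
    "BatchSpec",
    "OocyteRecord",
    "ExperimentBundle",
    "DEFAULT_PROTOCOLS",
    "generate_batch",
    "generate_worked_fixtures",
]


@dataclass(frozen=True)
class Protocol:
    """One bath-step protocol: solution, duration and sampling grid."""

    bath: BathSolution
    duration: float  # min
    sample_interval: float  # min
    osm_iso: float = 200.0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.sample_interval <= 0:
            raise ValueError("duration and sample_interval must be > 0")


#: The four protocols exercised by the analysis stages: hypotonic
#: swelling (Pf), isotonic solute substitution (Ps), hypertonic sucrose
#: (Lp), and hypertonic ethylene glycol (full K-K).
DEFAULT_PROTOCOLS: dict[str, Protocol] = {
    "hypotonic_pf": Protocol(
        bath=BathSolution(osm_impermeant=20.0),
        duration=1.0 / 3.0,
        sample_interval=2.0 / 60.0,
    ),
    "isotonic_ps": Protocol(
        bath=BathSolution(
            osm_impermeant=40.0,
            conc_permeant=0.16,
            permeant_id="ethylene_glycol",
        ),
        duration=1.0,
        sample_interval=5.0 / 60.0,
    ),
    "sucrose_0p9M": Protocol(
        bath=BathSolution(osm_impermeant=1460.0),
        duration=10.0,
        sample_interval=10.0 / 60.0,
    ),
    "eg_1p3M": Protocol(
        bath=BathSolution(
            osm_impermeant=200.0,
            conc_permeant=1.3,
            permeant_id="ethylene_glycol",
        ),
        duration=10.0,
        sample_interval=10.0 / 60.0,
    ),
}


@dataclass(frozen=True)
class BatchSpec:
    """Population spec for one synthetic batch of oocytes."""

    n_oocytes: int
    true_params: KKParameters
    cv_lognormal: float = 0.1
    diameter_mean: float = 0.12  # cm
    diameter_sd: float = 0.0
    noise_sd_rel_volume: float = 0.01
    vb_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_oocytes < 1:
            raise ValueError("n_oocytes must be >= 1")
        if self.cv_lognormal < 0 or self.noise_sd_rel_volume < 0:
            raise ValueError("cv and noise sd must be >= 0")
        if self.diameter_mean <= 0 or self.diameter_sd < 0:
            raise ValueError("invalid diameter distribution")


@dataclass
class OocyteRecord:
    oocyte_id: str
    params: KKParameters
    diameter: float
    trajectories: dict[str, VolumeTrajectory] = field(default_factory=dict)


@dataclass
class ExperimentBundle:
    records: list[OocyteRecord]
    cpm_table: pd.DataFrame
    ground_truth: pd.DataFrame
    seed: int

    def trajectories(self, protocol: str) -> list[VolumeTrajectory]:
        return [r.trajectories[protocol] for r in self.records]


def _draw_params(
    rng: np.random.Generator, spec: BatchSpec
) -> KKParameters:
    """Median-preserving lognormal draw for Lp and Ps; sigma is common."""
    if spec.cv_lognormal == 0:
        return spec.true_params
    s = math.sqrt(math.log1p(spec.cv_lognormal**2))
    z = rng.standard_normal(2)
    lp = spec.true_params.Lp * math.exp(s * z[0])
    ps = spec.true_params.Ps * math.exp(s * z[1]) if spec.true_params.Ps > 0 else 0.0
    return KKParameters(Lp=lp, Ps=ps, sigma=spec.true_params.sigma)


def generate_batch(
    spec: BatchSpec,
    protocols: Optional[Mapping[str, Protocol]] = None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    area_basis: str = "apparent",
    cpm_protocol: str = "eg_1p3M",
    cpm_per_ul: float = 73000.0,
    cpm_background: float = 500.0,
) -> ExperimentBundle:
    """Generate a fully reproducible synthetic batch.

    Per-oocyte parameters are drawn lognormally around the population
    medians, trajectories are simulated and perturbed with multiplicative
    Gaussian noise, and scintillation counts are drawn Poisson around the
    noise-free model prediction of intracellular permeant content.
    """
    if protocols is None:
        protocols = DEFAULT_PROTOCOLS
    records = []
    cpm_rows = []
    truth_rows = []
    for i in range(spec.n_oocytes):
        rng = np.random.default_rng([spec.seed, i])
        params = _draw_params(rng, spec)
        d = spec.diameter_mean
        if spec.diameter_sd > 0:
            d = max(
                spec.diameter_mean + spec.diameter_sd * rng.standard_normal(),
                0.2 * spec.diameter_mean,
            )
        geom = make_geometry(d, constants)
        rec = OocyteRecord(oocyte_id=f"oo{i:03d}", params=params, diameter=d)
        ns_final = None
        v_final = None
        for name, proto in protocols.items():
            clean = simulate(
                params,
                geom,
                proto.bath,
                vb_fraction=spec.vb_fraction,
                duration=proto.duration,
                sample_interval=proto.sample_interval,
                constants=constants,
                osm_iso=proto.osm_iso,
                area_basis=area_basis,  # type: ignore[arg-type]
            )
            rel = clean.rel_volumes.copy()
            if spec.noise_sd_rel_volume > 0:
                rel = rel * (
                    1.0
                    + spec.noise_sd_rel_volume
                    * rng.standard_normal(rel.shape)
                )
                rel = np.maximum(rel, 1e-6)
            rec.trajectories[name] = VolumeTrajectory(
                times=clean.times,
                rel_volumes=rel,
                V0=clean.V0,
                permeant_mol=clean.permeant_mol,
                label=f"{rec.oocyte_id}:{name}",
            )
            if name == cpm_protocol and clean.permeant_mol is not None:
                ns_final = float(clean.permeant_mol[-1])
                v_final = float(rel[-1] * clean.V0)
        if ns_final is not None and v_final is not None:
            bath_conc = protocols[cpm_protocol].bath.conc_permeant
            # ul of bath equivalents taken up -> expected net counts
            uptake_umol = ns_final * 1e6
            expected_net = uptake_umol / bath_conc * cpm_per_ul
            cpm_t0 = int(rng.poisson(cpm_background))
            cpm_t = int(rng.poisson(cpm_background + expected_net))
            cpm_rows.append(
                {
                    "oocyte_id": rec.oocyte_id,
                    "cpm_t0": cpm_t0,
                    "cpm_t": cpm_t,
                    "group": "synthetic",
                    "V_final_ul": v_final * CM3_TO_UL,
                }
            )
        truth_rows.append(
            {
                "oocyte_id": rec.oocyte_id,
                "Lp": params.Lp,
                "Ps": params.Ps,
                "sigma": params.sigma,
                "diameter_cm": d,
                "seed": spec.seed,
                "substream": i,
            }
        )
        records.append(rec)
    return ExperimentBundle(
        records=records,
        cpm_table=pd.DataFrame(cpm_rows),
        ground_truth=pd.DataFrame(truth_rows),
        seed=spec.seed,
    )


def write_bundle(bundle: ExperimentBundle, outdir) -> list[Path]:
    """Write a bundle to CSV files; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in bundle.records:
        for proto, traj in rec.trajectories.items():
            p = outdir / f"{rec.oocyte_id}_{proto}.csv"
            write_trajectory(traj, p)
            paths.append(p)
    p = outdir / "cpm_counts.csv"
    bundle.cpm_table.to_csv(p, index=False)
    paths.append(p)
    p = outdir / "ground_truth.csv"
    bundle.ground_truth.to_csv(p, index=False)
    paths.append(p)
    return paths


def generate_worked_fixtures(outdir) -> dict[str, str]:
    """Write the worked example fixtures (mutant loop table, reference
    parameter anchors, a noise-free example trajectory) and return a
    name -> sha256 map.  Deterministic: reruns produce identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("table2_loops.tsv", "loop_offsets.json", "reference_params.json"):
        text = resources.files("ooperm.data").joinpath(name).read_text()
        (outdir / name).write_text(text)

    ref = json.loads((outdir / "reference_params.json").read_text())
    lp = ref["sucrose_lp"]["DrAqp3b-T85A"]["lp_2min"]
    geom = make_geometry(0.12)
    traj = simulate(
        KKParameters(Lp=lp, Ps=0.0, sigma=1.0),
        geom,
        BathSolution(osm_impermeant=1460.0),
        vb_fraction=0.75,
        duration=10.0,
        sample_interval=10.0 / 60.0,
    )
    write_trajectory(traj, outdir / "example_sucrose_trajectory.csv")

    checksums = {}
    for p in sorted(outdir.iterdir()):
        if p.is_file() and p.name != "SHA256SUMS":
            checksums[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    (outdir / "SHA256SUMS").write_text(
        "".join(f"{v}  {k}\n" for k, v in checksums.items())
    )
    return checksums
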