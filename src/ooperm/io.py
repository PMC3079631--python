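"""CSV plumbing: trajectory readers/writers and scintillation-count
tables.

Dialect: comma-separated, UTF-8, mandatory header row, decimal point.
Units are declared in column names (``time_min``, ``time_s``,
``rel_volume``, ``volume_cm3``, ``apparent_diameter_cm``) or via the
``time_unit`` argument for a bare ``time`` column — never inferred
silently.
"""

from __future__ import annotations

import math
from typing import Optional

import pandas as pd

from .model import VolumeTrajectory

__all__ = ["read_trajectory", "write_trajectory", "read_counts"]

_VALUE_COLUMNS = ("rel_volume", "volume_cm3", "apparent_diameter_cm")


def read_trajectory(
    path, time_unit: Optional[str] = None, v0: Optional[float] = None
) -> VolumeTrajectory:
    """Read a trajectory CSV.

    The time column must be ``time_min``, ``time_s``, or ``time`` with an
    explicit ``time_unit`` ("min" or "s").  Exactly one value column of
    ``rel_volume``, ``volume_cm3`` or ``apparent_diameter_cm`` must be
    present; diameters are converted through the sphere volume.
    """
    df = pd.read_csv(path)
    if "time_min" in df.columns:
        t = df["time_min"].to_numpy(float)
    elif "time_s" in df.columns:
        t = df["time_s"].to_numpy(float) / 60.0
    elif "time" in df.columns:
        if time_unit == "min":
            t = df["time"].to_numpy(float)
        elif time_unit == "s":
            t = df["time"].to_numpy(float) / 60.0
        else:
            raise ValueError(
                "bare 'time' column requires time_unit='min' or 's'"
            )
    else:
        raise ValueError(f"{path}: no time column (time_min/time_s/time)")

    present = [c for c in _VALUE_COLUMNS if c in df.columns]
    if not present:
        raise ValueError(
            f"{path}: expected one of {_VALUE_COLUMNS}, found none"
        )
    # volume_cm3 is preferred when several are present: it also fixes V0
    col = "volume_cm3" if "volume_cm3" in present else present[0]
    vals = df[col].to_numpy(float)
    if col == "rel_volume":
        if v0 is None:
            v0 = (
                float(df["V0_cm3"].iloc[0])
                if "V0_cm3" in df.columns
                else 1.0  # relative-only trajectory; caller must rescale
            )
        rel = vals
    elif col == "volume_cm3":
        v0 = vals[0]
        rel = vals / v0
    else:  # apparent_diameter_cm
        volumes = math.pi / 6.0 * vals**3
        v0 = volumes[0]
        rel = volumes / v0
    perm = (
        df["internal_permeant_mol"].to_numpy(float)
        if "internal_permeant_mol" in df.columns
        else None
    )
    return VolumeTrajectory(times=t, rel_volumes=rel, V0=v0, permeant_mol=perm)


def write_trajectory(traj: VolumeTrajectory, path) -> None:
    """Write time_min, rel_volume, volume_cm3 and (if present)
    internal_permeant_mol columns."""
    data = {
        "time_min": traj.times,
        "rel_volume": traj.rel_volumes,
        "volume_cm3": traj.rel_volumes * traj.V0,
    }
    if traj.permeant_mol is not None:
        data["internal_permeant_mol"] = traj.permeant_mol
    pd.DataFrame(data).to_csv(path, index=False)


def read_counts(path) -> pd.DataFrame:
    """Read a scintillation export with columns oocyte_id, cpm_t0,
    cpm_t and optional group."""
    df = pd.read_csv(path)
    required = {"oocyte_id", "cpm_t0", "cpm_t"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "group" not in df.columns:
        df["group"] = ""
    return df
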