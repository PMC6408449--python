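"""File formats: trajectory CSV, profile JSON/CSV, YAML cohort configs, manifests.

Conventions, enforced everywhere: positions in mm with the cold end at 0,
temperatures in deg C, times in s; numeric CSV columns carry their unit in
the header (``time_s``, ``position_mm``, ``temperature_C``); bins are
half-open [lo, hi) with the final bin closed.  Every CLI command writes a
run manifest (full configuration, seeds, version, digests) next to its
outputs so any deterministic output can be reproduced bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohorts import CohortConfig
from .correction import PreferenceProfile
from .kinematics import (
    AdultKinematics,
    CohortSpec,
    DurationSurface,
    LarvalKinematics,
    VelocitySurface,
)
from .metrics import Trajectory
from .simulator import GradientArena, SimulationRecord
from .thermo import BodyModel

__all__ = [
    "TrajectoryParseError",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "write_record_csv",
    "read_record_csv",
    "write_profile",
    "load_cohort_yaml",
    "dump_cohort_yaml",
    "write_manifest",
]


class TrajectoryParseError(ValueError):
    pass


def read_trajectory_csv(path, label: str = "", stage: str = "adult") -> Trajectory:
    """Read a trajectory CSV with columns ``time_s``, ``position_mm`` [, ``temperature_C``]."""
    df = pd.read_csv(path)
    for col in ("time_s", "position_mm"):
        if col not in df.columns:
            raise TrajectoryParseError(f"{path}: missing required column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(~np.isfinite(t)) or np.any(~np.isfinite(df["position_mm"].to_numpy(dtype=float))):
        bad = int(np.nonzero(~np.isfinite(t))[0][0]) if np.any(~np.isfinite(t)) else "position"
        raise TrajectoryParseError(f"{path}: non-finite value near row {bad}")
    if t.size >= 2:
        dt = np.diff(t)
        if np.any(dt <= 0):
            row = int(np.nonzero(dt <= 0)[0][0]) + 1
            raise TrajectoryParseError(f"{path}: non-monotone time at row {row}")
    return Trajectory(
        time_s=t,
        position_mm=df["position_mm"].to_numpy(dtype=float),
        label=label or Path(path).stem,
        stage=stage,
    )


def write_trajectory_csv(path, traj: Trajectory, temperatures=None) -> None:
    data = {"time_s": traj.time_s, "position_mm": traj.position_mm}
    if temperatures is not None:
        data["temperature_C"] = np.asarray(temperatures, dtype=float)
    pd.DataFrame(data).to_csv(path, index=False)


def write_record_csv(path, record: SimulationRecord) -> None:
    """Long-format cohort record: time_s, agent_id, position_mm."""
    record.to_dataframe().to_csv(path, index=False)


def read_record_csv(path, arena: GradientArena, cohort_label: str = "", seed: int = 0) -> SimulationRecord:
    df = pd.read_csv(path)
    for col in ("time_s", "agent_id", "position_mm"):
        if col not in df.columns:
            raise TrajectoryParseError(f"{path}: missing required column {col!r}")
    times = np.sort(df["time_s"].unique())
    agents = np.sort(df["agent_id"].unique())
    wide = df.pivot(index="agent_id", columns="time_s", values="position_mm")
    wide = wide.loc[agents, times]
    if wide.isna().any().any():
        raise TrajectoryParseError(f"{path}: record grid is not complete")
    dt = float(times[1] - times[0]) if times.size > 1 else 1.0
    return SimulationRecord(
        times=np.asarray(times, float), positions=wide.to_numpy(dtype=float),
        arena=arena, cohort_label=cohort_label, seed=seed, grid_dt=dt,
    )


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_profile(path, profile: PreferenceProfile) -> None:
    """Write a preference profile as JSON (scalars + per-bin arrays)."""
    payload = {
        "bin_edges_C": profile.bin_edges.tolist(),
        "bin_centers_C": profile.bin_centers.tolist(),
        "preference_index": profile.index.tolist(),
        "labels": list(profile.labels),
        "null_occupancy": profile.null.tolist(),
        "t_preferred_C": None if math.isnan(profile.t_preferred) else profile.t_preferred,
        "cold_avoidance_start_C": None if math.isnan(profile.cold_avoidance_start) else profile.cold_avoidance_start,
        "hot_avoidance_start_C": None if math.isnan(profile.hot_avoidance_start) else profile.hot_avoidance_start,
        "tolerance_range_C": None if math.isnan(profile.tolerance_range) else profile.tolerance_range,
        "preference_range_C": profile.preference_range,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default))


def write_profile_csv(path, profile: PreferenceProfile) -> None:
    pd.DataFrame(
        {
            "bin_lo_C": profile.bin_edges[:-1],
            "bin_hi_C": profile.bin_edges[1:],
            "preference_index": profile.index,
            "label": profile.labels,
        }
    ).to_csv(path, index=False)


# -- cohort parameter files -------------------------------------------------

def _plain(obj):
    """Recursively cast numpy scalars/arrays so yaml.safe_dump can emit them."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def dump_cohort_yaml(path, config: CohortConfig) -> None:
    doc: dict = {
        "label": config.spec.label,
        "stage": config.spec.stage,
        "body": dataclasses.asdict(config.body),
    }
    if config.spec.stage == "adult":
        doc["rearing_temperature"] = config.spec.rearing_temperature
        doc["velocity_surface"] = dataclasses.asdict(config.kinematics.velocity_surface)
        doc["duration_surface"] = dataclasses.asdict(config.kinematics.duration_surface)
    else:
        lk = dataclasses.asdict(config.kinematics)
        lk["velocity_temp_poly"] = list(lk["velocity_temp_poly"])
        lk["velocity_prob_poly"] = list(lk["velocity_prob_poly"])
        doc["larval_kinematics"] = lk
    Path(path).write_text(yaml.safe_dump(_plain(doc), sort_keys=False))


def load_cohort_yaml(path) -> CohortConfig:
    """Load and validate a cohort parameter file (invariants enforced by the types)."""
    doc = yaml.safe_load(Path(path).read_text())
    try:
        stage = doc["stage"]
        spec = CohortSpec(
            stage=stage,
            label=doc["label"],
            rearing_temperature=doc.get("rearing_temperature"),
        )
        body = BodyModel(**doc.get("body", {}))
        if stage == "adult":
            kin = AdultKinematics(
                velocity_surface=VelocitySurface(**doc["velocity_surface"]),
                duration_surface=DurationSurface(**doc["duration_surface"]),
            )
        else:
            lk = dict(doc["larval_kinematics"])
            lk["velocity_temp_poly"] = tuple(lk["velocity_temp_poly"])
            lk["velocity_prob_poly"] = tuple(lk["velocity_prob_poly"])
            kin = LarvalKinematics(**lk)
    except (KeyError, TypeError) as exc:
        raise ValueError(f"{path}: malformed cohort config ({exc})") from exc
    return CohortConfig(spec=spec, kinematics=kin, body=body)


# -- run manifests ----------------------------------------------------------

def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(path, command: str, config: dict, seed: int | None,
                   inputs=(), outputs=()) -> None:
    manifest = {
        "command": command,
        "version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config": config,
        "inputs": {str(p): _digest(Path(p)) for p in inputs},
        "outputs": {str(p): _digest(Path(p)) for p in outputs},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=_json_default))
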