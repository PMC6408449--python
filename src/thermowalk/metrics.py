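"""Trajectory metrics: speed, bout segmentation, activity index, bout tables.

These are the empirical quantities the walker model is built from.  Input
trajectories are already-tracked 1-D position series (vertical height for
climbing assays, path position for crawling larvae) at a uniform frame rate.
For adults only upward (position-increasing) movement counts as locomotion:
downward frame-to-frame displacement contributes speed zero, because a
falling animal would otherwise register spuriously high speeds.  Larvae use
the unsigned path speed.

A *bout* is an uninterrupted span of movement: frames faster than the
activity threshold (0.2 mm/s, ten percent of a body length per second) are
"moving", and moving spans separated by stops of at most 1 s merge into a
single bout.  The *activity index* is the fraction of the observation time
spent moving faster than the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "Bout",
    "instantaneous_speed",
    "segment_bouts",
    "activity_index",
    "build_bout_table",
]

MOVE_THRESHOLD_MM_S = 0.2
STOP_GAP_S = 1.0


@dataclass(frozen=True)
class Trajectory:
    """Tracked 1-D positions at a uniform frame rate."""

    time_s: np.ndarray
    position_mm: np.ndarray
    label: str = ""
    stage: str = "adult"

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        x = np.asarray(self.position_mm, dtype=float)
        if t.shape != x.shape or t.ndim != 1:
            raise ValueError("time and position must be equal-length 1-D arrays")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "position_mm", x)
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("frame times must be strictly increasing")
            if dt.max() - dt.min() > 0.01 * dt.mean():
                raise ValueError("frame interval must be uniform within 1%")

    @property
    def frame_dt(self) -> float:
        if self.time_s.size < 2:
            raise ValueError("trajectory has fewer than 2 frames")
        return float(np.mean(np.diff(self.time_s)))

    @property
    def total_time_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])


def instantaneous_speed(traj: Trajectory, upward_only: bool | None = None) -> np.ndarray:
    """Per-frame-transition speeds (mm/s), length ``n_frames - 1``.

    ``upward_only`` defaults to True for adults (climbing assay) and False
    for larvae (unsigned path speed).
    """
    if traj.time_s.size < 2:
        return np.empty(0)
    if upward_only is None:
        upward_only = traj.stage == "adult"
    disp = np.diff(traj.position_mm)
    speeds = disp / np.diff(traj.time_s)
    if upward_only:
        return np.maximum(speeds, 0.0)
    return np.abs(speeds)


class Bout(NamedTuple):
    start_s: float
    duration_s: float
    median_speed_mm_s: float


def segment_bouts(
    traj: Trajectory,
    stop_gap_s: float = STOP_GAP_S,
    move_threshold_mm_s: float = MOVE_THRESHOLD_MM_S,
) -> list[Bout]:
    """Split a trajectory into locomotion bouts.

    Each speed sample spans one frame interval.  Moving spans separated by
    non-moving gaps of at most ``stop_gap_s`` merge; longer stops end the
    bout.  The bout duration covers the whole span including internal short
    gaps; the bout speed is the median over its moving frames only.
    """
    speeds = instantaneous_speed(traj)
    if speeds.size == 0:
        return []
    dt = traj.frame_dt
    moving = speeds > move_threshold_mm_s
    if not moving.any():
        return []

    # runs of consecutive moving frames: (first_index, last_index) inclusive
    idx = np.nonzero(moving)[0]
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    run_starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    run_ends = np.concatenate((idx[breaks], [idx[-1]]))

    bouts: list[Bout] = []
    cur_start, cur_end = int(run_starts[0]), int(run_ends[0])
    for s, e in zip(run_starts[1:], run_ends[1:]):
        gap_s = (s - cur_end - 1) * dt
        if gap_s <= stop_gap_s:
            cur_end = int(e)
        else:
            bouts.append(_make_bout(traj, speeds, moving, cur_start, cur_end, dt))
            cur_start, cur_end = int(s), int(e)
    bouts.append(_make_bout(traj, speeds, moving, cur_start, cur_end, dt))
    return bouts


def _make_bout(traj, speeds, moving, first, last, dt) -> Bout:
    span = slice(first, last + 1)
    duration = (last - first + 1) * dt
    med = float(np.median(speeds[span][moving[span]]))
    return Bout(start_s=float(traj.time_s[first]), duration_s=duration, median_speed_mm_s=med)


def activity_index(traj: Trajectory, move_threshold_mm_s: float = MOVE_THRESHOLD_MM_S) -> float:
    """Fraction of the trace time spent moving faster than the threshold."""
    if traj.time_s.size < 2 or traj.total_time_s <= 0:
        raise ValueError("activity index needs a trace of positive duration")
    speeds = instantaneous_speed(traj)
    return float((speeds > move_threshold_mm_s).sum() * traj.frame_dt / traj.total_time_s)


def build_bout_table(
    trajectories: Iterable[Trajectory],
    temperatures: Sequence[float],
    stop_gap_s: float = STOP_GAP_S,
    move_threshold_mm_s: float = MOVE_THRESHOLD_MM_S,
) -> pd.DataFrame:
    """One row per bout: velocity (bout median speed), duration, assay T_A, cohort."""
    trajectories = list(trajectories)
    if len(trajectories) != len(temperatures):
        raise ValueError("need one assay temperature per trajectory")
    rows = []
    for traj, t_a in zip(trajectories, temperatures):
        for bout in segment_bouts(traj, stop_gap_s, move_threshold_mm_s):
            rows.append(
                {
                    "velocity_mm_s": bout.median_speed_mm_s,
                    "duration_s": bout.duration_s,
                    "temperature_C": float(t_a),
                    "cohort": traj.label,
                }
            )
    return pd.DataFrame(rows, columns=["velocity_mm_s", "duration_s", "temperature_C", "cohort"])
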