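"""Event-driven random walk of agents in a 1-D linear temperature gradient.

Each agent repeats: (1) relax its body temperature toward the local ambient
temperature over the time elapsed since the previous update, (2) draw a bout
(velocity, duration, heading) from its cohort's kinematics at the current
body temperature, (3) step by ``heading * velocity * duration`` with
reflective walls.  The walls fold the position by the sawtooth map of period
``2 L``, equivalent to an infinite repetitive sawtooth gradient.  The
dynamics are event-driven (no fixed time step); positions are sampled onto a
regular output grid afterwards.

An optional directional bias turns the null walker into a walker with a
known preferred temperature: the heading points toward the target with
probability ``0.5 + bias`` instead of ``0.5``.  With ``bias = 0`` the code
path is exactly the null model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .kinematics import sample_bout
from .thermo import BodyModel, relaxation_time, update_body_temperature

__all__ = [
    "GradientArena",
    "AgentState",
    "SimulationRecord",
    "position_to_temperature",
    "reflect",
    "step_agent",
    "run_cohort",
    "cold_trapped_fraction",
    "stable_onset",
    "equilibrium_time",
    "NOT_REACHED",
]

NOT_REACHED = math.inf  # sentinel returned by equilibrium_time


@dataclass(frozen=True)
class GradientArena:
    """Linear 1-D temperature gradient: cold end at position 0, hot end at L."""

    length_mm: float = 50.0
    t_cold: float = 14.0
    t_hot: float = 32.0

    def __post_init__(self) -> None:
        if self.length_mm <= 0:
            raise ValueError("arena length must be positive")
        if not self.t_cold < self.t_hot:
            raise ValueError("require t_cold < t_hot")

    def temperature_at(self, x):
        return position_to_temperature(x, self)

    def position_of(self, temperature: float) -> float:
        """Inverse of the linear map (temperature -> position in mm)."""
        return (temperature - self.t_cold) / (self.t_hot - self.t_cold) * self.length_mm

    @property
    def slope(self) -> float:
        """deg C per mm."""
        return (self.t_hot - self.t_cold) / self.length_mm


def position_to_temperature(x, arena: GradientArena):
    """Linear interpolation between the arena ends; errors outside [0, L]."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0.0) or np.any(x > arena.length_mm):
        raise ValueError("position outside arena")
    out = arena.t_cold + (x / arena.length_mm) * (arena.t_hot - arena.t_cold)
    return float(out) if out.ndim == 0 else out


def reflect(x_raw, length_mm: float):
    """Fold any real position into [0, L] by the sawtooth map of period 2L."""
    if length_mm <= 0:
        raise ValueError("arena length must be positive")
    y = np.mod(np.asarray(x_raw, dtype=float), 2.0 * length_mm)
    out = np.where(y > length_mm, 2.0 * length_mm - y, y)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class AgentState:
    """A walker: position in the arena, body temperature, elapsed clock.

    ``pending_s`` is the time since the last body-temperature update (the
    previous bout's duration); the next step integrates the heat exchange
    over it before sampling new kinematics.
    """

    position_mm: float
    t_body: float
    clock_s: float = 0.0
    pending_s: float = 0.0


def step_agent(
    agent: AgentState,
    arena: GradientArena,
    kin,
    body: BodyModel,
    rng: np.random.Generator,
) -> AgentState:
    """Advance one bout: update T_B, sample (v, d, dir), move with reflection."""
    t_a = arena.temperature_at(agent.position_mm)
    t_b = update_body_temperature(agent.t_body, t_a, agent.pending_s, body)
    v, d, direction = sample_bout(rng, t_b, kin)
    x = reflect(agent.position_mm + direction * v * d, arena.length_mm)
    return AgentState(position_mm=x, t_body=t_b, clock_s=agent.clock_s + d, pending_s=d)


@dataclass(frozen=True)
class SimulationRecord:
    """Cohort run sampled on a regular time grid.

    ``positions`` has shape (n_agents, n_times); every value lies in [0, L].
    """

    times: np.ndarray
    positions: np.ndarray
    arena: GradientArena
    cohort_label: str
    seed: int
    grid_dt: float = 1.0

    @property
    def n_agents(self) -> int:
        return self.positions.shape[0]

    @property
    def duration_s(self) -> float:
        return float(self.times[-1])

    def to_dataframe(self):
        import pandas as pd

        n_a, n_t = self.positions.shape
        return pd.DataFrame(
            {
                "time_s": np.tile(self.times, n_a),
                "agent_id": np.repeat(np.arange(n_a), n_t),
                "position_mm": self.positions.ravel(),
            }
        )


_START_POSITIONS = {"mid": 0.5, "cold": 0.0, "hot": 1.0}


def run_cohort(
    n_agents: int,
    duration_s: float,
    arena: GradientArena,
    kin,
    body: BodyModel,
    seed: int,
    start: str | float = "mid",
    cohort_label: str = "",
    grid_dt: float = 1.0,
    bias: float = 0.0,
    bias_target_temp: float | None = None,
) -> SimulationRecord:
    """Simulate ``n_agents`` independent walkers and sample their positions.

    Each agent gets its own seeded random stream (spawned from ``seed``), so
    the record is reproducible and independent of execution order.  Agents
    start with their body temperature equal to the local ambient temperature.
    ``start`` is 'mid' | 'cold' | 'hot' or a position in mm.  ``bias`` in
    [0, 0.5) steers the heading toward ``bias_target_temp`` with probability
    ``0.5 + bias``; the default 0 is the null model.
    """
    if n_agents < 1:
        raise ValueError("need at least one agent")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if not 0.0 <= bias < 0.5:
        raise ValueError("bias must lie in [0, 0.5)")
    if bias > 0.0 and bias_target_temp is None:
        raise ValueError("bias > 0 requires a target temperature")

    length = arena.length_mm
    t_cold, slope = arena.t_cold, arena.slope
    if isinstance(start, str):
        try:
            x0 = _START_POSITIONS[start] * length
        except KeyError:
            raise ValueError(f"start must be 'mid', 'cold', 'hot' or a position, got {start!r}")
    else:
        x0 = float(start)
        if not 0.0 <= x0 <= length:
            raise ValueError("start position outside arena")

    vel, dur = kin.scalar_funcs()
    tau = relaxation_time(body)
    x_target = arena.position_of(bias_target_temp) if bias > 0.0 else None
    p_toward = 0.5 + bias

    grid = np.arange(0.0, duration_s + grid_dt * 1e-9, grid_dt)
    out = np.empty((n_agents, grid.size))
    exp = math.exp
    two_l = 2.0 * length

    root = np.random.SeedSequence(seed)
    for i, child in enumerate(root.spawn(n_agents)):
        rng = np.random.Generator(np.random.PCG64(child))
        xu = x0  # unfolded coordinate on the infinite sawtooth
        t_b = t_cold + (x0 / length) * slope * length
        t = 0.0
        d_prev = 0.0
        times = [0.0]
        xs = [xu]
        buf = rng.random(3072)
        k = 0
        while t < duration_s:
            if k >= 3070:
                buf = rng.random(3072)
                k = 0
            y = xu % two_l
            if y > length:  # descending branch: folded +x is unfolded -x
                x = two_l - y
                branch = -1.0
            else:
                x = y
                branch = 1.0
            t_a = t_cold + x * slope
            t_b = t_a + (t_b - t_a) * exp(-d_prev / tau)
            p_v = buf[k]
            p_d = buf[k + 1]
            p_dir = buf[k + 2]
            k += 3
            v = vel(p_v, t_b)
            d = dur(p_d, t_b)
            if x_target is None:
                direction = 1.0 if p_dir < 0.5 else -1.0
            else:
                toward = 1.0 if x_target >= x else -1.0
                direction = toward if p_dir < p_toward else -toward
            # direction is a heading in the folded arena; translate to the
            # unfolded sawtooth coordinate before stepping
            xu += branch * direction * v * d
            t += d
            d_prev = d
            times.append(t)
            xs.append(xu)
        raw = np.interp(grid, times, xs)
        y = np.mod(raw, two_l)
        out[i] = np.where(y > length, two_l - y, y)

    return SimulationRecord(
        times=grid,
        positions=out,
        arena=arena,
        cohort_label=cohort_label,
        seed=seed,
        grid_dt=grid_dt,
    )


def cold_trapped_fraction(record: SimulationRecord, zone_mm: float = 4.0) -> np.ndarray:
    """Fraction of agents within ``zone_mm`` of the cold end, per output time."""
    if not 0.0 < zone_mm < record.arena.length_mm:
        raise ValueError("cold zone must lie strictly inside the arena")
    return (record.positions <= zone_mm).mean(axis=0)


def stable_onset(times: np.ndarray, values: np.ndarray, window_s: float, tolerance: float) -> float:
    """Earliest time from which ``values`` stays within +-tolerance of its final level.

    The reference level is the median over the trailing ``window_s`` seconds.
    Returns :data:`NOT_REACHED` (inf) if the series is still outside the band
    at its last sample, and 0.0 if it never leaves the band.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times[-1] - times[0] <= window_s:
        raise ValueError("series shorter than the stability window")
    ref = float(np.median(values[times >= times[-1] - window_s]))
    outside = np.abs(values - ref) > tolerance
    if not outside.any():
        return 0.0
    last = int(np.nonzero(outside)[0][-1])
    if last == len(times) - 1:
        return NOT_REACHED
    return float(times[last + 1])


def equilibrium_time(
    record: SimulationRecord,
    window_s: float = 600.0,
    tolerance: float = 0.05,
    zone_mm: float = 4.0,
) -> float:
    """Time at which the cold-trapped fraction stabilizes (see :func:`stable_onset`)."""
    frac = cold_trapped_fraction(record, zone_mm=zone_mm)
    return stable_onset(record.times, frac, window_s, tolerance)
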