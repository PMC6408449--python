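"""Synthetic fixtures: bout tables from known surfaces; null and biased walkers.

No experimental trajectories ship with the package, so every pipeline stage
is exercised on data generated from known ground truth: bout samples drawn
from a cohort's kinematics at a grid of assay temperatures (emulating
climbing/crawling assays), and gradient trajectories of walkers that either
have no preference (``bias = 0``, exactly the null model code path) or are
steered toward a known target temperature T_P* by heading toward it with
probability ``0.5 + bias``.  Preference is injected only through the
heading, never through the kinematics, so the correction's subtraction logic
is what any recovery test exercises.

Every generator is reproducible from (spec, seed); ``SyntheticSpec.manifest``
serializes the full configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohorts import get_cohort
from .kinematics import sample_bout
from .metrics import Trajectory
from .simulator import GradientArena, SimulationRecord, run_cohort

__all__ = [
    "SyntheticSpec",
    "FlatKinematics",
    "generate_bout_samples",
    "generate_walkers",
    "record_to_trajectories",
]


@dataclass(frozen=True)
class FlatKinematics:
    """Temperature-independent kinematics: the gas-molecule limit.

    Bout velocity is ``2 * velocity_mm_s * p`` (mean ``velocity_mm_s``,
    independent of temperature) and duration is constant, so step lengths
    are iid symmetric and position-independent.  The stationary occupancy of
    such a walker is uniform over the arena -- the probability density of
    gas molecules in a temperature gradient -- which makes this the
    strongest correctness oracle for the simulator.  (A strictly constant
    velocity would put the walker on a degenerate step lattice; the spread
    over ``p`` keeps the walk mixing while staying temperature-independent.)
    """

    velocity_mm_s: float = 5.0
    duration_s: float = 2.0

    def velocity(self, p, t_body):
        return 2.0 * self.velocity_mm_s * p

    def duration(self, p, t_body):
        return self.duration_s

    def scalar_funcs(self):
        v2, d = 2.0 * self.velocity_mm_s, self.duration_s
        return (lambda p, t: v2 * p), (lambda p, t: d)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for a synthetic dataset.

    ``bias`` in [0, 0.5): 0 generates null walkers, > 0 walkers preferring
    ``target_temp``.  ``assay_temperatures`` and ``bouts_per_temperature``
    configure bout-table generation; arena / n / duration configure walkers.
    """

    cohort: str = "wt25"
    arena: GradientArena = field(default_factory=GradientArena)
    n_individuals: int = 45
    duration_s: float = 1800.0
    bias: float = 0.0
    target_temp: float | None = None
    # odd-degree grid so assay temperatures sit at the centers of 2 deg C bins
    assay_temperatures: tuple[float, ...] = tuple(float(t) for t in range(11, 42, 2))
    bouts_per_temperature: int = 1000
    position_noise_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.bias < 0.5:
            raise ValueError("bias must lie in [0, 0.5)")
        if self.bias > 0 and self.target_temp is None:
            raise ValueError("bias > 0 requires target_temp")

    @property
    def manifest(self) -> dict:
        d = asdict(self)
        d["arena"] = asdict(self.arena)
        return d


def generate_bout_samples(spec: SyntheticSpec) -> pd.DataFrame:
    """Bout table drawn from the cohort's true surfaces at assay temperatures.

    Assumes body temperature equals the assay temperature (the animal is
    fully equilibrated, as in an incubator assay).  Round-trips through the
    calibration module to recover the truth parameters.
    """
    config = get_cohort(spec.cohort)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(spec.seed)))
    rows = []
    for t_a in spec.assay_temperatures:
        for _ in range(spec.bouts_per_temperature):
            v, d, _ = sample_bout(rng, t_a, config.kinematics)
            rows.append((v, d, t_a, spec.cohort))
    return pd.DataFrame(rows, columns=["velocity_mm_s", "duration_s", "temperature_C", "cohort"])


def generate_walkers(spec: SyntheticSpec) -> SimulationRecord:
    """Simulate null (bias=0) or preference-biased walkers under the spec."""
    config = get_cohort(spec.cohort)
    record = run_cohort(
        n_agents=spec.n_individuals,
        duration_s=spec.duration_s,
        arena=spec.arena,
        kin=config.kinematics,
        body=config.body,
        seed=spec.seed,
        cohort_label=spec.cohort,
        bias=spec.bias,
        bias_target_temp=spec.target_temp,
    )
    if spec.position_noise_mm > 0.0:
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((spec.seed, 1))))
        noisy = record.positions + rng.normal(0.0, spec.position_noise_mm, record.positions.shape)
        noisy = np.clip(noisy, 0.0, spec.arena.length_mm)
        record = SimulationRecord(
            times=record.times, positions=noisy, arena=record.arena,
            cohort_label=record.cohort_label, seed=record.seed, grid_dt=record.grid_dt,
        )
    return record


def record_to_trajectories(record: SimulationRecord) -> list[Trajectory]:
    """Split a cohort record into one trajectory per simulated individual."""
    stage = "larva" if record.cohort_label == "wtL" else "adult"
    return [
        Trajectory(time_s=record.times, position_mm=pos,
                   label=f"{record.cohort_label}_{i:04d}", stage=stage)
        for i, pos in enumerate(record.positions)
    ]
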