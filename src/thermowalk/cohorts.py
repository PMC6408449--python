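"""Shipped cohort parameter sets.

The Gaussian centers and widths of the adult velocity surface are the
printed wt25 fit values (26/5.41 and 34/2.27 deg C in the temperature
domain, -1.49/0.5 in the probability domain).  The remaining coefficients
(velocity amplitudes, the rearing-dependent duration width ``sigma_t1`` and
center ``mu_t2``, and the larval polynomials) are free parameters of the
model; the shipped values were produced once by the calibration procedure
described in ``docs/methods.md``: amplitudes anchored to realistic bout
speeds (``alpha_p ~= 1/G(0.5)`` so ``alpha_t1`` is the median bout speed at
the 26 deg C optimum, in mm/s) and duration widths chosen so that the
simulated wild-type cohorts reproduce the qualitative assay picture
(wt18 cold-resistant, wt30 slow, ~70-80% of wt25 adults cold-trapped at
equilibrium in a 14-32 deg C gradient).  All values can be overridden via
YAML parameter files (see :mod:`thermowalk.io`).
"""

from __future__ import annotations

from dataclasses import dataclass

from .kinematics import (
    AdultKinematics,
    CohortSpec,
    DurationSurface,
    LarvalKinematics,
    VelocitySurface,
)
from .thermo import BodyModel

__all__ = ["CohortConfig", "DEFAULT_COHORTS", "get_cohort", "adult_kinematics_for_rearing"]


@dataclass(frozen=True)
class CohortConfig:
    spec: CohortSpec
    kinematics: AdultKinematics | LarvalKinematics
    body: BodyModel


# Larval velocity polynomials (highest-order coefficient first).  Temperature
# polynomial: near-zero below 8 deg C, sharp rise through 10 deg C, broad
# plateau around 1.4-1.6 mm/s at 25-35 deg C.  Probability polynomial: a
# decreasing quantile map from 3.0 mm/s (p=0) to 0.5 mm/s (p=1).
_LARVAL_VELOCITY_TEMP_POLY = (
    -1.20745221e-07,
    -7.40964881e-05,
    3.60572801e-03,
    2.59051220e-02,
    -3.88554821e-01,
)
_LARVAL_VELOCITY_PROB_POLY = (-1.8, 4.95, -5.65, 3.0)


def _adult(label: str, t_rearing: float, a1: float, a2: float, dur_sigma_t1: float, dur_mu_t2: float) -> CohortConfig:
    return CohortConfig(
        spec=CohortSpec(stage="adult", label=label, rearing_temperature=t_rearing),
        kinematics=AdultKinematics(
            velocity_surface=VelocitySurface(alpha_t1=a1, alpha_t2=a2, alpha_p=2750.0),
            duration_surface=DurationSurface(sigma_t1=dur_sigma_t1, mu_t2=dur_mu_t2),
        ),
        body=BodyModel(),
    )


DEFAULT_COHORTS: dict[str, CohortConfig] = {
    # wt18: cold-acclimated; flatter duration profile (larger sigma_t1) keeps
    # bouts long in the cold, hence less cold-trapping.
    "wt18": _adult("wt18", 18.0, a1=1.0, a2=0.4, dur_sigma_t1=10.0, dur_mu_t2=34.0),
    # wt25: reference cohort; printed velocity Gaussians, calibrated defaults.
    "wt25": _adult("wt25", 25.0, a1=1.0, a2=0.5, dur_sigma_t1=6.0, dur_mu_t2=34.0),
    # wt30: generally slow and inactive; takes much longer to equilibrate.
    "wt30": _adult("wt30", 30.0, a1=0.4, a2=0.3, dur_sigma_t1=6.0, dur_mu_t2=36.0),
    "wtL": CohortConfig(
        spec=CohortSpec(stage="larva", label="wtL"),
        kinematics=LarvalKinematics(
            velocity_temp_poly=_LARVAL_VELOCITY_TEMP_POLY,
            velocity_prob_poly=_LARVAL_VELOCITY_PROB_POLY,
        ),
        body=BodyModel(),
    ),
}


def get_cohort(label: str) -> CohortConfig:
    try:
        return DEFAULT_COHORTS[label]
    except KeyError:
        raise KeyError(f"unknown cohort {label!r}; shipped: {sorted(DEFAULT_COHORTS)}") from None


def adult_kinematics_for_rearing(t_rearing: float) -> AdultKinematics:
    """Adult kinematics at an arbitrary rearing temperature in [18, 35] deg C.

    Linear interpolation of the rearing-dependent coefficients between the
    fitted cohort anchors (18, 25, 30 deg C); above 30 deg C the wt30 values
    are held.  A config-level convenience, not a fitted relationship.
    """
    if not 18.0 <= t_rearing <= 35.0:
        raise ValueError("rearing temperature must lie in [18, 35] deg C")
    import numpy as np

    anchors = [18.0, 25.0, 30.0]
    cohorts = [DEFAULT_COHORTS[k].kinematics for k in ("wt18", "wt25", "wt30")]

    def interp(values):
        return float(np.interp(t_rearing, anchors, values))

    vel = VelocitySurface(
        alpha_t1=interp([c.velocity_surface.alpha_t1 for c in cohorts]),
        alpha_t2=interp([c.velocity_surface.alpha_t2 for c in cohorts]),
        alpha_p=2750.0,
    )
    dur = DurationSurface(
        sigma_t1=interp([c.duration_surface.sigma_t1 for c in cohorts]),
        mu_t2=interp([c.duration_surface.mu_t2 for c in cohorts]),
    )
    return AdultKinematics(velocity_surface=vel, duration_surface=dur)
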