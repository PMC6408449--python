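"""Bout kinematics: temperature- and rearing-dependent velocity and duration maps.

The locomotion of a small ectotherm is decomposed into discrete bouts of
walking/crawling.  Each bout has a velocity (mm/s) and a duration (s) that
depend on the animal's body temperature ``T_B`` and, for adults, on the
rearing temperature ``T_R`` of the cohort.  The maps are quantile surfaces:
a uniform random number ``p`` in [0, 1] drawn per bout is sent through the
surface at the current body temperature, so the surfaces act as inverse-CDF
lookup tables for the bout statistics observed in climbing/crawling assays.

Adult surfaces are built from unnormalized Gaussians
``G(x; mu, s) = exp(-(x - mu)^2 / (2 s^2))``.  The adult velocity surface is

    v(p, T_B) = (a_t1 G(T_B; mu_t1, s_t1) + a_t2 G(T_B; mu_t2, s_t2))
                * a_p exp(-(p - mu_p)^2 / (2 s_p^2))

while the adult duration surface uses ``(2 s)^2`` denominators:

    d(p, T_B) = 20 * (exp(-(T_B - 37)^2 / (2 s_t1)^2)
                      + exp(-(T_B - mu_t2)^2 / (2 * 6.44)^2))
                * 0.33 * exp(-(p - 2)^2 / (2 * 0.64)^2)

The two denominator conventions are intentional and kept distinct.  Larvae
use a polynomial-product velocity and a two-component Gaussian duration
(temperature centers 9 and 34 deg C).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "CohortSpec",
    "VelocitySurface",
    "DurationSurface",
    "LarvalKinematics",
    "AdultKinematics",
    "velocity_at",
    "duration_at",
    "larval_velocity_at",
    "larval_duration_at",
    "sample_bout",
]


def _check_probability(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError(f"probability outside [0, 1]: {p}")
    return p


@dataclass(frozen=True)
class CohortSpec:
    """Identity of a cohort: life stage, rearing temperature, label."""

    stage: Literal["adult", "larva"]
    label: str
    rearing_temperature: float | None = None

    def __post_init__(self) -> None:
        if self.stage not in ("adult", "larva"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.stage == "adult":
            if self.rearing_temperature is None:
                raise ValueError("adult cohorts require a rearing temperature")
            if not 18.0 <= self.rearing_temperature <= 35.0:
                raise ValueError(
                    "adult rearing temperature must lie in [18, 35] deg C, "
                    f"got {self.rearing_temperature}"
                )
        elif self.rearing_temperature is not None:
            raise ValueError("larval cohorts carry no rearing temperature (single 25 deg C condition)")


@dataclass(frozen=True)
class VelocitySurface:
    """Parameters of the adult bout-velocity quantile surface (mm/s).

    ``alpha_t1``/``alpha_t2`` scale the two temperature Gaussians; ``alpha_p``
    scales the probability-domain Gaussian.  Only the products
    ``alpha_t1 * alpha_p`` and ``alpha_t2 * alpha_p`` are identifiable; by
    convention ``alpha_p ~= 1/G(0.5; mu_p, s_p)`` so that ``alpha_t1`` is the
    median bout velocity at the cool optimum ``mu_t1``.
    """

    alpha_t1: float
    alpha_t2: float
    alpha_p: float
    mu_t1: float = 26.0
    sigma_t1: float = 5.41
    mu_t2: float = 34.0
    sigma_t2: float = 2.27
    mu_p: float = -1.49
    sigma_p: float = 0.5

    def __post_init__(self) -> None:
        if self.alpha_t1 < 0 or self.alpha_t2 < 0 or self.alpha_p < 0:
            raise ValueError("velocity amplitudes must be non-negative")
        if self.sigma_t1 <= 0 or self.sigma_t2 <= 0 or self.sigma_p <= 0:
            raise ValueError("velocity sigma values must be positive")


@dataclass(frozen=True)
class DurationSurface:
    """Parameters of the adult bout-duration quantile surface (s).

    Only ``sigma_t1`` and ``mu_t2`` vary with rearing temperature; the rest
    are fixed constants of the functional form.  Note the ``(2 sigma)^2``
    denominator convention, distinct from the velocity surface.
    """

    sigma_t1: float
    mu_t2: float
    scale: float = 20.0
    mu_fixed: float = 37.0
    sigma_fixed: float = 6.44
    p_amp: float = 0.33
    mu_p: float = 2.0
    sigma_p: float = 0.64

    def __post_init__(self) -> None:
        if self.sigma_t1 <= 0 or self.sigma_fixed <= 0 or self.sigma_p <= 0:
            raise ValueError("duration sigma values must be positive")
        if self.scale <= 0 or self.p_amp <= 0:
            raise ValueError("duration amplitudes must be positive")


def velocity_at(p, t_body, surface: VelocitySurface):
    """Evaluate the adult bout-velocity surface at probability ``p`` and ``t_body``."""
    p = _check_probability(p)
    t = np.asarray(t_body, dtype=float)
    s = surface
    temp = s.alpha_t1 * np.exp(-((t - s.mu_t1) ** 2) / (2.0 * s.sigma_t1**2)) + s.alpha_t2 * np.exp(
        -((t - s.mu_t2) ** 2) / (2.0 * s.sigma_t2**2)
    )
    prob = s.alpha_p * np.exp(-((p - s.mu_p) ** 2) / (2.0 * s.sigma_p**2))
    out = temp * prob
    return float(out) if out.ndim == 0 else out


def duration_at(p, t_body, surface: DurationSurface):
    """Evaluate the adult bout-duration surface at probability ``p`` and ``t_body``."""
    p = _check_probability(p)
    t = np.asarray(t_body, dtype=float)
    s = surface
    temp = np.exp(-((t - s.mu_fixed) ** 2) / (2.0 * s.sigma_t1) ** 2) + np.exp(
        -((t - s.mu_t2) ** 2) / (2.0 * s.sigma_fixed) ** 2
    )
    prob = s.p_amp * np.exp(-((p - s.mu_p) ** 2) / (2.0 * s.sigma_p) ** 2)
    out = s.scale * temp * prob
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class LarvalKinematics:
    """Larval bout kinematics: polynomial-product velocity, Gaussian-sum duration.

    ``velocity_temp_poly`` holds 5 coefficients (degree 4, highest first) over
    the temperature domain; ``velocity_prob_poly`` 4 coefficients (degree 3)
    over the probability domain.  The product is clamped at zero below.  The
    duration is a sum of two (temperature Gaussian x probability Gaussian)
    products with temperature centers fixed at 9.0 and 34.0 deg C.
    """

    velocity_temp_poly: tuple[float, ...]
    velocity_prob_poly: tuple[float, ...]
    dur_amp_cold: float = 1.5
    dur_sigma_cold: float = 3.0
    dur_amp_hot: float = 12.0
    dur_sigma_hot: float = 8.0
    dur_mu_cold: float = 9.0
    dur_mu_hot: float = 34.0
    dur_mu_p: float = 2.0
    dur_sigma_p: float = 0.64

    def __post_init__(self) -> None:
        if len(self.velocity_temp_poly) != 5:
            raise ValueError("velocity_temp_poly needs 5 coefficients (degree 4)")
        if len(self.velocity_prob_poly) != 4:
            raise ValueError("velocity_prob_poly needs 4 coefficients (degree 3)")
        if min(self.dur_sigma_cold, self.dur_sigma_hot, self.dur_sigma_p) <= 0:
            raise ValueError("larval duration sigma values must be positive")

    # uniform interface with AdultKinematics
    def velocity(self, p, t_body):
        return larval_velocity_at(p, t_body, self)

    def duration(self, p, t_body):
        return larval_duration_at(p, t_body, self)

    def scalar_funcs(self):
        ct = tuple(self.velocity_temp_poly)
        cp = tuple(self.velocity_prob_poly)
        ac, sc, ah, sh = self.dur_amp_cold, self.dur_sigma_cold, self.dur_amp_hot, self.dur_sigma_hot
        mc, mh, mp, sp = self.dur_mu_cold, self.dur_mu_hot, self.dur_mu_p, self.dur_sigma_p
        exp = math.exp
        inv_c = 1.0 / (2.0 * sc * sc)
        inv_h = 1.0 / (2.0 * sh * sh)
        inv_p = 1.0 / (2.0 * sp) ** 2

        def vel(p: float, t: float) -> float:
            vt = (((ct[0] * t + ct[1]) * t + ct[2]) * t + ct[3]) * t + ct[4]
            vp = ((cp[0] * p + cp[1]) * p + cp[2]) * p + cp[3]
            v = vt * vp
            return v if v > 0.0 else 0.0

        def dur(p: float, t: float) -> float:
            gp = exp(-((p - mp) ** 2) * inv_p)
            return (ac * exp(-((t - mc) ** 2) * inv_c) + ah * exp(-((t - mh) ** 2) * inv_h)) * gp

        return vel, dur


def larval_velocity_at(p, t_body, model: LarvalKinematics):
    """Larval crawling speed (mm/s), clamped at zero below."""
    p = _check_probability(p)
    t = np.asarray(t_body, dtype=float)
    vt = np.polyval(model.velocity_temp_poly, t)
    vp = np.polyval(model.velocity_prob_poly, p)
    out = np.maximum(vt * vp, 0.0)
    return float(out) if out.ndim == 0 else out


def larval_duration_at(p, t_body, model: LarvalKinematics):
    """Larval bout duration (s): two Gaussian products, temperature centers 9 and 34 deg C."""
    p = _check_probability(p)
    t = np.asarray(t_body, dtype=float)
    m = model
    gp = np.exp(-((p - m.dur_mu_p) ** 2) / (2.0 * m.dur_sigma_p) ** 2)
    out = (
        m.dur_amp_cold * np.exp(-((t - m.dur_mu_cold) ** 2) / (2.0 * m.dur_sigma_cold**2))
        + m.dur_amp_hot * np.exp(-((t - m.dur_mu_hot) ** 2) / (2.0 * m.dur_sigma_hot**2))
    ) * gp
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class AdultKinematics:
    """Adult bout kinematics bundling a velocity and a duration surface."""

    velocity_surface: VelocitySurface
    duration_surface: DurationSurface

    def velocity(self, p, t_body):
        return velocity_at(p, t_body, self.velocity_surface)

    def duration(self, p, t_body):
        return duration_at(p, t_body, self.duration_surface)

    def scalar_funcs(self):
        """Fast scalar (p, T) -> value closures for the event-driven walker."""
        v, d = self.velocity_surface, self.duration_surface
        exp = math.exp
        a1, a2, ap = v.alpha_t1, v.alpha_t2, v.alpha_p
        m1, m2, mpv = v.mu_t1, v.mu_t2, v.mu_p
        iv1 = 1.0 / (2.0 * v.sigma_t1**2)
        iv2 = 1.0 / (2.0 * v.sigma_t2**2)
        ivp = 1.0 / (2.0 * v.sigma_p**2)
        dscale, dmu1, dmu2, dpamp, dmp = d.scale, d.mu_fixed, d.mu_t2, d.p_amp, d.mu_p
        id1 = 1.0 / (2.0 * d.sigma_t1) ** 2
        id2 = 1.0 / (2.0 * d.sigma_fixed) ** 2
        idp = 1.0 / (2.0 * d.sigma_p) ** 2

        def vel(p: float, t: float) -> float:
            return (a1 * exp(-((t - m1) ** 2) * iv1) + a2 * exp(-((t - m2) ** 2) * iv2)) * ap * exp(
                -((p - mpv) ** 2) * ivp
            )

        def dur(p: float, t: float) -> float:
            return (
                dscale
                * (exp(-((t - dmu1) ** 2) * id1) + exp(-((t - dmu2) ** 2) * id2))
                * dpamp
                * exp(-((p - dmp) ** 2) * idp)
            )

        return vel, dur


def sample_bout(rng: np.random.Generator, t_body: float, kin) -> tuple[float, float, int]:
    """Draw one bout: (velocity mm/s, duration s, direction in {+1, -1}).

    ``P_V`` and ``P_D`` are independent uniforms on [0, 1] mapped through the
    kinematics surfaces; the heading is a fair coin.  Draw order is fixed
    (velocity, duration, direction) so that identical seeds give identical
    bout sequences.
    """
    p_v = rng.random()
    p_d = rng.random()
    p_dir = rng.random()
    v = kin.velocity(p_v, t_body)
    d = kin.duration(p_d, t_body)
    direction = 1 if p_dir < 0.5 else -1
    return float(v), float(d), direction
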