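"""Body-temperature dynamics: conductive heat exchange with the substrate.

The animal is modelled as a small water-filled cylinder exchanging heat with
its surroundings by conduction.  The heat flow ``Q/t = lambda * A * (T_A - T_B) / D``
drives the body temperature toward the ambient temperature; with heat
capacity ``C = mass / heating_factor`` this is Newton cooling with relaxation
time ``tau = C / (lambda * A / D)``.  The update is implemented as the exact
exponential solution of that linear law, which a single explicit-Euler step
(heat flow times bout duration) approximates to first order; the exact form
never overshoots the ambient temperature, even for bouts much longer than
``tau``.  The model acts as a low-pass filter on the ambient temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BodyModel",
    "relaxation_time",
    "update_body_temperature",
    "euler_body_temperature_update",
    "cylinder_surface_area_mm2",
    "cylinder_mass_if_water_mg",
]

_WATER_DENSITY_MG_PER_MM3 = 1.0


def cylinder_surface_area_mm2(radius_mm: float = 0.5, length_mm: float = 2.0) -> float:
    """Total surface of a cylinder, 2*pi*r*(l + r), in mm^2 (default fly geometry)."""
    return 2.0 * math.pi * radius_mm * (length_mm + radius_mm)


def cylinder_mass_if_water_mg(radius_mm: float = 0.5, length_mm: float = 2.0) -> float:
    """Mass of the water-filled cylinder, pi*r^2*l*rho_water, in mg."""
    return math.pi * radius_mm**2 * length_mm * _WATER_DENSITY_MG_PER_MM3


@dataclass(frozen=True)
class BodyModel:
    """Geometric and thermal constants of the conduction model.

    conductivity      heat conductivity, W/(m K); water: 0.6
    area_m2           conductive surface, m^2; fly-sized cylinder: 7.85e-6
    thickness_m       conduction path (wall-to-wall) length, m
    mass_g            body mass, g (a fly weighs about 0.25 mg)
    heating_factor    deg C per J per g of water, 0.2449 (inverse specific heat)
    """

    conductivity: float = 0.6
    area_m2: float = 7.85e-6
    thickness_m: float = 1.0e-3
    mass_g: float = 2.5e-4
    heating_factor: float = 0.2449

    def __post_init__(self) -> None:
        for name in ("conductivity", "area_m2", "thickness_m", "mass_g", "heating_factor"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"BodyModel field {name!r} must be strictly positive")

    @property
    def conductance_w_per_k(self) -> float:
        """lambda * A / D, W/K."""
        return self.conductivity * self.area_m2 / self.thickness_m

    @property
    def heat_capacity_j_per_k(self) -> float:
        """mass / heating_factor, J/K."""
        return self.mass_g / self.heating_factor


def relaxation_time(body: BodyModel) -> float:
    """Thermal relaxation time tau = C / G in seconds (defaults: ~0.217 s)."""
    return body.heat_capacity_j_per_k / body.conductance_w_per_k


def update_body_temperature(t_body, t_ambient, t: float, body: BodyModel):
    """Relax body temperature toward ambient over ``t`` seconds (exact solution).

    Returns ``T_A + (T_B - T_A) * exp(-t / tau)``; lies between ``T_B`` and
    ``T_A`` and never overshoots.
    """
    if t < 0.0:
        raise ValueError(f"elapsed time must be non-negative, got {t}")
    tau = relaxation_time(body)
    t_body = np.asarray(t_body, dtype=float)
    t_ambient = np.asarray(t_ambient, dtype=float)
    out = t_ambient + (t_body - t_ambient) * math.exp(-t / tau)
    return float(out) if out.ndim == 0 else out


def euler_body_temperature_update(t_body: float, t_ambient: float, t: float, body: BodyModel) -> float:
    """Single explicit-Euler step: T_B + Q * heating_factor / mass with Q = G*(T_A-T_B)*t.

    First-order approximation of :func:`update_body_temperature`; can
    overshoot for ``t`` approaching ``tau`` and is provided for reference and
    for consistency checks only.
    """
    if t < 0.0:
        raise ValueError(f"elapsed time must be non-negative, got {t}")
    q = body.conductance_w_per_k * (t_ambient - t_body) * t
    return t_body + q * body.heating_factor / body.mass_g
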