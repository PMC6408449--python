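"""Fit kinematics surfaces to bout histograms; empirical-histogram sampling mode.

Bout tables are binned into 2-D histograms (value axis x ambient-temperature
axis, each temperature column normalized to unit mass).  The parametric
surfaces are fitted to the per-column empirical quantile functions -- the
cumulative form of the histogram -- by nonlinear least squares: for the
velocity surface, whose probability-domain Gaussian is decreasing on [0, 1],
the q-quantile of the observed velocities at temperature T must equal
``v(1 - q, T)``; for the increasing duration surface it equals ``d(q, T)``.

The *empirical mode* bypasses the fit entirely: bouts are drawn by
inverse-CDF lookup in the nearest temperature column of the histogram.  The
fitted mode exists to make the simulation continuous in temperature (and
faster); both modes should produce nearly identical occupancy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .kinematics import DurationSurface, VelocitySurface, velocity_at, duration_at

__all__ = [
    "BoutHistogram2D",
    "FitError",
    "FitResult",
    "build_histogram",
    "fit_velocity_surface",
    "fit_duration_surface",
    "empirical_sampler",
    "EmpiricalSampler",
    "EmpiricalKinematics",
]

logger = logging.getLogger(__name__)

_AXIS_COLUMNS = {"velocity": "velocity_mm_s", "duration": "duration_s"}


class FitError(RuntimeError):
    """Surface fit did not converge; carries residual diagnostics."""

    def __init__(self, message: str, residual_norm: float | None = None):
        super().__init__(message)
        self.residual_norm = residual_norm


@dataclass(frozen=True)
class BoutHistogram2D:
    """Column-normalized 2-D histogram of a bout statistic vs temperature."""

    value_edges: np.ndarray  # (nv + 1,) mm/s or s
    temp_edges: np.ndarray  # (nt + 1,) deg C
    probs: np.ndarray  # (nv, nt); populated columns sum to 1
    counts: np.ndarray  # (nv, nt) raw counts

    @property
    def value_centers(self) -> np.ndarray:
        return 0.5 * (self.value_edges[:-1] + self.value_edges[1:])

    @property
    def temp_centers(self) -> np.ndarray:
        return 0.5 * (self.temp_edges[:-1] + self.temp_edges[1:])

    @property
    def populated_columns(self) -> np.ndarray:
        return np.nonzero(self.counts.sum(axis=0) > 0)[0]

    def column_quantile(self, col: int, q) -> np.ndarray:
        """Inverse of the column's piecewise-linear CDF at probabilities ``q``."""
        c = self.probs[:, col]
        cdf = np.concatenate(([0.0], np.cumsum(c)))
        cdf[-1] = 1.0
        # make the CDF strictly increasing for interpolation across empty bins
        eps = 1e-12 * np.arange(cdf.size)
        return np.interp(np.asarray(q, dtype=float), cdf + eps, self.value_edges)


def build_histogram(
    bouts: pd.DataFrame,
    axis: str = "velocity",
    value_bin_width: float = 1.0,
    temp_bin_width: float = 2.0,
    value_edges: np.ndarray | None = None,
    temp_edges: np.ndarray | None = None,
) -> BoutHistogram2D:
    """Bin a bout table into a column-normalized 2-D histogram.

    Default bins are 1 (mm/s or s) by 2 deg C; pass explicit edges or widths
    for finer resolution.  Bins are half-open [lo, hi) with the final bin
    closed.
    """
    if axis not in _AXIS_COLUMNS:
        raise ValueError(f"axis must be 'velocity' or 'duration', got {axis!r}")
    if bouts.empty:
        raise ValueError("cannot build a histogram from an empty bout table")
    values = bouts[_AXIS_COLUMNS[axis]].to_numpy(dtype=float)
    temps = bouts["temperature_C"].to_numpy(dtype=float)

    if value_edges is None:
        hi = values.max() + value_bin_width
        value_edges = np.arange(0.0, hi + value_bin_width, value_bin_width)
    if temp_edges is None:
        lo = np.floor(temps.min() / temp_bin_width) * temp_bin_width
        hi = np.ceil(temps.max() / temp_bin_width) * temp_bin_width
        temp_edges = np.arange(lo, hi + temp_bin_width / 2, temp_bin_width)
        if temp_edges.size < 2:
            temp_edges = np.array([lo, lo + temp_bin_width])

    counts, _, _ = np.histogram2d(values, temps, bins=(value_edges, temp_edges))
    col_sums = counts.sum(axis=0)
    probs = np.divide(counts, col_sums, where=col_sums > 0, out=np.zeros_like(counts))
    return BoutHistogram2D(
        value_edges=np.asarray(value_edges, dtype=float),
        temp_edges=np.asarray(temp_edges, dtype=float),
        probs=probs,
        counts=counts,
    )


@dataclass(frozen=True)
class FitResult:
    surface: VelocitySurface | DurationSurface
    residual_norm: float
    n_points: int


_QUANTILES = np.linspace(0.05, 0.95, 19)


def _quantile_targets(hist: BoutHistogram2D):
    cols = hist.populated_columns
    if cols.size < 5:
        raise ValueError("surface fit needs at least 5 populated temperature columns")
    temps = hist.temp_centers[cols]
    targets = np.stack([hist.column_quantile(c, _QUANTILES) for c in cols], axis=1)
    return temps, targets  # (nq,), (nq, ncols)


def fit_velocity_surface(hist: BoutHistogram2D, init: VelocitySurface | None = None) -> FitResult:
    """Least-squares fit of the velocity surface to the histogram's quantiles.

    ``alpha_p`` is held at its initial value (only the products
    ``alpha_ti * alpha_p`` are identifiable).  Initialization defaults to the
    printed wt25 parameter values.
    """
    if init is None:
        init = VelocitySurface(alpha_t1=1.0, alpha_t2=0.5, alpha_p=2750.0)
    temps, targets = _quantile_targets(hist)
    t_grid = np.repeat(temps[None, :], _QUANTILES.size, axis=0)
    p_grid = np.repeat((1.0 - _QUANTILES)[:, None], temps.size, axis=1)
    alpha_p = init.alpha_p
    t_lo, t_hi = hist.temp_edges[0] - 5.0, hist.temp_edges[-1] + 5.0

    def unpack(theta):
        a1, a2, m1, s1, m2, s2, mp, sp = theta
        return VelocitySurface(
            alpha_t1=a1, alpha_t2=a2, alpha_p=alpha_p,
            mu_t1=m1, sigma_t1=s1, mu_t2=m2, sigma_t2=s2, mu_p=mp, sigma_p=sp,
        )

    def resid(theta):
        s = unpack(theta)
        return (velocity_at(p_grid, t_grid, s) - targets).ravel()

    x0 = [init.alpha_t1, init.alpha_t2, init.mu_t1, init.sigma_t1, init.mu_t2, init.sigma_t2,
          init.mu_p, init.sigma_p]
    lb = [0.0, 0.0, t_lo, 0.5, t_lo, 0.5, -10.0, 0.05]
    ub = [np.inf, np.inf, t_hi, 50.0, t_hi, 50.0, 2.0, 5.0]
    res = least_squares(resid, x0, bounds=(lb, ub), method="trf",
                        x_scale=[1.0, 1.0, 10.0, 5.0, 10.0, 5.0, 1.0, 0.5],
                        max_nfev=20_000)
    norm = float(np.linalg.norm(res.fun))
    if not res.success:
        raise FitError(f"velocity surface fit did not converge: {res.message}", norm)
    return FitResult(surface=unpack(res.x), residual_norm=norm, n_points=targets.size)


def fit_duration_surface(hist: BoutHistogram2D, init: DurationSurface | None = None) -> FitResult:
    """Least-squares fit of the rearing-dependent duration coefficients.

    Only ``sigma_t1`` and ``mu_t2`` are free; the remaining coefficients are
    fixed constants of the functional form.
    """
    if init is None:
        init = DurationSurface(sigma_t1=6.0, mu_t2=34.0)
    temps, targets = _quantile_targets(hist)
    t_grid = np.repeat(temps[None, :], _QUANTILES.size, axis=0)
    p_grid = np.repeat(_QUANTILES[:, None], temps.size, axis=1)
    t_lo, t_hi = hist.temp_edges[0] - 5.0, hist.temp_edges[-1] + 5.0

    def unpack(theta):
        s1, m2 = theta
        return DurationSurface(sigma_t1=s1, mu_t2=m2, scale=init.scale, mu_fixed=init.mu_fixed,
                               sigma_fixed=init.sigma_fixed, p_amp=init.p_amp,
                               mu_p=init.mu_p, sigma_p=init.sigma_p)

    def resid(theta):
        return (duration_at(p_grid, t_grid, unpack(theta)) - targets).ravel()

    res = least_squares(resid, [init.sigma_t1, init.mu_t2],
                        bounds=([0.5, t_lo], [50.0, t_hi]), method="trf",
                        x_scale=[5.0, 10.0], max_nfev=20_000)
    norm = float(np.linalg.norm(res.fun))
    if not res.success:
        raise FitError(f"duration surface fit did not converge: {res.message}", norm)
    return FitResult(surface=unpack(res.x), residual_norm=norm, n_points=targets.size)


class EmpiricalSampler:
    """Inverse-CDF lookup in the nearest temperature column of a histogram.

    ``sampler(p, T)`` returns the center of the bin whose cumulative mass
    first exceeds ``p``; p=0 maps to the lowest populated bin, p=1 to the
    highest.  Temperatures outside the histogram range clamp to the nearest
    column (with a log warning).
    """

    def __init__(self, hist: BoutHistogram2D):
        cols = hist.populated_columns
        if cols.size == 0:
            raise ValueError("histogram has no populated columns")
        self.temp_centers = hist.temp_centers[cols]
        self.value_centers = hist.value_centers
        self._cum = np.cumsum(hist.probs[:, cols], axis=0)  # (nv, ncols)
        self._cum[-1, :] = 1.0
        self._last_populated = np.array(
            [np.nonzero(hist.counts[:, c] > 0)[0][-1] for c in cols]
        )
        self._t_lo = hist.temp_edges[0]
        self._t_hi = hist.temp_edges[-1]

    def column_for(self, temperature: float) -> int:
        if temperature < self._t_lo or temperature > self._t_hi:
            logger.warning(
                "temperature %.2f outside histogram range [%.2f, %.2f]; clamping",
                temperature, self._t_lo, self._t_hi,
            )
        return int(np.argmin(np.abs(self.temp_centers - temperature)))

    def __call__(self, p: float, temperature: float) -> float:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability outside [0, 1]: {p}")
        j = self.column_for(temperature)
        idx = int(np.searchsorted(self._cum[:, j], p, side="right"))
        idx = min(idx, int(self._last_populated[j]))
        return float(self.value_centers[idx])


def empirical_sampler(hist: BoutHistogram2D) -> EmpiricalSampler:
    return EmpiricalSampler(hist)


@dataclass(frozen=True)
class EmpiricalKinematics:
    """Kinematics backed by empirical histograms instead of fitted surfaces."""

    velocity_sampler: EmpiricalSampler
    duration_sampler: EmpiricalSampler

    def velocity(self, p, t_body):
        return self.velocity_sampler(float(p), float(t_body))

    def duration(self, p, t_body):
        return self.duration_sampler(float(p), float(t_body))

    def scalar_funcs(self):
        # bisect on plain lists: the event-driven walker calls these millions
        # of times, so avoid per-call numpy temporaries
        from bisect import bisect_right

        def make(sampler: EmpiricalSampler):
            temps = sampler.temp_centers
            t0 = float(temps[0])
            n_col = temps.size
            step = float(temps[1] - t0) if n_col > 1 else 1.0
            uniform = n_col > 1 and np.allclose(np.diff(temps), step)
            cums = [list(sampler._cum[:, j]) for j in range(n_col)]
            lasts = [int(i) for i in sampler._last_populated]
            centers = list(sampler.value_centers)

            def lookup(p: float, t: float) -> float:
                if uniform:
                    j = int((t - t0) / step + 0.5)
                    j = 0 if j < 0 else (n_col - 1 if j >= n_col else j)
                else:
                    j = int(np.argmin(np.abs(temps - t)))
                idx = bisect_right(cums[j], p)
                last = lasts[j]
                return centers[idx if idx <= last else last]

            return lookup

        return make(self.velocity_sampler), make(self.duration_sampler)
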