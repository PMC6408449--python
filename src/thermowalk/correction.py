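"""Occupancy bias correction: preference indices, T_P, avoidance onsets, stats.

A gradient assay yields, per animal, a probability vector of residence over
temperature bins.  Because locomotion slows in the cold, raw occupancy
overweights cold bins (cold-trapping).  Subtracting the occupancy of the
simulated null walker -- same kinematics, no preference -- removes that
bias:

    preference index = p_observed - p_null        (per bin; sums to zero)

Per-bin significance uses the 95% confidence interval of the observed group
median (bootstrap over individuals) or, for a single animal, exact binomial
(Clopper-Pearson) intervals: a bin is *preferred* if the whole interval lies
above the null, *avoided* if entirely below, otherwise *neutral*.  The
preferred temperature T_P is the index-weighted mean of the preferred bin
centers; the cold/hot avoidance starts are the inner edges of the avoided
runs touching the arena ends, and their span is the tolerance range.

Group comparisons use Fisher's permutation test (exhaustive when feasible)
with Benjamini-Hochberg false-discovery-rate correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .simulator import GradientArena, SimulationRecord

__all__ = [
    "OccupancyProfile",
    "PreferenceProfile",
    "default_bins",
    "occupancy_density",
    "median_with_ci",
    "binomial_bin_ci",
    "preference_index",
    "classify_bins",
    "preferred_temperature",
    "avoidance_starts",
    "preference_range",
    "correct_profile",
    "null_occupancy",
    "permutation_test",
    "bh_fdr",
    "paired_t_test",
]

PREFERRED, AVOIDED, NEUTRAL = "preferred", "avoided", "neutral"


def default_bins(arena: GradientArena, width: float = 1.0) -> np.ndarray:
    """1 deg C temperature bin edges spanning the arena."""
    return np.arange(arena.t_cold, arena.t_hot + width / 2, width)


def occupancy_density(positions_mm, arena: GradientArena, bin_edges) -> np.ndarray:
    """Time-weighted occupancy probability over temperature bins (sums to 1).

    ``positions_mm`` are position samples on a uniform time grid; they are
    mapped through the arena's linear temperature profile and histogrammed.
    Bins are half-open [lo, hi) with the final bin closed (numpy convention).
    """
    positions = np.asarray(positions_mm, dtype=float).ravel()
    if positions.size == 0:
        raise ValueError("occupancy needs at least one position sample")
    temps = arena.temperature_at(positions)
    counts, _ = np.histogram(temps, bins=bin_edges)
    return counts / counts.sum()


@dataclass(frozen=True)
class OccupancyProfile:
    """Per-individual occupancy vectors with group median and 95% CI per bin."""

    bin_edges: np.ndarray
    individual: np.ndarray  # (n_individuals, n_bins); rows sum to 1
    median: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_time_samples: int = 0

    def __post_init__(self) -> None:
        rows = np.asarray(self.individual, dtype=float)
        if rows.ndim != 2:
            raise ValueError("individual vectors must form a 2-D array")
        if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every individual occupancy vector must sum to 1")
        if np.any(self.ci_low > self.median + 1e-12) or np.any(self.ci_high < self.median - 1e-12):
            raise ValueError("CI must bracket the median")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @classmethod
    def from_individuals(
        cls,
        individual: np.ndarray,
        bin_edges: np.ndarray,
        level: float = 0.95,
        method: str = "exact",
        n_boot: int = 10_000,
        seed: int = 0,
        n_time_samples: int = 0,
    ) -> "OccupancyProfile":
        med, (lo, hi) = median_with_ci(individual, level=level, method=method,
                                       n_boot=n_boot, seed=seed)
        return cls(bin_edges=np.asarray(bin_edges, float), individual=np.asarray(individual, float),
                   median=med, ci_low=lo, ci_high=hi, n_time_samples=n_time_samples)

    @classmethod
    def from_record(
        cls,
        record: SimulationRecord,
        bin_edges: np.ndarray | None = None,
        t_from: float = 0.0,
        level: float = 0.95,
        method: str = "exact",
        n_boot: int = 10_000,
        seed: int = 0,
    ) -> "OccupancyProfile":
        """Occupancy of each simulated agent over output samples with t >= t_from."""
        if bin_edges is None:
            bin_edges = default_bins(record.arena)
        mask = record.times >= t_from
        if not mask.any():
            raise ValueError("t_from is beyond the end of the record")
        rows = np.stack(
            [occupancy_density(p[mask], record.arena, bin_edges) for p in record.positions]
        )
        return cls.from_individuals(rows, bin_edges, level=level, method=method,
                                    n_boot=n_boot, seed=seed, n_time_samples=int(mask.sum()))


def median_with_ci(
    individual: np.ndarray,
    level: float = 0.95,
    method: str = "exact",
    n_boot: int = 10_000,
    seed: int = 0,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Per-bin median across individuals with a confidence interval.

    ``method='exact'`` (default) uses the distribution-free order-statistic
    interval: the CI endpoints are the sample order statistics whose ranks
    are the binomial(n, 1/2) quantiles, guaranteeing at least the nominal
    coverage for any continuous per-bin distribution.  ``method='bootstrap'``
    resamples individuals (rows) with replacement ``n_boot`` times (seeded)
    and takes percentile bounds; the percentile bootstrap undercovers for
    medians of strongly bimodal occupancy data, which is why it is not the
    default.  Requires at least 3 individuals; for fewer, use
    :func:`binomial_bin_ci` on the single animal's time samples instead.
    """
    rows = np.asarray(individual, dtype=float)
    if rows.ndim != 2 or rows.shape[0] < 3:
        raise ValueError(
            "median CI needs >= 3 individuals; for single animals use binomial_bin_ci"
        )
    n = rows.shape[0]
    med = np.median(rows, axis=0)
    alpha = 1.0 - level
    if method == "exact":
        srt = np.sort(rows, axis=0)
        l_rank = int(sps.binom.ppf(alpha / 2, n, 0.5))  # P(Bin < l_rank) <= alpha/2
        u_rank = int(sps.binom.isf(alpha / 2, n, 0.5))  # P(Bin > u_rank) <= alpha/2
        lo = srt[max(l_rank - 1, 0)]
        hi = srt[min(u_rank, n - 1)]
    elif method == "bootstrap":
        rng = np.random.Generator(np.random.PCG64(seed))
        boots = np.empty((n_boot, rows.shape[1]))
        chunk = max(1, int(2e7 // (n * rows.shape[1])))
        for s in range(0, n_boot, chunk):
            e = min(s + chunk, n_boot)
            idx = rng.integers(0, n, size=(e - s, n))
            boots[s:e] = np.median(rows[idx], axis=1)
        lo = np.quantile(boots, alpha / 2, axis=0)
        hi = np.quantile(boots, 1 - alpha / 2, axis=0)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    # a discrete/degenerate bin can put the bound on the far side of the median
    lo = np.minimum(lo, med)
    hi = np.maximum(hi, med)
    return med, (lo, hi)


def binomial_bin_ci(
    individual_vector: np.ndarray, n_time_samples: int, level: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """Exact (Clopper-Pearson) CI for each bin's occupancy proportion."""
    if n_time_samples < 1:
        raise ValueError("need at least one time sample")
    p = np.asarray(individual_vector, dtype=float)
    k = np.rint(p * n_time_samples)
    n = float(n_time_samples)
    alpha = 1.0 - level
    lo = np.where(k > 0, sps.beta.ppf(alpha / 2, k, n - k + 1), 0.0)
    hi = np.where(k < n, sps.beta.ppf(1 - alpha / 2, k + 1, n - k), 1.0)
    return lo, hi


def preference_index(observed: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Element-wise observed minus null occupancy; components sum to ~0."""
    observed = np.asarray(observed, dtype=float)
    null = np.asarray(null, dtype=float)
    if observed.shape != null.shape:
        raise ValueError("observed and null vectors must share their bins")
    return observed - null


def classify_bins(ci_low_diff: np.ndarray, ci_high_diff: np.ndarray,
                  atol: float = 0.0) -> np.ndarray:
    """Label bins from the CI of (observed - null): preferred / avoided / neutral.

    ``atol`` is a quantization guard: occupancy estimated from ``n`` time
    samples is quantized in steps of ``1/n``, so a CI that clears zero by
    less than one sample's mass is not a meaningful exclusion (such hairline
    offsets arise from renormalization alone).  Callers that know the
    sampling resolution pass ``atol = 1/n_time_samples``.
    """
    lo = np.asarray(ci_low_diff, dtype=float)
    hi = np.asarray(ci_high_diff, dtype=float)
    labels = np.full(lo.shape, NEUTRAL, dtype=object)
    labels[lo > atol] = PREFERRED
    labels[hi < -atol] = AVOIDED
    return labels


def preferred_temperature(bin_centers: np.ndarray, index: np.ndarray, labels: np.ndarray) -> float:
    """Index-weighted mean of the preferred bin centers; NaN when none is preferred."""
    sel = np.asarray(labels) == PREFERRED
    if not sel.any():
        return math.nan
    w = np.asarray(index, dtype=float)[sel]
    return float(np.average(np.asarray(bin_centers, float)[sel], weights=w))


def avoidance_starts(bin_edges: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(cold_start, hot_start) in deg C; NaN where no avoided run touches the end.

    The cold start is the warm edge of the contiguous avoided run anchored at
    the cold end; the hot start is the cool edge of the run anchored at the
    hot end.  Interior avoided islands stay avoided but do not move the
    starts.
    """
    labels = np.asarray(labels)
    edges = np.asarray(bin_edges, dtype=float)
    n = labels.size
    cold_start = math.nan
    if n and labels[0] == AVOIDED:
        i = 0
        while i + 1 < n and labels[i + 1] == AVOIDED:
            i += 1
        cold_start = float(edges[i + 1])
    hot_start = math.nan
    if n and labels[-1] == AVOIDED:
        j = n - 1
        while j - 1 >= 0 and labels[j - 1] == AVOIDED:
            j -= 1
        hot_start = float(edges[j])
    return cold_start, hot_start


def preference_range(bin_edges: np.ndarray, labels: np.ndarray) -> float:
    """Expanse (deg C) of the bins categorized as preferred; 0 when none."""
    sel = np.nonzero(np.asarray(labels) == PREFERRED)[0]
    if sel.size == 0:
        return 0.0
    edges = np.asarray(bin_edges, dtype=float)
    return float(edges[sel[-1] + 1] - edges[sel[0]])


@dataclass(frozen=True)
class PreferenceProfile:
    """Corrected gradient profile: per-bin preference index and derived scalars."""

    bin_edges: np.ndarray
    index: np.ndarray
    labels: np.ndarray
    t_preferred: float
    cold_avoidance_start: float
    hot_avoidance_start: float
    tolerance_range: float
    preference_range: float
    null: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def correct_profile(observed: OccupancyProfile, null: np.ndarray) -> PreferenceProfile:
    """Subtract the null occupancy from an observed profile and derive T_P etc.

    The per-bin median of individual histograms does not itself sum to 1, so
    the observed median and its CI are rescaled by the same factor to unit
    mass before subtraction (the null vector is normalized the same way in
    :func:`null_occupancy`); the preference index then sums to zero exactly.
    """
    null = np.asarray(null, dtype=float)
    scale = observed.median.sum()
    if scale <= 0:
        raise ValueError("degenerate observed profile (zero median mass)")
    med = observed.median / scale
    index = preference_index(med, null)
    atol = 1.0 / observed.n_time_samples if observed.n_time_samples else 0.0
    labels = classify_bins(observed.ci_low / scale - null, observed.ci_high / scale - null,
                           atol=atol)
    centers = observed.bin_centers
    t_p = preferred_temperature(centers, index, labels)
    cold, hot = avoidance_starts(observed.bin_edges, labels)
    tol = hot - cold if not (math.isnan(cold) or math.isnan(hot)) else math.nan
    return PreferenceProfile(
        bin_edges=observed.bin_edges,
        index=index,
        labels=labels,
        t_preferred=t_p,
        cold_avoidance_start=cold,
        hot_avoidance_start=hot,
        tolerance_range=tol,
        preference_range=preference_range(observed.bin_edges, labels),
        null=null,
    )


def null_occupancy(record: SimulationRecord, bin_edges: np.ndarray | None = None,
                   t_from: float = 0.0) -> np.ndarray:
    """Null vector for correction: median over simulated agents, renormalized."""
    if bin_edges is None:
        bin_edges = default_bins(record.arena)
    mask = record.times >= t_from
    rows = np.stack(
        [occupancy_density(p[mask], record.arena, bin_edges) for p in record.positions]
    )
    med = np.median(rows, axis=0)
    s = med.sum()
    if s <= 0:
        raise ValueError("degenerate null occupancy")
    return med / s


def _diff_of_medians(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.median(a) - np.median(b))


def permutation_test(
    sample_a,
    sample_b,
    statistic=_diff_of_medians,
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Two-sided Fisher permutation test on two independent samples.

    Enumerates all label arrangements exhaustively when their number does not
    exceed ``n_perm`` (then the p-value is the exact proportion of
    arrangements with |statistic| >= observed); otherwise draws ``n_perm``
    random permutations and returns (1 + hits) / (1 + n_perm).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    n, n_a = pooled.size, a.size
    obs = abs(statistic(a, b))
    tol = 1e-12 * max(1.0, obs)

    if math.comb(n, n_a) <= n_perm:
        hits = total = 0
        for idx_a in combinations(range(n), n_a):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx_a)] = True
            s = abs(statistic(pooled[mask], pooled[~mask]))
            hits += s >= obs - tol
            total += 1
        return hits / total

    rng = np.random.Generator(np.random.PCG64(seed))
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        s = abs(statistic(perm[:n_a], perm[n_a:]))
        hits += s >= obs - tol
    return (1 + hits) / (1 + n_perm)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)


def paired_t_test(before, after) -> tuple[float, float]:
    """Convenience wrapper: paired t-test, returns (statistic, p)."""
    res = sps.ttest_rel(np.asarray(before, float), np.asarray(after, float))
    return float(res.statistic), float(res.pvalue)
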