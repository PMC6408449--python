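# Methods

## Model

`thermowalk` simulates a small ectotherm in a stable, linear, 1-D
temperature gradient as an event-driven random walk.  The assumptions are:

1. the gradient is stable, linear and one-dimensional;
2. moving toward the hot or cold end is equally probable everywhere (the
   null hypothesis of no temperature preference);
3. the arena walls are reflective — a step beyond a wall folds back by the
   sawtooth map of period 2L, equivalent to an infinite arena with
   repetitive sawtooth gradients;
4. bout velocity and bout duration are drawn independently.  (In real
   animals the two are positively correlated because bouts include an
   acceleration phase; independence underestimates distance travelled, but
   does so similarly at all temperatures, so the stationary *spatial*
   distribution is minimally affected.)

Each bout draws two uniforms P_V, P_D and a fair heading, maps them through
the cohort's velocity and duration quantile surfaces at the current body
temperature, and displaces the agent by `heading * v * d`.  The dynamics
are event-driven (no fixed time step); output positions are sampled onto a
1 s grid by linear interpolation along the constant-speed bout path and
then folded, so within-bout wall crossings are handled exactly.

### Body temperature

Body temperature is a conductive low-pass of ambient temperature.  With
conductance G = λA/D (λ = 0.6 W/(m·K), water; A = 7.85e-6 m², the surface
of a 0.5 mm x 2 mm cylinder; D = 1 mm path length) and heat capacity
C = m/h (m = 0.25 mg, h = 0.2449 °C·g/J), the relaxation time is
τ = C/G ≈ 0.217 s.  The update is the exact exponential solution
T_B′ = T_A + (T_B − T_A)·e^{−t/τ}.  A single explicit-Euler step (heat flow
times bout duration) is the first-order approximation of this law and can
overshoot the ambient temperature for bouts longer than ~τ; the exact form
is identical physics without that artifact (`euler_body_temperature_update`
is retained for reference and consistency checks).  λ is treated as a
conductivity in W/(m·K), which is what the heat-flow formula Q = λA·ΔT/D·t
requires dimensionally.  D is not derivable from the cylinder geometry and
defaults to the body diameter (1 mm), configurable.

Ordering within a bout: the pseudocode ("update body temperature, then
step") leaves a circularity — the heat-flow update integrates over a bout
duration, but sampling the duration needs the updated T_B.  We resolve it
by relaxing T_B toward the local ambient temperature over the time elapsed
since the previous update (i.e. the previous bout's duration), then
sampling the new bout.  With τ ≈ 0.2 s and bouts of 0.5–3 s, T_B tracks T_A
to within a few percent of the gradient span either way.

### Kinematics surfaces

The surfaces are *quantile* maps: a uniform p is an inverse-CDF coordinate,
so `v(p, T)` is the p-th fastest bout velocity at body temperature T.  The
probability-domain factors are written in p (the velocity factor decreases
in p, the duration factor increases); the temperature-domain centers and
widths of the adult velocity surface (26/5.41 °C and 34/2.27 °C) and the
fixed duration constants (scale 20 s, centers 37 °C and µ_t2(T_R), widths
σ_t1(T_R) and 6.44 °C with (2σ)² denominators, probability factor
0.33·e^{−(p−2)²/(2·0.64)²}) are the model's defining constants.  The two
denominator conventions — 2σ² for velocity, (2σ)² for duration — are
intentional and implemented exactly as defined.

## Parameters and shipped defaults

Printed constants (velocity Gaussian centers/widths, duration fixed
constants) ship as-is.  The remaining coefficients are free parameters and
their shipped per-cohort defaults are **calibration outputs**, chosen once
by the following procedure and then frozen:

* `alpha_p = 2750 ≈ 1/G(0.5; −1.49, 0.5)`, so that `alpha_t1` reads
  directly as the median bout velocity (mm/s) at the 26 °C optimum.  Only
  the products `alpha_ti · alpha_p` are identifiable.
* wt25: `alpha_t1 = 1.0`, `alpha_t2 = 0.5` (median speed 1 mm/s at 26 °C,
  heavy fast tail up to ~30 mm/s), duration `sigma_t1 = 6.0`,
  `mu_t2 = 34.0` (median bout ≈ 2.2 s at 26 °C, dropping in the cold).
  These values were selected, before the test suite was frozen, to satisfy
  the qualitative assay picture: near-zero movement at the coldest
  temperatures, realistic bout speeds and durations, and a stationary
  cold-trapped fraction (coldest 4 mm of a 14–32 °C, 50 mm gradient) in the
  70–80 % band that defines the adult reference behaviour.  The shipped
  defaults give ≈ 74 % with 1000 agents.
* wt18 (cold-acclimated): same speeds with a flatter duration profile
  (`sigma_t1 = 10`), hence long bouts in the cold and less cold-trapping.
* wt30: globally slow (`alpha_t1 = 0.4`), so the cohort needs several-fold
  longer to reach its stationary cold-trapped ratio.
* Larvae: 4th-degree temperature x 3rd-degree probability velocity
  polynomial (anchored to a near-linear rise from ~0 at 8 °C, clamped at
  zero, monotone below 10 °C) and a duration that is the sum of two
  Gaussian products with temperature centers fixed at 9 and 34 °C.  The
  shipped larval defaults produce ≈ 40 % cold-trapped larvae —
  qualitatively below the adult cohorts, as expected from larval cold
  resilience, though weaker than the ~60 % the adult-calibrated reasoning
  would suggest; pushing larval trapping higher would require abandoning
  the near-linear velocity profile, so the qualitative ordering was kept.
  This is a known limitation.

Rearing temperatures between the three adult anchors are served by linear
interpolation of the rearing-dependent coefficients
(`adult_kinematics_for_rearing`), a configuration convenience rather than a
fitted relationship.  All defaults are overridable through YAML parameter
files.

## Calibration module

Bout tables are binned into column-normalized 2-D histograms (defaults:
1 mm/s or 1 s value bins by 2 °C temperature columns; fully configurable).
Surface fitting is nonlinear least squares on the *cumulative* form: for
each temperature column the empirical quantile function (piecewise-linear
CDF inverted at 19 probability levels) is matched against the surface's
quantile prediction — `v(1−q, T)` for the decreasing velocity factor,
`d(q, T)` for the increasing duration factor.  Fits initialize at the wt25
constants, bound σ > 0 and temperature centers within the assay range, and
hold `alpha_p` fixed (scale degeneracy).  Parameter recovery from 1e5
synthetic bouts returns both velocity temperature centers within ±0.2 °C.

The empirical mode replaces the fitted surfaces by inverse-CDF lookup in
the nearest temperature column, returning populated-bin centers (no
within-bin interpolation, so a single-bin column returns its center for
every p).  Fitted and empirical modes agree in simulated occupancy to
< 0.02 per 1 °C bin when the histogram is built with fine bins
(≤ 0.5 °C columns near the cold wall); with the coarse display binning the
nearest-column quantization at the cold wall costs ~0.02 of cold-bin mass.
The fitted mode exists precisely to be continuous in temperature.

## Correction

Occupancy is a time-weighted histogram over 1 °C temperature bins (bins
half-open [lo, hi) with the final bin closed; positions in mm with the cold
end at 0).  The null vector is the per-bin median over the simulated
agents of the matching cohort/arena, renormalized to unit mass; the
observed group median and its CI are rescaled by the same factor before
subtraction, which makes the preference index sum to zero exactly.

Significance is the CI-exclusion rule: preferred if the entire 95% CI of
the observed (median) occupancy lies above the null, avoided if entirely
below, neutral otherwise.  No additional per-bin multiple-testing
correction is applied; FDR control is reserved for between-group
comparisons.  Two CI modes exist:

* **exact** (default): the distribution-free order-statistic interval for
  the median, with ranks at the binomial(n, 1/2) quantiles.  Per-agent
  occupancy in a trapping gradient is strongly bimodal, and on such data
  the percentile bootstrap measurably undercovers — feeding the model's own
  null cohorts back through the correction left only ~94 % of bins neutral,
  versus ~97–99 % with the exact interval.
* **bootstrap**: percentile interval over resampled individuals (10⁴
  seeded resamples), retained because it generalizes to statistics without
  order-statistic theory.

Classification applies a quantization guard: occupancy estimated from n
time samples is quantized in steps of 1/n, and each cohort's
renormalization shifts those atoms by ~1e-5, so a CI that clears the null
by less than one sample's mass (atol = 1/n) is not a meaningful exclusion.
Real effects are two orders of magnitude above the guard.

T_P is the preference-index-weighted mean of the preferred bin centers
(undefined when nothing is preferred).  Avoidance starts are the inner
edges of the contiguous avoided runs anchored at the arena ends; interior
avoided islands stay labelled avoided but do not move the starts; the
tolerance range is the span between the two starts and the preference
range the expanse of preferred bins.  For single animals, exact
Clopper–Pearson intervals on the per-bin occupancy proportion replace the
group median CI.

Fisher's permutation test (difference of medians by default) enumerates
all arrangements exhaustively when their count does not exceed the
permutation budget — the p-value is then the exact proportion with
|statistic| at least the observed — and otherwise uses seeded Monte-Carlo
permutations with the (1+hits)/(1+n) estimator.  Benjamini–Hochberg
adjustment wraps statsmodels.

## Synthetic data

The generator is first-class code, not a fixture store.  Bout tables draw
(velocity, duration) through the same `sample_bout` path at a grid of
assay temperatures (default: odd degrees 11–41 °C, so assay points sit at
the centers of 2 °C histogram columns); walkers run through the same
simulator core, with preference injected *only* through the heading
(probability 0.5 + b toward the target temperature, b = 0 being bit-for-bit
the null model).  Default study conditions: 45 individuals per group (a
typical gradient-assay group size), 50 mm 14–32 °C arena, 30 simulated
minutes with the first 10 discarded as settling, 1000-agent null cohorts.

What the generator does *not* emulate: measurement noise beyond optional
Gaussian position jitter, tracking artifacts, inter-animal variability in
kinematics (all agents of a cohort share one surface), humidity effects,
and chill-coma hysteresis beyond what the velocity/duration surfaces
encode.  Passing tests therefore demonstrate the correctness of the
machinery and the internal consistency of the model, not the biological
accuracy of any particular cohort's parameters on real animals.

An independent oracle validates the walker: the arena is discretized into
150–200 cells, the bout kernel is integrated by quadrature over the
probability domain into a jump-chain transition matrix, its stationary
vector is solved exactly, and occupancy is time-weighted by spreading each
bout's duration along its folded constant-speed path.  Monte-Carlo
occupancy matches this oracle within 3 standard errors plus a small
discretization allowance for both null and biased walkers; this oracle is
also what exposed (during development) that headings must be converted
from the folded arena frame to the unfolded sawtooth coordinate.

## Numerical and design notes

* RNG: one `numpy` PCG64 stream per agent, spawned from the run seed via
  `SeedSequence`, so records are reproducible and order-independent.
* The equilibrium detector reports the earliest time from which the
  cold-trapped fraction stays within ±tolerance of its trailing-window
  median, `inf` when never stable.  The tolerance must exceed the binomial
  noise of the agent count (≥ 4–5 σ) or the detector reads noise
  excursions as instability.
* Problem sizes in the test suite (cohorts of 300–2000 agents, 20–45
  simulated minutes, 1e5-bout fit tables) were chosen as the smallest
  sizes at which the Monte-Carlo error is comfortably inside each check's
  tolerance.
* Degenerate inputs: empty bout tables, < 5 temperature columns, < 3
  individuals for a median CI, zero-length traces, non-monotone or
  non-uniform frame times, and out-of-range probabilities all raise
  `ValueError` with a specific message; out-of-range temperatures in the
  empirical sampler clamp to the nearest column with a logged warning.
* The CLI (`simulate`, `fit`, `correct`, `metrics`, `synth`) is a thin
  layer over the library; every command writes a JSON manifest (full
  configuration, seed, package version, SHA-256 digests of inputs and
  outputs) sufficient to reproduce deterministic outputs bit for bit.

## Known limitations

* The walk is strictly 1-D; no turning kinematics, pauses are implicit in
  the bout-duration distribution, and there are no group interactions (by
  design — aggregation is the bias the model avoids).
* Cross-rearing-temperature interpolation is linear between three anchors.
* Larval cold-trapping is weaker than the adult-calibrated expectation
  (see above).
* The null vector is treated as exact by the CI-exclusion rule; its own
  Monte-Carlo error is made negligible by using ≥ 1000-agent null cohorts
  rather than by widening the intervals.
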