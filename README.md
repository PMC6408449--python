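# thermowalk

Individual-based random-walk null model and bias correction for thermal
preference assays of small ectotherms.

## The problem

Placing a fly or larva in a linear temperature gradient and recording where
it spends its time is the standard way to measure an absolute temperature
preference (T_P).  But an ectotherm's locomotion slows drastically in the
cold: animals that wander into the cold end linger there or fall into
chill-coma-like stasis, so the raw residence histogram is biased toward cold
temperatures ("cold-trapping").  Group-based diffusion models correct for
this at the population level, but aggregation biases group behaviour; this
package instead simulates *individual* walkers whose bout-based locomotion
depends on body temperature but whose heading does not — the occupancy such
agents produce is the null distribution of an animal with no temperature
preference, and subtracting it from a measured distribution yields unbiased
preference indices, T_P, avoidance onsets, and tolerance ranges.

## The model

An agent in a linear gradient (cold end at position 0) repeats discrete
walking bouts.  For bout *i*:

    step_i  =  ±1 · v(P_V, T_B) · d(P_D, T_B)

where P_V, P_D ~ U(0,1) are fresh uniform draws, the heading ±1 is a fair
coin, and `v` (mm/s) and `d` (s) are quantile surfaces fitted to climbing /
crawling assays.  For adults the velocity surface is a product of Gaussians

    v(p, T_B) = (α_t1 e^{−(T_B−26)²/2·5.41²} + α_t2 e^{−(T_B−34)²/2·2.27²})
                · α_p e^{−(p+1.49)²/2·0.5²}

and the duration surface uses (2σ)² denominators

    d(p, T_B) = 20 (e^{−(T_B−37)²/(2σ_t1)²} + e^{−(T_B−µ_t2)²/(2·6.44)²})
                · 0.33 e^{−(p−2)²/(2·0.64)²}

with σ_t1, µ_t2 depending on rearing temperature.  Body temperature follows
ambient temperature through a conductive low-pass, T_B′ = T_A + (T_B−T_A)
e^{−t/τ} with τ ≈ 0.22 s for a fly-sized water cylinder.  Walls reflect the
agent (sawtooth fold of period 2L).  Correction: per-bin preference index =
p_observed − p_null; a bin is significantly preferred/avoided when the 95%
CI of the observed group median clears the null entirely; T_P is the
index-weighted mean of the preferred bin centers.

## Worked example

Simulate the reference cohort (wild-type adults reared at 25 °C) in a
14–32 °C, 50 mm gradient, then recover a known synthetic preference:

```python
import numpy as np
import thermowalk as tw
from thermowalk.correction import (OccupancyProfile, correct_profile,
                                   default_bins, null_occupancy)
from thermowalk.simulator import cold_trapped_fraction
from thermowalk.synthetic import SyntheticSpec, generate_walkers

cfg, arena = tw.get_cohort("wt25"), tw.GradientArena()
null = tw.run_cohort(1000, 1800.0, arena, cfg.kinematics, cfg.body, seed=1)
frac = cold_trapped_fraction(null, zone_mm=4.0)
print(f"cold-trapped at equilibrium: {np.median(frac[null.times >= 1200]):.1%}")

bins = default_bins(arena)                      # 1 deg C bins, 14..32
walkers = generate_walkers(SyntheticSpec(n_individuals=45, bias=0.2,
                                         target_temp=22.0, seed=2))
obs = OccupancyProfile.from_record(walkers, bins, t_from=600.0)
profile = correct_profile(obs, null_occupancy(null, bins, t_from=600.0))
print(f"recovered T_P: {profile.t_preferred:.2f} C")
```

Output:

```
cold-trapped at equilibrium: 73.6%
recovered T_P: 21.61 C
```

73.6% of the preference-free agents end up in the coldest 4 mm — that is
the magnitude of the cold-trapping bias a raw histogram would absorb — and
the correction recovers the walkers' built-in 22 °C preference to within
one bin despite it.

The same pipeline is scriptable from the shell (`thermowalk simulate`,
`synth`, `metrics`, `fit`, `correct`); every command writes a JSON run
manifest with the full configuration and seed.

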