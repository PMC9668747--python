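# plateaulearn

Models and analysis for how entorhinal cortex layer 3 (EC3) input can
direct the formation of hippocampal CA1 place-cell representations during
spatial learning on a circular treadmill.

When a mouse learns a fixed reward location on a 180-cm belt, the CA1 map
over-represents that location: previously silent pyramidal neurons acquire
place fields abruptly, in a single lap, through behavioural-timescale
synaptic plasticity (BTSP) — a rule driven by seconds-long dendritic
plateau potentials in the apical tuft, where EC3 axons terminate. This
package implements, as a tested library:

- **`plateaulearn.chains`** — EC3 persistent activity as two-state Markov
  chains (per step Δt: inactive→active with probability `P01·Δt`,
  active→inactive with `P10·Δt`), with environment-specific spatial tuning
  imposed by recurring 1-s boosts of `P01` at fixed within-lap phases,
  plus the chain spatial metrics (peak histograms, selectivity index
  max/mean, odd–even lap correlations, activity–velocity correlation).
- **`plateaulearn.plateau`** — the plateau threshold model: each of
  10,000 model CA1 neurons receives `drive(t) = Σ_{i∈S} x_i(t) −
  0.05·Σ_{all} x_i(t)` with `|S| = 100` of 2,000 chains; a threshold is
  calibrated so 20–25% of neurons cross it during a session, and upward
  crossings — the proxy for plateau initiation — are mapped to spatial
  bins through the dwell-time profile.
- **`plateaulearn.signals`** — calcium-trace processing: ΔF/F with F0 the
  mode of the fluorescence histogram, significant-transient detection at
  3σ of the noise, EC3 ROI→axon merging by trace correlation (threshold
  0.45), and reward-aligned 50-bin (3.6 cm) lap-by-bin activity maps from
  running frames (velocity > 2 cm/s), boxcar-smoothed.
- **`plateaulearn.placecells`** — place-cell identification: the eventual
  field (contiguous bins > 20% of peak), the induction lap (first lap with
  significant field activity confirmed in ≥2 of the 5 following laps),
  spatial information `SI = Σᵢ Pᵢ λᵢ log₂(λᵢ/λ)` tested against 100
  circular-shift/chunk-permutation shuffles, reliability (> 30% of
  post-induction laps), plus BTSP signatures (backward peak shift,
  width–velocity relation) and population summaries.
- **`plateaulearn.synth`** — a seeded generator of treadmill behaviour,
  CA1 fluorescence with ground-truth place fields, and EC3 axonal ROI
  traces with known axon groupings, so every stage is testable without any
  recordings.
- **`plateaulearn.pipeline`** — one-call end-to-end runs with a saved,
  reproducible configuration.

## Worked example

```python
import numpy as np
import plateaulearn as pl
from plateaulearn.chains import SpaceMapping

population = pl.simulate_chains(pl.build_config("A"), seed=1)
drives = pl.simulate_population_drive(population, n_neurons=10_000,
                                      n_inputs=100, inhibition_scale=0.05,
                                      seed=2)
threshold, recruited = pl.calibrate_threshold(drives)
zone = pl.zone_bins(90.0)                       # reward ± 18 cm
mapping = SpaceMapping.with_zone_factor(zone, 2.0)   # ~2x dwell at reward
result = pl.crossing_profile(drives, threshold, mapping, population,
                             recruited_fraction=recruited)
off = np.setdiff1d(np.arange(50), zone)
print(f"{recruited:.1%} recruited; reward-zone enrichment "
      f"{result.crossing_profile[zone].mean() / result.crossing_profile[off].mean():.2f}")
```

prints

```
22.2% recruited; reward-zone enrichment 1.93
```

— the calibrated threshold recruits 22.2% of model neurons (inside the
observed 20–25% band of CA1 cells forming new fields per session), and
doubling the dwell time in the reward zone roughly doubles the
plateau-initiation probability there: the over-representation emerges from
the running behaviour alone, with spatially uniform EC3 drive. The
`examples/` directory walks through each capability (synthetic sessions,
the place-cell pipeline, chain configurations for both environments, the
plateau prediction, and the end-to-end run).

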