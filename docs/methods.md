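# Methods

## The model in brief

CA1 pyramidal neurons acquire place fields through behavioural-timescale
synaptic plasticity (BTSP), which is triggered by seconds-long dendritic
plateau potentials in the apical tuft. The tuft is innervated by
entorhinal-cortex layer-3 (EC3) axons, so the spatial statistics of EC3
activity — together with the animal's running behaviour — determine where
along the track plateaus, and therefore new place fields, are most likely
to arise. The package implements this causal chain in three parts: a
stochastic model of EC3 activity, a threshold model of plateau initiation,
and the calcium-imaging analysis that measures the resulting place-cell
population.

## EC3 chains

Each EC3 axon is a two-state Markov chain on a Δt = 0.1 s grid: an
inactive chain activates with probability `P01·Δt` per step and an active
chain inactivates with `P10·Δt`. This produces exponentially distributed
active and inactive periods with means `1/P10` and `1/P01` — the
persistent-firing regime characteristic of EC3 — and a stationary active
fraction `P01/(P01+P10)`. Sessions are 50 laps of 10 s (100 steps per
lap); chains start inactive and the first 100 steps are discarded as
burn-in. The per-step transition draw uses a continuous uniform variate
compared against `P·Δt`, equivalent to an integer scheme at 1/1000
granularity without requiring `P·100` to be integral.

Parameters and defaults:

| parameter | default | meaning |
| --- | --- | --- |
| `n_chains` | 2000 | approximate count of tuft synapses on a CA1 neuron |
| `P01` (base) | 0.04 s⁻¹ | baseline activation rate → 25-s mean inactive period |
| `P10` | 0.25 s⁻¹ | inactivation rate → 4-s mean active period |
| boost | 0.20 / 0.28 s⁻¹ | elevated `P01` for 1 s (10 steps) per lap |
| `dt` | 0.1 s | transition-probability step |

`P10` is a modelling choice: the seconds-scale persistent-activity regime
constrains it only loosely, and 4-s mean active periods sit in the middle
of that regime. It is exposed in `ChainConfig` for sensitivity analysis.

Spatial tuning is imposed by recurring boosts: a modulated chain's `P01`
steps up to the boost value for 10 steps starting at a fixed within-lap
phase, every lap. Environment A (uniform cue-rich belt) modulates 1400 of
2000 chains at boost 0.20 s⁻¹, 14 chains per phase step so the phases tile
all 100 steps; 600 chains stay homogeneous. Environment B (single
predictive cue at 40 cm) modulates 1850 chains at boost 0.28 s⁻¹ with
phase density `1 + A·exp(−d²/2σ²)` about the cue (σ = 10 cm), leaving 150
homogeneous. Because excess activity accumulates across the boost window
and persists for ~`1/P10` afterwards, a chain's spatial activity peak sits
at the *end* of its boost window, not its start; the density is therefore
applied to window ends. The amplitude was calibrated once (A = 30) so the
cue-zone fraction of chain activity peaks is about three times the uniform
configuration's, then frozen. With `enhanced_tuning` on, the ~100
modulated chains whose phases fall nearest the salient zone get their
boost raised to 0.68 s⁻¹ (A) or three times the B boost, mimicking the
enhanced tuning observed around reward/cue.

Chain metrics (selectivity index = max/mean of the across-lap mean map,
odd–even lap correlation with a 10-cm peak-agreement criterion,
activity–velocity correlation, fraction of active laps) operate on
lap-by-bin maps built by assigning within-lap steps to 50 spatial bins via
cumulative dwell time and smoothing each lap with a circular three-point
boxcar. Odd–even comparisons at full scale use a 1000-chain subsample to
match typical recorded-axon counts.

## Plateau threshold model

Each of 10,000 model CA1 neurons sums 100 chains sampled without
replacement (5% of the input population, independently per neuron) and
subtracts feedforward inhibition equal to 5% of the all-chain sum:
`drive(t) = Σ_{i∈S} x_i(t) − 0.05·Σ_all x_i(t)`. A single threshold,
shared across neurons, is found by bisection so that the fraction of
neurons with at least one upward crossing during the session lands in the
20–25% band (aiming at 0.225) — the observed fraction of CA1 cells that
form a new place field in a session. Upward crossings (drive passes the
threshold from below; no refractoriness, consecutive crossings distinct)
are the proxy for plateau initiation; each is assigned to the spatial bin
of its time step through the dwell mapping, and the profile is crossings
per bin divided by the neuron count. The drive is thresholded unsmoothed.
The profile is reported on the 50-bin grid used everywhere else; a
coarser grid is available through `SpaceMapping`.

Numerical notes: excitatory sums are stored as uint8 (exact for ≤255
inputs) with the inhibitory waveform shared, so the 10,000-neuron ensemble
fits in ~50 MB; calibration starts from the per-neuron maximum-drive
quantile, which is already near-exact because a neuron whose maximum
exceeds the threshold almost surely crosses it from below at least once.

A caveat measured by the test suite: with the default `P10`, a 500-s
session yields a few thousand crossing events in total, so the per-bin
counting noise of the constant-speed profile is of order 10%, and its
max/min bin ratio lands well above what the noiseless expectation (exactly
flat) would suggest. The dwell-driven *enrichment* — a zone average over
ten bins against the remote-track average — is robust at this event count;
the single-bin extremes are not.

## Trace processing

- **ΔF/F**: `F0` is the mode of the fluorescence histogram, implemented as
  the centre of the tallest of 100 equal bins spanning the 1st–99th
  percentile of F (bin rule configurable). Requires ≥1000 frames.
- **Noise**: σ is the RMS of negative ΔF/F values (mirrored about zero),
  robust to the positive-going transients; a zero estimate is an error
  (degenerate trace).
- **Significant transients**: excursions with ΔF/F above 3σ for at least
  2 consecutive frames (the duration guard suppresses single-frame shot
  noise).
- **Axon merging**: ROIs are linked when the Pearson correlation of their
  ΔF/F traces reaches the threshold (default 0.45, the midpoint of the
  0.4–0.5 range used in practice); connected components form axons and the
  merged trace is the pixel-count-weighted mean. Correlation uses the full
  traces by default — axonal signal dominates them — with a
  significant-frame-masked variant behind the `mode` flag.
- **Activity maps**: 50 bins of 3.6 cm, half-open `[k·3.6, (k+1)·3.6)`,
  running frames only (velocity > 2 cm/s); empty bins are filled by
  circular linear interpolation before a circular three-point boxcar (the
  belt is a loop, so all smoothing wraps); maps are rotated so the reward
  sits in bin 26 (environment A) or 24 (environment B), 1-based. Laps
  without running frames are flagged invalid and excluded from averages.

## Place-cell identification

For each unit: (1) the eventual field is the maximal contiguous circular
run of bins above 20% of the mean-map peak that contains the peak (ties on
the peak break to the lowest bin index; one field per unit); (2) the
induction lap is the earliest lap with significant field activity
confirmed by significant field activity in ≥2 of the 5 following laps —
if the field subsequently disappears for more than 20 consecutive laps the
candidate is treated as a false start and the search resumes after the
gap; (3) spatial information is computed over post-induction laps as
`SI = Σᵢ Pᵢ λᵢ log₂(λᵢ/λ)` with `λ = Σᵢ Pᵢ λᵢ` (the occupancy-weighted
mean, which makes SI a Jensen divergence and hence non-negative; an
unweighted-mean variant is behind a flag), occupancy `Pᵢ` from running
frames only; (4) the unit passes if SI exceeds the 95th percentile
(empirical quantile, linear interpolation) of 100 shuffles — each shuffle
circularly shifts the post-induction trace by ≥500 frames, then splits it
into six equal chunks and permutes their order (identity excluded, chunk
boundaries applied after the shift); and (5) reliability — the fraction of
post-induction laps with significant field activity — must exceed 0.30.
Negative binned activity (noise dips below baseline) is clipped to zero
inside the SI sum.

BTSP signatures: the peak shift is the circular signed difference between
the post-induction mean-map peak and the induction-lap activity peak,
wrapped to (−90, +90] cm with negative = backward (opposite running);
induction-lap velocity is the mean of running-frame velocities on that
lap; the width–velocity relation averages widths in 5 cm/s velocity bins
and fits a line to the bin means.

## Synthetic data

The generator emulates: a 180-cm belt sampled on the 30-Hz imaging clock
(behaviour and imaging share one clock — this removes resampling ambiguity
and changes no statistic); running at 18 cm/s with half speed within
±18 cm of the reward, which exactly doubles per-bin dwell time there;
lognormal per-lap speed jitter (σ = 0.05); brief stops (0.5 s) just before
the reward on 10% of laps so the running filter has frames to remove;
licking as an inhomogeneous point process ramping up 0–20 cm before the
reward. CA1 units are place cells (silent until an induction lap, then a
Gaussian spatial field traversed every lap with lognormal amplitude jitter
σ = 0.3), noise-only units (spontaneous transients at random times,
~0.02 Hz), or silent units. Field width is proportional to the
induction-lap running speed (default 2.0 s of travel, floored at two bins)
and the field centre sits a fixed 5 cm behind the induction-lap activity
peak. Fluorescence is `F0·(1 + signal) + noise` with a 50-ms-rise /
300-ms-decay transient kernel and additive Gaussian noise (σ = 0.1 ΔF/F);
activation is shifted earlier by the kernel's temporal centroid so the
fluorescence peak lands on the ground-truth centre despite the indicator
lag. EC3 ROI traces convolve resampled chain states with the same kernel
and split each axon into 1–3 ROIs sharing the signal with independent
noise (σ = 0.15).

What the generator does **not** emulate: pixel-level movies (no motion
artefacts, no segmentation errors, no neuropil contamination), indicator
nonlinearity and saturation, slow drift in F0, theta-timescale spiking
structure, experience-dependent drift of field amplitude, or
reward-concentrated field placement (field centres are uniform by
default). Passing recovery tests therefore demonstrates correctness of the
analysis chain under the stated forward model, not robustness to every
artefact of real recordings.

## Problem sizes

The test suite and acceptance script run the models at their study-scale
defaults: 2,000 chains × 5,000 retained steps, 10,000 model neurons, and a
200-unit, 60-lap synthetic session (~21,700 frames) for parameter
recovery; shuffle tests use 100 shuffles per unit. The closed-form period
laws are checked on a 500-chain, 200-lap run because excluding
end-censored periods biases the completed-period mean low by roughly
(mean period)/(window length) — about 5% at 500 s, about 1% at 2,000 s.
The end-to-end example and pipeline tests use reduced sizes; `RunConfig`
defaults are the full conditions.

## Known limitations

- The model's `P10` is a regime-level choice, not a fitted value; chain
  odd–even correlations and crossing counts depend on it.
- The environment-B phase-density shape is constrained only through its
  outcome (the ~3-fold cue-zone enrichment); different density shapes
  could produce the same enrichment.
- The plateau model abstracts dendritic integration to a subtraction and
  a fixed threshold: no conductances, no voltage dynamics, no per-neuron
  threshold variability.
- Group-comparison hypothesis tests between experimental arms are out of
  scope; the package reports correlations and descriptive summaries only.
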