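"""Dendritic-plateau threshold model for place-field recruitment.

Each model CA1 neuron receives 100 of the 2000 EC3 chains (5% of the
input population, roughly matching the count of distal-tuft synapses times
a plausible active fraction).  Feedforward inhibition is the sum of all
chains scaled by the same fraction; the net drive is the excitatory sum
minus that inhibitory waveform.  A drive threshold is calibrated so that
the fraction of model neurons with at least one upward threshold crossing
during the session matches the observed fraction of CA1 cells that form a
new place field (20-25%).  Upward crossings, assigned to spatial bins via
a dwell-time mapping, are the proxy for plateau-potential initiation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .chains import ChainPopulation, SpaceMapping

_BATCH = 1000


@dataclass
class DriveEnsemble:
    """Compact per-neuron net drive: integer excitatory sums plus the
    shared inhibitory waveform (drive = exc - inh)."""

    exc: np.ndarray               # (n_neurons, T) uint8, sum of sampled inputs
    inh: np.ndarray               # (T,) float32, inhibition_scale * total sum
    inhibition_scale: float
    n_inputs: int

    @property
    def n_neurons(self) -> int:
        return self.exc.shape[0]

    @property
    def n_steps(self) -> int:
        return self.exc.shape[1]

    def drive(self, neurons=slice(None)) -> np.ndarray:
        return self.exc[neurons].astype(np.float32) - self.inh


@dataclass
class PlateauResult:
    threshold: float
    recruited_fraction: float
    crossing_profile: np.ndarray            # crossings per bin / n_neurons
    crossing_profile_constant_speed: np.ndarray
    n_model_neurons: int
    n_inputs_per_neuron: int
    inhibition_scale: float
    dwell: np.ndarray


def simulate_population_drive(population: ChainPopulation,
                              n_neurons: int = 10_000,
                              n_inputs: int = 100,
                              inhibition_scale: float = 0.05,
                              seed: int = 0) -> DriveEnsemble:
    """Net drive traces for a population of model CA1 neurons.

    Input subsets are drawn without replacement within a neuron and
    independently across neurons.
    """
    if not (0.0 <= inhibition_scale <= 1.0):
        raise ValueError("inhibition_scale must lie in [0, 1]")
    states = population.states
    n_chains, n_steps = states.shape
    if n_inputs > n_chains:
        raise ValueError("n_inputs exceeds the number of chains")
    if n_inputs > 255:
        raise ValueError("n_inputs above 255 overflows the uint8 drive store")
    rng = np.random.default_rng(seed)
    states_f = states.astype(np.float32)
    inh = (inhibition_scale * states_f.sum(axis=0)).astype(np.float32)
    exc = np.empty((n_neurons, n_steps), dtype=np.uint8)
    for start in range(0, n_neurons, _BATCH):
        stop = min(start + _BATCH, n_neurons)
        b = stop - start
        # without-replacement sample per neuron via random-key argpartition
        keys = rng.random((b, n_chains))
        idx = np.argpartition(keys, n_inputs - 1, axis=1)[:, :n_inputs]
        sel = np.zeros((b, n_chains), dtype=np.float32)
        np.put_along_axis(sel, idx, 1.0, axis=1)
        exc[start:stop] = np.rint(sel @ states_f).astype(np.uint8)
    return DriveEnsemble(exc=exc, inh=inh, inhibition_scale=inhibition_scale,
                         n_inputs=n_inputs)


def _crossing_stats(ensemble: DriveEnsemble, threshold: float,
                    per_step: bool = False):
    """Fraction of neurons with >=1 upward crossing and (optionally) the
    total crossing count per time step."""
    thr = threshold + ensemble.inh  # drive > threshold  <=>  exc > thr
    recruited = 0
    counts = np.zeros(ensemble.n_steps, dtype=np.int64) if per_step else None
    for start in range(0, ensemble.n_neurons, _BATCH):
        e = ensemble.exc[start:start + _BATCH]
        above = e > thr
        crossings = above[:, 1:] & ~above[:, :-1]
        recruited += int(np.count_nonzero(crossings.any(axis=1)))
        if per_step:
            counts[1:] += crossings.sum(axis=0)
    frac = recruited / ensemble.n_neurons
    return (frac, counts) if per_step else frac


def calibrate_threshold(ensemble: DriveEnsemble,
                        target_band: tuple[float, float] = (0.20, 0.25),
                        max_iter: int = 80) -> tuple[float, float]:
    """Bisection for the drive threshold whose recruited fraction (neurons
    with >=1 upward crossing) falls inside ``target_band``.

    Starts from the per-neuron maximum-drive quantile at the band midpoint,
    which is already near-exact because almost every neuron whose maximum
    exceeds the threshold crosses it from below at least once.
    """
    lo_f, hi_f = target_band
    mid = 0.5 * (lo_f + hi_f)
    max_drive = np.empty(ensemble.n_neurons, dtype=np.float32)
    for start in range(0, ensemble.n_neurons, _BATCH):
        d = ensemble.drive(slice(start, start + _BATCH))
        max_drive[start:start + _BATCH] = d.max(axis=1)
    if np.ptp(max_drive) == 0:
        raise ValueError("degenerate drive distribution; cannot calibrate")
    theta = float(np.quantile(max_drive, 1.0 - mid))
    frac = _crossing_stats(ensemble, theta)
    if lo_f <= frac <= hi_f:
        return theta, frac
    lo, hi = float(max_drive.min()) - 1.0, float(max_drive.max()) + 1.0
    for _ in range(max_iter):
        theta = 0.5 * (lo + hi)
        frac = _crossing_stats(ensemble, theta)
        if lo_f <= frac <= hi_f:
            return theta, frac
        if frac > mid:
            lo = theta    # recruited too many -> raise threshold
        else:
            hi = theta
    raise ValueError(
        f"target band {target_band} unreachable; last fraction {frac:.3f}")


def crossing_profile(ensemble: DriveEnsemble, threshold: float,
                     mapping: SpaceMapping, population: ChainPopulation,
                     recruited_fraction: float | None = None) -> PlateauResult:
    """Spatial profile of threshold crossings (plateau-initiation proxy).

    Every upward crossing is assigned to the spatial bin of its time step
    via the dwell mapping; the profile is crossings per bin divided by the
    number of model neurons.  A constant-speed reference profile is
    computed alongside.
    """
    c = population.config
    if recruited_fraction is None:
        recruited_fraction = _crossing_stats(ensemble, threshold)
    _, counts = _crossing_stats(ensemble, threshold, per_step=True)
    step_of_t = np.arange(ensemble.n_steps) % c.steps_per_lap

    def _bin_counts(m: SpaceMapping) -> np.ndarray:
        return np.bincount(m.step_to_bin[step_of_t], weights=counts,
                           minlength=m.n_bins)

    const = SpaceMapping.constant_speed(n_bins=mapping.n_bins,
                                        steps_per_lap=c.steps_per_lap, dt=c.dt)
    return PlateauResult(
        threshold=float(threshold),
        recruited_fraction=float(recruited_fraction),
        crossing_profile=_bin_counts(mapping) / ensemble.n_neurons,
        crossing_profile_constant_speed=_bin_counts(const) / ensemble.n_neurons,
        n_model_neurons=ensemble.n_neurons,
        n_inputs_per_neuron=ensemble.n_inputs,
        inhibition_scale=ensemble.inhibition_scale,
        dwell=mapping.dwell,
    )


def compare_profiles(model_profile: np.ndarray, observed_density: np.ndarray,
                     zone: np.ndarray | None = None) -> dict:
    """Compare a model crossing profile with an observed place-cell density.

    Both are scaled to unit mean; reports the Pearson correlation across
    bins (with its two-sided p value) and, if a zone is given, each curve's
    zone fold-enrichment (zone mean / off-zone mean).
    """
    m = np.asarray(model_profile, dtype=float)
    o = np.asarray(observed_density, dtype=float)
    if m.shape != o.shape:
        raise ValueError("profiles must share the bin grid")
    out: dict = {}
    for name, prof in (("model", m), ("observed", o)):
        scaled = prof / prof.mean() if prof.mean() > 0 else prof
        out[f"{name}_scaled"] = scaled
        if zone is not None:
            zone_idx = np.asarray(zone, dtype=int)
            off = np.setdiff1d(np.arange(prof.size), zone_idx)
            off_mean = prof[off].mean()
            out[f"{name}_zone_enrichment"] = (
                float(prof[zone_idx].mean() / off_mean) if off_mean > 0 else np.nan)
    if np.std(m) == 0 or np.std(o) == 0:
        out["r"], out["p"] = float("nan"), float("nan")
        out["degenerate"] = True
    else:
        r, p = stats.pearsonr(m, o)
        out["r"], out["p"] = float(r), float(p)
        out["degenerate"] = False
    return out
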