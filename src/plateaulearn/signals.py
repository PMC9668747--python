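"""Fluorescence trace processing and spatial activity maps.

The processing chain mirrors the standard treadmill two-photon pipeline:
raw fluorescence is converted to dF/F with the baseline F0 taken as the
mode of the fluorescence histogram; significant transients are excursions
whose dF/F exceeds three standard deviations of the noise; EC3 axonal ROIs
are merged into putative parent axons when their trace correlation exceeds
a threshold (0.4-0.5 in practice, default 0.45); and activity is binned
into 50 spatial bins of 3.6 cm using running frames only (velocity >
2 cm/s), smoothed with a circular three-point boxcar and rotated so the
reward sits in spatial bin 26 (environment A) or 24 (environment B;
1-based convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .synth import BehaviorSession, RoiTraceSet, RUNNING_THRESHOLD_CMS
from .utils import circular_boxcar, circular_interpolate_nan

N_BINS = 50
BIN_WIDTH_CM = 3.6
# 1-based "reward in bin 26 / bin 24" convention -> 0-based indices
REWARD_BIN = {"A": 25, "B": 23}


# ---------------------------------------------------------------------------
# dF/F and transients
# ---------------------------------------------------------------------------

def estimate_f0(F: np.ndarray, n_hist_bins: int = 100,
                pct: tuple[float, float] = (1.0, 99.0)) -> float:
    """Mode of the fluorescence histogram: centre of the tallest of 100
    equal bins spanning the 1st-99th percentile of F."""
    lo, hi = np.percentile(F, pct)
    if hi <= lo:
        return float(lo)
    counts, edges = np.histogram(F, bins=n_hist_bins, range=(lo, hi))
    k = int(np.argmax(counts))
    return float(0.5 * (edges[k] + edges[k + 1]))


def compute_dff(traces: RoiTraceSet, n_hist_bins: int = 100) -> RoiTraceSet:
    """dF/F = (F - F0) / F0 per ROI, F0 from the histogram mode."""
    if traces.n_frames < 1000:
        raise ValueError("need >= 1000 frames for a stable F0 estimate")
    dff = np.empty_like(traces.F, dtype=float)
    for i in range(traces.n_rois):
        f0 = estimate_f0(traces.F[i], n_hist_bins)
        if f0 <= 0:
            raise ValueError(f"non-positive F0 estimate for ROI {i}")
        dff[i] = (traces.F[i] - f0) / f0
    return RoiTraceSet(F=traces.F, roi_size=traces.roi_size,
                       frame_rate=traces.frame_rate, modality=traces.modality,
                       dff=dff)


def noise_sigma(dff: np.ndarray) -> float:
    """Noise standard deviation from negative dF/F values mirrored about
    zero (transients are positive-going, so the negative tail is noise)."""
    neg = dff[dff < 0]
    if neg.size == 0:
        raise ValueError("degenerate trace: no negative dF/F values to estimate noise")
    sigma = float(np.sqrt(np.mean(neg ** 2)))
    if sigma == 0:
        raise ValueError("degenerate trace: zero noise estimate")
    return sigma


def detect_transients(traces: RoiTraceSet, n_sigma: float = 3.0,
                      min_frames: int = 2) -> np.ndarray:
    """Boolean per-frame significance mask.

    A frame is significant when it belongs to an excursion of at least
    ``min_frames`` consecutive frames with dF/F above ``n_sigma`` times the
    per-ROI noise standard deviation.
    """
    if traces.dff is None:
        raise ValueError("run compute_dff first")
    mask = np.zeros_like(traces.dff, dtype=bool)
    for i in range(traces.n_rois):
        d = traces.dff[i]
        above = d > n_sigma * noise_sigma(d)
        if not above.any():
            continue
        # drop runs shorter than min_frames
        padded = np.concatenate([[False], above, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(int)))
        starts, stops = edges[0::2], edges[1::2]
        for s, e in zip(starts, stops):
            if e - s >= min_frames:
                mask[i, s:e] = True
    return mask


# ---------------------------------------------------------------------------
# axon merging
# ---------------------------------------------------------------------------

@dataclass
class AxonGrouping:
    """Partition of EC3 ROIs into putative parent axons."""

    roi_to_axon: np.ndarray      # axon label per ROI
    merge_threshold: float
    merged_traces: np.ndarray    # (n_axons, T), size-weighted mean dF/F
    axon_size: np.ndarray        # summed pixel count per axon
    frame_rate: float

    @property
    def n_axons(self) -> int:
        return self.merged_traces.shape[0]


def merge_rois_by_noise_correlation(traces: RoiTraceSet,
                                    threshold: float = 0.45,
                                    mode: str = "raw") -> AxonGrouping:
    """Group ROIs whose pairwise Pearson correlation reaches ``threshold``.

    Linked ROIs form connected components (axons); the merged trace is the
    pixel-count-weighted mean of the member dF/F traces.  ``mode`` selects
    the trace used for correlation: ``"raw"`` (full dF/F; axonal signal
    dominates) or ``"nonsignificant"`` (significant-transient frames masked
    out, a stricter reading of noise correlation).
    """
    if traces.modality != "ec3_axon":
        raise ValueError("merging applies to EC3 axonal ROI sets")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    if traces.dff is None:
        raise ValueError("run compute_dff first")
    n = traces.n_rois
    if n < 1:
        raise ValueError("no ROIs to merge")
    if mode == "raw":
        corr = np.corrcoef(traces.dff)
    elif mode == "nonsignificant":
        sig = detect_transients(traces)
        masked = np.ma.masked_array(traces.dff, mask=sig)
        corr = np.ma.corrcoef(masked).filled(0.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    corr = np.atleast_2d(corr)
    adj = csr_matrix(np.triu(corr >= threshold, k=1))
    _, labels = connected_components(adj, directed=False)
    n_axons = labels.max() + 1
    merged = np.zeros((n_axons, traces.n_frames))
    sizes = np.zeros(n_axons)
    w = traces.roi_size.astype(float)
    for a in range(n_axons):
        members = np.flatnonzero(labels == a)
        if members.size == 1:           # singleton: exactly the ROI trace
            merged[a] = traces.dff[members[0]]
        else:
            wm = w[members]
            merged[a] = wm @ traces.dff[members] / wm.sum()
        sizes[a] = w[members].sum()
    return AxonGrouping(roi_to_axon=labels, merge_threshold=threshold,
                        merged_traces=merged, axon_size=sizes,
                        frame_rate=traces.frame_rate)


# ---------------------------------------------------------------------------
# activity maps
# ---------------------------------------------------------------------------

@dataclass
class ActivityMap:
    """Per-unit, per-lap, 50-bin mean dF/F tensor, reward-aligned."""

    mean_dff: np.ndarray        # (n_units, n_laps, n_bins)
    occupancy: np.ndarray       # (n_laps, n_bins), seconds of running time
    significant: np.ndarray     # (n_units, n_laps, n_bins) bool
    valid_laps: np.ndarray      # (n_laps,) bool; False = no running frames
    reward_bin: int             # 0-based, after alignment
    rotation_shift: int         # bins rolled to align the reward
    environment: str
    n_bins: int = N_BINS
    bin_width: float = BIN_WIDTH_CM

    @property
    def n_units(self) -> int:
        return self.mean_dff.shape[0]

    @property
    def n_laps(self) -> int:
        return self.mean_dff.shape[1]

    def mean_map(self, unit=None, laps=None) -> np.ndarray:
        """Across-lap mean map (valid laps only)."""
        sel = np.flatnonzero(self.valid_laps) if laps is None \
            else np.asarray(laps)[self.valid_laps[np.asarray(laps)]]
        m = self.mean_dff[:, sel].mean(axis=1)
        return m if unit is None else m[unit]

    def occupancy_probability(self, laps=None) -> np.ndarray:
        sel = np.flatnonzero(self.valid_laps) if laps is None \
            else np.asarray(laps)[self.valid_laps[np.asarray(laps)]]
        occ = self.occupancy[sel].sum(axis=0)
        return occ / occ.sum()

    def unrotated(self) -> np.ndarray:
        """Undo the reward alignment (pure rotation)."""
        return np.roll(self.mean_dff, -self.rotation_shift, axis=2)

    def bin_centers_cm(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width


def _position_bins(behavior: BehaviorSession, n_bins: int) -> np.ndarray:
    return np.minimum((behavior.position / behavior.belt_length * n_bins).astype(int),
                      n_bins - 1)


def _alignment_shift(behavior: BehaviorSession, n_bins: int) -> tuple[int, int]:
    raw = min(int(behavior.reward_position / behavior.belt_length * n_bins),
              n_bins - 1)
    target = REWARD_BIN.get(behavior.environment, raw)
    return (target - raw) % n_bins, target


def build_activity_map(source, behavior: BehaviorSession,
                       max_lap: int | None = None,
                       significant: np.ndarray | None = None,
                       n_bins: int = N_BINS,
                       velocity_threshold: float = RUNNING_THRESHOLD_CMS) -> ActivityMap:
    """Bin dF/F into reward-aligned lap-by-bin activity maps.

    ``source`` is a RoiTraceSet with dF/F or an AxonGrouping (merged
    traces).  Only running frames contribute; empty bins are filled by
    circular interpolation before smoothing; each lap row gets a circular
    three-point boxcar.  Laps without any running frame are flagged invalid.
    """
    if isinstance(source, AxonGrouping):
        dff = source.merged_traces
        if significant is None:
            tmp = RoiTraceSet(F=np.ones_like(dff) + 1.0, roi_size=source.axon_size,
                              frame_rate=source.frame_rate, modality="ec3_axon",
                              dff=dff)
            significant = detect_transients(tmp)
    else:
        if source.dff is None:
            raise ValueError("run compute_dff first")
        dff = source.dff
        if significant is None:
            significant = detect_transients(source)
    if dff.shape[1] != behavior.n_frames:
        raise ValueError("traces and behaviour do not share the frame grid")

    n_units = dff.shape[0]
    n_laps = behavior.n_laps if max_lap is None else min(max_lap, behavior.n_laps)
    bins = _position_bins(behavior, n_bins)
    running = behavior.running_mask(velocity_threshold)
    dt = behavior.dt

    mean_dff = np.full((n_units, n_laps, n_bins), np.nan)
    occupancy = np.zeros((n_laps, n_bins))
    sig_map = np.zeros((n_units, n_laps, n_bins), dtype=bool)
    valid = np.ones(n_laps, dtype=bool)

    for lap in range(n_laps):
        sel = behavior.lap_mask(lap) & running
        if not sel.any():
            valid[lap] = False
            continue
        b = bins[sel]
        counts = np.bincount(b, minlength=n_bins)
        occupancy[lap] = counts * dt
        sums = dff[:, sel] @ np.eye(n_bins)[b]          # (units, bins)
        with np.errstate(invalid="ignore"):
            row = sums / counts
        if (counts == 0).any():
            row = np.apply_along_axis(circular_interpolate_nan, 1, row)
        mean_dff[:, lap] = circular_boxcar(row, axis=1)
        sig = significant[:, sel]
        np.logical_or.at(sig_map[:, lap].T, b, sig.T)

    shift, target = _alignment_shift(behavior, n_bins)
    return ActivityMap(mean_dff=np.roll(mean_dff, shift, axis=2),
                       occupancy=np.roll(occupancy, shift, axis=1),
                       significant=np.roll(sig_map, shift, axis=2),
                       valid_laps=valid, reward_bin=target, rotation_shift=shift,
                       environment=behavior.environment, n_bins=n_bins,
                       bin_width=behavior.belt_length / n_bins)


@dataclass
class BehaviorMaps:
    lick_rate: np.ndarray       # Hz per bin
    velocity: np.ndarray        # cm/s per bin
    occupancy: np.ndarray       # s per bin (all frames)
    reward_bin: int
    rotation_shift: int


def behavior_maps(behavior: BehaviorSession, n_bins: int = N_BINS) -> BehaviorMaps:
    """Per-bin lick rate and mean velocity on the aligned 50-bin grid."""
    if behavior.n_laps < 1:
        raise ValueError("need at least one complete lap")
    bins = _position_bins(behavior, n_bins)
    time_in_bin = np.bincount(bins, minlength=n_bins) * behavior.dt
    licks = np.bincount(bins, weights=behavior.lick.astype(float), minlength=n_bins)
    vsum = np.bincount(bins, weights=behavior.velocity, minlength=n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        lick_rate = np.where(time_in_bin > 0, licks / np.maximum(time_in_bin, 1e-12), np.nan)
        vel = np.where(counts > 0, vsum / np.maximum(counts, 1), np.nan)
    if np.isnan(lick_rate).any():
        lick_rate = circular_interpolate_nan(lick_rate)
        vel = circular_interpolate_nan(vel)
    shift, target = _alignment_shift(behavior, n_bins)
    return BehaviorMaps(lick_rate=np.roll(lick_rate, shift),
                        velocity=np.roll(vel, shift),
                        occupancy=np.roll(time_in_bin, shift),
                        reward_bin=target, rotation_shift=shift)
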