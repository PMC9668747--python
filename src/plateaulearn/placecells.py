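"""Place-cell identification and population analyses.

A CA1 neuron qualifies as a place cell when (i) it has an eventual place
field — the contiguous circular run of spatial bins above 20% of the peak
of its mean dF/F map that contains the global peak; (ii) a place-field
induction lap exists — the earliest lap X with significant activity in the
field confirmed by significant field activity in at least two of the five
following laps (if the field then vanishes for more than 20 consecutive
laps the search resumes after the gap); (iii) its spatial information,
computed over post-induction laps, exceeds the 95th percentile of 100
trace shuffles (circular shift by >= 500 frames, then six chunks permuted);
and (iv) its reliability — the fraction of post-induction laps with
significant field activity — exceeds 0.30.

Spatial information (bits) is the occupancy-weighted divergence of the
per-bin activity from its mean:

    SI = sum_i P_i * lambda_i * log2(lambda_i / lambda),
    lambda = sum_i P_i * lambda_i,

with P_i the running-frame occupancy probability of bin i and lambda_i the
smoothed mean dF/F in bin i.  Taking lambda as the occupancy-weighted mean
guarantees SI >= 0 (Jensen); bins with lambda_i = 0 contribute 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .signals import ActivityMap, BehaviorMaps
from .synth import BehaviorSession, RoiTraceSet
from .utils import circular_boxcar, circular_signed_difference, pearson

SI_PERCENTILE = 95.0
RELIABILITY_THRESHOLD = 0.30
FIELD_FRACTION_OF_PEAK = 0.20
CONFIRM_WINDOW_LAPS = 5
CONFIRM_MIN_LAPS = 2
DISAPPEARANCE_GAP_LAPS = 20
MIN_SHIFT_FRAMES = 500
N_SHUFFLE_CHUNKS = 6


@dataclass
class PlaceFieldRecord:
    unit: int
    is_place_cell: bool
    silent: bool
    induction_lap: int                  # -1 when absent
    field_bins: np.ndarray
    peak_bin: int
    peak_position: float                # cm, aligned space
    width: float                        # cm
    si: float
    si_percentile: float
    reliability: float
    induction_velocity: float
    peak_shift: float                   # cm, signed; negative = backward


# ---------------------------------------------------------------------------
# field geometry
# ---------------------------------------------------------------------------

def find_eventual_field(mean_map: np.ndarray,
                        fraction: float = FIELD_FRACTION_OF_PEAK):
    """Contiguous circular run of bins above ``fraction`` of the peak that
    contains the global peak.  Returns (field_bins, peak_bin) or (None, -1)
    for an all-non-positive map.  Peak ties break on the lowest bin index.
    """
    m = np.asarray(mean_map, dtype=float)
    n = m.size
    if not np.any(m > 0):
        return None, -1
    peak = int(np.argmax(m))
    thr = fraction * m[peak]
    above = m > thr
    if above.all():
        return np.arange(n), peak
    lo = peak
    while above[(lo - 1) % n]:
        lo -= 1
    hi = peak
    while above[(hi + 1) % n]:
        hi += 1
    return np.arange(lo, hi + 1) % n, peak


def detect_induction_lap(significant_lap_bin: np.ndarray, field_bins: np.ndarray,
                         confirm_window: int = CONFIRM_WINDOW_LAPS,
                         confirm_min: int = CONFIRM_MIN_LAPS,
                         gap_laps: int = DISAPPEARANCE_GAP_LAPS) -> int:
    """Earliest lap with significant field activity confirmed in at least
    ``confirm_min`` of the ``confirm_window`` following laps.

    If the field later disappears for more than ``gap_laps`` consecutive
    laps, the accepted induction is considered a weak false start and the
    search resumes after the gap.  Returns -1 when no lap qualifies.
    """
    sig = np.asarray(significant_lap_bin, dtype=bool)
    n_laps = sig.shape[0]
    field_active = sig[:, np.asarray(field_bins, dtype=int)].any(axis=1)
    active_laps = np.flatnonzero(field_active)
    if active_laps.size == 0:
        return -1

    def qualifies(x: int) -> bool:
        window = field_active[x + 1:min(x + 1 + confirm_window, n_laps)]
        return int(window.sum()) >= confirm_min

    start = 0
    accepted = -1
    while True:
        cands = active_laps[active_laps >= start]
        cand = next((int(x) for x in cands if qualifies(int(x))), -1)
        if cand < 0:
            return accepted
        accepted = cand
        later = active_laps[active_laps > cand]
        runs = np.diff(np.concatenate([[cand], later]))
        big = np.flatnonzero(runs > gap_laps)
        if big.size == 0:
            return accepted
        # resume after the first over-long disappearance
        start = int(np.concatenate([[cand], later])[big[0] + 1])
        if start <= accepted:            # safety against non-progress
            return accepted


# ---------------------------------------------------------------------------
# spatial information
# ---------------------------------------------------------------------------

def spatial_information(lambda_i: np.ndarray, p_i: np.ndarray,
                        weighted_mean: bool = True) -> float:
    """SI in bits; see module docstring.  Negative activity values are
    clipped to zero (dF/F noise can dip below baseline)."""
    lam = np.clip(np.asarray(lambda_i, dtype=float), 0.0, None)
    p = np.asarray(p_i, dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("occupancy probabilities must be >= 0 and sum to 1")
    mean_rate = float(np.sum(p * lam)) if weighted_mean else float(np.mean(lam))
    if mean_rate <= 0:
        return 0.0
    pos = lam > 0
    # log2(lam) - log2(mean) avoids underflow of the ratio for tiny lam
    # (the lam*log(lam) term vanishes in the limit lam -> 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p[pos] * lam[pos] * (np.log2(lam[pos]) - np.log2(mean_rate))
    return float(np.sum(terms[np.isfinite(terms)]))


def _binned_lambda(dff: np.ndarray, bin_idx: np.ndarray, counts: np.ndarray,
                   n_bins: int) -> np.ndarray:
    sums = np.bincount(bin_idx, weights=dff, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        lam = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return circular_boxcar(lam)


def si_shuffle_test(dff: np.ndarray, bin_idx: np.ndarray,
                    occupancy_p: np.ndarray, n_shuffles: int = 100,
                    seed: int = 0, n_bins: int = 50,
                    min_shift: int = MIN_SHIFT_FRAMES):
    """Shuffle-null test of spatial information for one unit.

    ``dff`` and ``bin_idx`` are the running-frame trace and its spatial bin
    per frame (post-induction laps).  Each shuffle circularly shifts the
    trace by an offset uniform in [min_shift, T - min_shift], splits it
    into six equal chunks and permutes their order (identity excluded),
    then recomputes SI against the fixed occupancy.  The unit passes when
    the observed SI exceeds the 95th percentile of the shuffle values.
    """
    dff = np.asarray(dff, dtype=float)
    T = dff.size
    if T < 2 * min_shift or T < 1500:
        raise ValueError(f"trace of {T} frames too short for a {min_shift}-frame shift")
    rng = np.random.default_rng(seed)
    counts = np.bincount(bin_idx, minlength=n_bins)
    observed = spatial_information(_binned_lambda(dff, bin_idx, counts, n_bins),
                                   occupancy_p)
    edges = np.linspace(0, T, N_SHUFFLE_CHUNKS + 1).astype(int)
    perms = [p for p in itertools.permutations(range(N_SHUFFLE_CHUNKS))
             if p != tuple(range(N_SHUFFLE_CHUNKS))]
    shuffles = np.empty(n_shuffles)
    for s in range(n_shuffles):
        shift = int(rng.integers(min_shift, T - min_shift + 1))
        rolled = np.roll(dff, shift)
        perm = perms[rng.integers(len(perms))]
        pieces = [rolled[edges[c]:edges[c + 1]] for c in perm]
        shuffled = np.concatenate(pieces)
        shuffles[s] = spatial_information(
            _binned_lambda(shuffled, bin_idx, counts, n_bins), occupancy_p)
    passes = observed > np.percentile(shuffles, SI_PERCENTILE)
    return observed, shuffles, bool(passes)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _aligned_bins(behavior: BehaviorSession, maps: ActivityMap) -> np.ndarray:
    raw = np.minimum((behavior.position / behavior.belt_length
                      * maps.n_bins).astype(int), maps.n_bins - 1)
    return (raw + maps.rotation_shift) % maps.n_bins


def classify_place_cells(maps: ActivityMap, traces: RoiTraceSet,
                         behavior: BehaviorSession, n_shuffles: int = 100,
                         seed: int = 0,
                         reliability_threshold: float = RELIABILITY_THRESHOLD) -> pd.DataFrame:
    """Run the full identification chain for every unit.

    Returns one row per non-silent unit (units without any significant
    activity are excluded as silent, but still reported with
    ``silent=True`` and ``is_place_cell=False`` so record counts match the
    unit count).
    """
    if traces.dff is None:
        raise ValueError("run compute_dff first")
    running = behavior.running_mask()
    bins_aligned = _aligned_bins(behavior, maps)
    lap_of_frame = behavior.lap_index
    n_laps = maps.n_laps
    records = []
    for u in range(maps.n_units):
        rec = dict(unit=u, is_place_cell=False, silent=False, induction_lap=-1,
                   field_bins=None, peak_bin=-1, peak_position=np.nan,
                   width=np.nan, si=np.nan, si_percentile=np.nan,
                   reliability=np.nan, induction_velocity=np.nan,
                   peak_shift=np.nan)
        if not maps.significant[u].any():
            rec["silent"] = True
            records.append(rec)
            continue
        field, _ = find_eventual_field(maps.mean_map(unit=u))
        if field is None:
            rec["silent"] = True
            records.append(rec)
            continue
        x = detect_induction_lap(maps.significant[u], field)
        rec["induction_lap"] = x
        if x < 0 or x >= n_laps - 1:
            records.append(rec)
            continue
        post = np.arange(x + 1, n_laps)
        post_valid = post[maps.valid_laps[post]]
        if post_valid.size == 0:
            records.append(rec)
            continue
        mean_post = maps.mean_dff[u, post_valid].mean(axis=0)
        field_post, peak_bin = find_eventual_field(mean_post)
        if field_post is None:
            records.append(rec)
            continue
        rec["field_bins"] = field_post
        rec["peak_bin"] = peak_bin
        rec["peak_position"] = (peak_bin + 0.5) * maps.bin_width
        rec["width"] = field_post.size * maps.bin_width
        # reliability over post-induction laps
        rec["reliability"] = float(
            maps.significant[u][post_valid][:, field_post].any(axis=1).mean())
        # SI + shuffle on the post-induction running frames
        sel = running & np.isin(lap_of_frame, post_valid)
        p_i = maps.occupancy_probability(laps=post)
        try:
            si, shuffles, passes = si_shuffle_test(
                traces.dff[u][sel], bins_aligned[sel], p_i,
                n_shuffles=n_shuffles, seed=seed + u, n_bins=maps.n_bins)
        except ValueError:
            records.append(rec)
            continue
        rec["si"] = si
        rec["si_percentile"] = float(stats.percentileofscore(shuffles, si, kind="strict"))
        rec["is_place_cell"] = bool(passes and rec["reliability"] > reliability_threshold)
        rec["induction_velocity"] = behavior.lap_mean_running_velocity(x)
        # backward shift: post-induction mean-map peak vs induction-lap peak
        ind_row = maps.mean_dff[u, x]
        if np.isfinite(ind_row).all() and np.any(ind_row > 0):
            ind_peak_cm = (int(np.argmax(ind_row)) + 0.5) * maps.bin_width
            rec["peak_shift"] = float(circular_signed_difference(
                rec["peak_position"], ind_peak_cm, behavior.belt_length))
        records.append(rec)
    return pd.DataFrame(records)


def peak_shift(record: pd.Series) -> float:
    """Signed displacement (cm) of the established field peak from the
    induction-lap activity peak; negative = backward re running direction."""
    return float(record["peak_shift"])


# ---------------------------------------------------------------------------
# population summaries
# ---------------------------------------------------------------------------

def width_velocity_relation(records: pd.DataFrame, velocity_bin_width: float = 5.0) -> dict:
    """Field width vs induction-lap running speed, averaged in 5 cm/s bins
    and fitted with a line; reports the Pearson R of the bin means."""
    pc = records[records["is_place_cell"]
                 & np.isfinite(records["induction_velocity"])
                 & np.isfinite(records["width"])]
    if len(pc) == 0:
        raise ValueError("no place cells with induction velocity")
    vbin = np.floor(pc["induction_velocity"] / velocity_bin_width).astype(int)
    grouped = pc.groupby(vbin).agg(v=("induction_velocity", "mean"),
                                   w=("width", "mean"),
                                   n=("width", "size"))
    if len(grouped) < 2:
        raise ValueError("all cells fall in one velocity bin; fit refused")
    fit = stats.linregress(grouped["v"], grouped["w"])
    return dict(slope=float(fit.slope), intercept=float(fit.intercept),
                r=float(fit.rvalue), p=float(fit.pvalue),
                bin_velocity=grouped["v"].to_numpy(),
                bin_width_mean=grouped["w"].to_numpy(),
                bin_counts=grouped["n"].to_numpy())


def population_summaries(records: pd.DataFrame, maps: ActivityMap,
                         behavior_map: BehaviorMaps,
                         density_bin_cm: float = 18.0) -> dict:
    """Density profile of field peaks (18-cm bins), cumulative appearance
    time course (per lap and per session quarter), and the correlation of
    density with the peak-normalised velocity profile."""
    pc = records[records["is_place_cell"]]
    if len(pc) == 0:
        raise ValueError("no place cells")
    n_coarse = int(round(maps.n_bins * maps.bin_width / density_bin_cm))
    coarse = np.minimum((pc["peak_position"] / density_bin_cm).astype(int), n_coarse - 1)
    density = np.bincount(coarse, minlength=n_coarse) / len(pc)

    n_laps = maps.n_laps
    ind = pc["induction_lap"].to_numpy()
    appearance = np.array([(ind <= lap).mean() for lap in range(n_laps)])
    quarters = np.array_split(np.arange(n_laps), 4)
    per_quarter = np.array([np.isin(ind, q).mean() for q in quarters])

    factor = maps.n_bins // n_coarse
    vel_coarse = behavior_map.velocity[:factor * n_coarse].reshape(n_coarse, factor).mean(axis=1)
    vel_norm = vel_coarse / vel_coarse.max()
    if np.std(density) > 0 and np.std(vel_norm) > 0:
        r, p = stats.pearsonr(density, vel_norm)
    else:
        r, p = float("nan"), float("nan")
    return dict(density=density, appearance=appearance,
                appearance_per_quarter=per_quarter,
                density_velocity_r=float(r), density_velocity_p=float(p),
                n_place_cells=int(len(pc)))


def population_vector_correlation(map_ref: ActivityMap, map_cmp: ActivityMap,
                                  units: np.ndarray | None = None) -> dict:
    """Per-spatial-bin Pearson correlation of across-unit activity vectors
    between two conditions, plus the mean over bins."""
    if map_ref.n_units != map_cmp.n_units:
        raise ValueError("maps must share a unit set")
    a = map_ref.mean_map()
    b = map_cmp.mean_map()
    if units is not None:
        a, b = a[units], b[units]
    if a.shape[0] < 3:
        raise ValueError("need at least 3 shared units")
    per_bin = np.array([pearson(a[:, i], b[:, i]) for i in range(a.shape[1])])
    return dict(per_bin=per_bin, mean=float(np.nanmean(per_bin)))


def odd_even_reliability(maps: ActivityMap, units: np.ndarray | None = None) -> dict:
    """Within-session reliability: population-vector correlation between
    odd-lap and even-lap mean maps."""
    laps = np.flatnonzero(maps.valid_laps)
    odd, even = laps[1::2], laps[0::2]
    a = maps.mean_dff[:, odd].mean(axis=1)
    b = maps.mean_dff[:, even].mean(axis=1)
    if units is not None:
        a, b = a[units], b[units]
    if a.shape[0] < 3:
        raise ValueError("need at least 3 shared units")
    per_bin = np.array([pearson(a[:, i], b[:, i]) for i in range(a.shape[1])])
    return dict(per_bin=per_bin, mean=float(np.nanmean(per_bin)))


def session_section_profiles(ec3_maps: ActivityMap, ca1_records: pd.DataFrame,
                             ca1_maps: ActivityMap, section_laps: int = 10,
                             n_sections: int | None = None,
                             zone_halfwidth_cm: float = 18.0) -> dict:
    """Session-section summaries: per consecutive ``section_laps``-lap
    section, the mean EC3 dF/F in the over-representation zone (reward
    +/- 18 cm by default), the fraction of place-cell inductions falling in
    the section, and the Pearson correlation between the summed EC3 and
    summed CA1 50-bin activity profiles."""
    n_laps = min(ec3_maps.n_laps, ca1_maps.n_laps)
    max_sections = n_laps // section_laps
    if n_sections is None:
        n_sections = max_sections
    if n_sections < 1 or n_sections > max_sections:
        raise ValueError(f"session supports at most {max_sections} sections")
    zone_lo = ec3_maps.reward_bin - int(round(zone_halfwidth_cm / ec3_maps.bin_width))
    zone = np.arange(zone_lo, ec3_maps.reward_bin
                     + int(round(zone_halfwidth_cm / ec3_maps.bin_width)) + 1) % ec3_maps.n_bins
    if zone.size == 0:
        raise ValueError("empty over-representation zone")
    pc = ca1_records[ca1_records["is_place_cell"]]
    total_inductions = max(len(pc), 1)
    zone_means, formed, corrs = [], [], []
    for s in range(n_sections):
        laps = np.arange(s * section_laps, (s + 1) * section_laps)
        laps = laps[ec3_maps.valid_laps[laps] & ca1_maps.valid_laps[laps]]
        ec3_prof = ec3_maps.mean_dff[:, laps].mean(axis=1).sum(axis=0)
        ca1_prof = ca1_maps.mean_dff[:, laps].mean(axis=1).sum(axis=0)
        zone_means.append(float(ec3_maps.mean_dff[:, laps][:, :, zone].mean()))
        formed.append(float(np.isin(pc["induction_lap"], laps).sum() / total_inductions))
        corrs.append(pearson(ec3_prof, ca1_prof))
    return dict(ec3_zone_mean=np.array(zone_means),
                formation_fraction=np.array(formed),
                ec3_ca1_correlation=np.array(corrs),
                zone_bins=zone, n_sections=n_sections)
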