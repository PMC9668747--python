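"""Synthetic treadmill behaviour and calcium-imaging traces with ground truth.

No recordings from the study are deposited, so every downstream stage is
exercised against seeded synthetic sessions that emulate the experimental
setup: a 180-cm circular belt sampled on the ~30-Hz imaging clock, CA1
somatic fluorescence with abruptly appearing place fields carrying the
behavioural-timescale-plasticity signatures (silent before an induction
lap, field width proportional to induction-lap running speed, field peak
displaced backward from the induction-lap activity peak), and EC3 axonal
ROI traces driven by the two-state Markov chains with several ROIs per
parent axon.

The generator's defaults are the study conditions (dwell time doubled in
the reward zone, licking concentrated just before reward, brief stops near
the reward for the running filter to remove); the fluorescence forward
model (50-ms rise / 300-ms decay transient kernel, lognormal amplitude
jitter sigma = 0.3, additive Gaussian noise) is a documented fixture
convention, not a claim about the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .utils import circular_distance

BELT_LENGTH_CM = 180.0
FRAME_RATE_HZ = 30.0
RUNNING_THRESHOLD_CMS = 2.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class BehaviorSession:
    """Time-indexed record of one treadmill session on the imaging clock."""

    time: np.ndarray            # s, uniform grid at frame_rate
    position: np.ndarray        # cm in [0, belt_length)
    velocity: np.ndarray        # cm/s >= 0, frame-to-frame derivative
    lick: np.ndarray            # bool per frame
    lap_index: np.ndarray       # int per frame, increments at each wrap
    reward_position: float      # cm
    frame_rate: float = FRAME_RATE_HZ
    belt_length: float = BELT_LENGTH_CM
    cue_position: float | None = None
    environment: str = "A"

    @property
    def n_frames(self) -> int:
        return self.time.size

    @property
    def n_laps(self) -> int:
        return int(self.lap_index.max()) + 1

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    def running_mask(self, threshold: float = RUNNING_THRESHOLD_CMS) -> np.ndarray:
        return self.velocity > threshold

    def lap_mask(self, lap: int) -> np.ndarray:
        return self.lap_index == lap

    def lap_mean_running_velocity(self, lap: int,
                                  threshold: float = RUNNING_THRESHOLD_CMS) -> float:
        m = self.lap_mask(lap) & self.running_mask(threshold)
        return float(self.velocity[m].mean()) if m.any() else float("nan")

    def dwell_profile(self, n_bins: int = 50, running_only: bool = False) -> np.ndarray:
        """Mean seconds per spatial bin per lap."""
        sel = self.running_mask() if running_only else np.ones(self.n_frames, bool)
        bins = np.minimum((self.position[sel] / self.belt_length * n_bins).astype(int),
                          n_bins - 1)
        return np.bincount(bins, minlength=n_bins) * self.dt / self.n_laps


@dataclass
class RoiTraceSet:
    """Raw fluorescence (and derived dF/F) per ROI."""

    F: np.ndarray                       # (n_rois, n_frames), > 0
    roi_size: np.ndarray                # pixel count per ROI
    frame_rate: float = FRAME_RATE_HZ
    modality: str = "ca1_soma"          # or "ec3_axon"
    dff: np.ndarray | None = None       # filled by signals.compute_dff

    def __post_init__(self):
        if not np.all(np.isfinite(self.F)) or np.any(self.F <= 0):
            raise ValueError("raw fluorescence must be finite and strictly positive")
        if self.dff is not None and self.dff.shape != self.F.shape:
            raise ValueError("dff and F must share a shape")

    @property
    def n_rois(self) -> int:
        return self.F.shape[0]

    @property
    def n_frames(self) -> int:
        return self.F.shape[1]


@dataclass
class GroundTruth:
    """Generator-side labels used as the oracle in parameter-recovery tests."""

    cell_class: np.ndarray                       # {"silent","place_cell","noise_only"} or "axon"
    true_induction_lap: np.ndarray               # int, -1 when absent
    true_field_center: np.ndarray                # cm, NaN when absent
    true_field_width: np.ndarray                 # cm, NaN when absent
    induction_velocity: np.ndarray               # cm/s, NaN when absent
    axon_id: np.ndarray | None = None            # per EC3 ROI
    modulation_phase: np.ndarray | None = None   # per chain, lap fraction

    def place_cell_indices(self) -> np.ndarray:
        return np.flatnonzero(self.cell_class == "place_cell")


@dataclass
class SpeedParams:
    """Running-speed profile specification.

    The default halves the speed within +/- ``slow_zone_halfwidth`` of the
    reward, which exactly doubles per-bin dwell time there relative to the
    remote track, and injects a brief stop just before the reward on a
    fraction of laps so the running filter (velocity > 2 cm/s) has frames
    to remove.
    """

    base_speed: float = 18.0            # cm/s
    slow_factor: float = 0.5            # zone speed = base * factor
    slow_zone_halfwidth: float = 18.0   # cm
    lap_jitter_sigma: float = 0.05      # lognormal sigma of per-lap speed scale
    stop_probability: float = 0.1       # fraction of laps with a stop
    stop_duration: float = 0.5          # s
    constant: bool = False              # uniform speed, no stops


@dataclass
class NoiseParams:
    dff_sigma: float = 0.1              # additive noise, dF/F units
    f0_range: tuple = (80.0, 150.0)     # baseline fluorescence, a.u.
    transient_rate_hz: float = 0.02     # spontaneous events in noise-only cells
    transient_amplitude: float = 0.8    # dF/F


@dataclass
class BtspParams:
    """Plasticity-signature parameters for generated place fields."""

    width_velocity_slope: float = 2.0   # s; field width = slope * induction speed
    backward_shift_cm: float = 5.0      # field centre sits this far behind the
                                        # induction-lap activity peak
    min_width_cm: float = 7.2           # floor (2 bins) for very slow inductions
    peak_dff: float = 1.0               # median transient amplitude


# ---------------------------------------------------------------------------
# behaviour
# ---------------------------------------------------------------------------

def generate_behavior(n_laps: int, environment: str = "A",
                      speed_params: SpeedParams | None = None,
                      seed: int = 0,
                      frame_rate: float = FRAME_RATE_HZ) -> BehaviorSession:
    """Simulate belt position, velocity, licks and lap markers.

    Environment conventions: A has the reward at 90 cm (cue-rich belt);
    B has the reward at 84 cm with a predictive visual cue 50 cm before it
    (34 cm); habituation has uniform speed and spatially uniform licking.
    """
    if n_laps < 1:
        raise ValueError("n_laps must be >= 1")
    sp = speed_params or SpeedParams()
    if sp.base_speed <= 0 or sp.slow_factor <= 0:
        raise ValueError("speed profile must be strictly positive")
    if environment == "A":
        reward, cue = 90.0, None
    elif environment == "B":
        reward, cue = 84.0, 34.0
    elif environment == "habituation":
        reward, cue = 90.0, None
        sp = SpeedParams(base_speed=sp.base_speed, slow_factor=1.0,
                         lap_jitter_sigma=sp.lap_jitter_sigma,
                         stop_probability=0.0, constant=sp.constant)
    else:
        raise ValueError(f"unknown environment {environment!r}")

    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate
    jitter = np.exp(rng.normal(0.0, sp.lap_jitter_sigma, n_laps)) \
        if sp.lap_jitter_sigma > 0 else np.ones(n_laps)
    stop_laps = (rng.random(n_laps) < sp.stop_probability) \
        if not sp.constant else np.zeros(n_laps, bool)
    stop_pos = (reward - 2.0) % BELT_LENGTH_CM

    def profile_speed(x: float) -> float:
        if sp.constant:
            return sp.base_speed
        if circular_distance(x, reward) <= sp.slow_zone_halfwidth:
            return sp.base_speed * sp.slow_factor
        return sp.base_speed

    pos, vel, laps = [], [], []
    x, lap = 0.0, 0
    stop_remaining, stopped_this_lap = 0.0, False
    while lap < n_laps:
        if stop_remaining > 0:
            v = 0.0
            stop_remaining -= dt
        else:
            v = profile_speed(x) * jitter[lap]
            if (stop_laps[lap] and not stopped_this_lap
                    and (stop_pos - x) % BELT_LENGTH_CM < v * dt):
                stop_remaining = sp.stop_duration
                stopped_this_lap = True
        pos.append(x)
        vel.append(v)
        laps.append(lap)
        x = x + v * dt
        if x >= BELT_LENGTH_CM:
            x -= BELT_LENGTH_CM
            lap += 1
            stopped_this_lap = False

    pos = np.array(pos)
    vel = np.array(vel)
    laps = np.array(laps, dtype=int)
    time = np.arange(pos.size) * dt

    if environment == "habituation":
        rate = np.full(pos.size, 0.5)
    else:
        center = (reward - 10.0) % BELT_LENGTH_CM   # licking ramps up before reward
        d = circular_distance(pos, center)
        rate = 0.2 + 8.0 * np.exp(-d ** 2 / (2.0 * 6.0 ** 2))
    lick = rng.random(pos.size) < rate * dt

    return BehaviorSession(time=time, position=pos, velocity=vel, lick=lick,
                           lap_index=laps, reward_position=reward,
                           cue_position=cue, frame_rate=frame_rate,
                           environment=environment)


# ---------------------------------------------------------------------------
# fluorescence forward model
# ---------------------------------------------------------------------------

def transient_kernel(frame_rate: float = FRAME_RATE_HZ, rise_s: float = 0.05,
                     decay_s: float = 0.3) -> np.ndarray:
    """Fast-indicator-like impulse response, normalised to unit peak."""
    t = np.arange(0, int(np.ceil(6 * decay_s * frame_rate))) / frame_rate
    k = (1.0 - np.exp(-t / rise_s)) * np.exp(-t / decay_s)
    return k / k.max()


def _kernel_lag_s(kernel: np.ndarray, frame_rate: float) -> float:
    """Temporal centre of mass of the kernel; the generator shifts activation
    earlier by this lag so the fluorescence peak lands on the ground-truth
    field centre despite the indicator's slow decay."""
    t = np.arange(kernel.size) / frame_rate
    return float(np.sum(t * kernel) / np.sum(kernel))


def _traces_from_signal(signal: np.ndarray, rng: np.random.Generator,
                        noise: NoiseParams) -> tuple[np.ndarray, np.ndarray]:
    """Wrap dimensionless activity signals into raw fluorescence."""
    n, T = signal.shape
    f0 = rng.uniform(*noise.f0_range, size=n)
    F = f0[:, None] * (1.0 + signal) \
        + rng.normal(0.0, noise.dff_sigma, size=(n, T)) * f0[:, None]
    return np.maximum(F, 1e-3), f0


# ---------------------------------------------------------------------------
# CA1 somata
# ---------------------------------------------------------------------------

def generate_ca1_traces(behavior: BehaviorSession, n_cells: int = 200,
                        frac_place: float = 0.4,
                        btsp_params: BtspParams | None = None,
                        noise_params: NoiseParams | None = None,
                        seed: int = 0) -> tuple[RoiTraceSet, GroundTruth]:
    """CA1 somatic fluorescence with known place-field ground truth.

    Cell classes: ``place_cell`` (silent until an induction lap, then a
    spatial field every traversal with lap-wise lognormal amplitude
    jitter), ``noise_only`` (spontaneous transients at random times) and
    ``silent`` (baseline noise).  Place-field width is proportional to the
    induction-lap running speed and the field centre sits a fixed distance
    behind the induction-lap activity peak (opposite the running
    direction) — the two plasticity signatures the analysis must recover.
    """
    if not (0.0 <= frac_place <= 1.0):
        raise ValueError("frac_place must lie in [0, 1]")
    if behavior.n_laps < 10:
        raise ValueError("behavior shorter than 10 laps: induction laps cannot be placed")
    bp = btsp_params or BtspParams()
    noise = noise_params or NoiseParams()
    rng = np.random.default_rng(seed)
    T = behavior.n_frames
    n_place = int(round(frac_place * n_cells))
    n_noise = (n_cells - n_place + 1) // 2
    n_silent = n_cells - n_place - n_noise
    classes = np.array(["place_cell"] * n_place + ["noise_only"] * n_noise
                       + ["silent"] * n_silent)
    rng.shuffle(classes)

    kernel = transient_kernel(behavior.frame_rate)
    lag = _kernel_lag_s(kernel, behavior.frame_rate)
    n_laps = behavior.n_laps
    last_usable = n_laps - 10    # leave room to confirm the induction

    induction = np.full(n_cells, -1, dtype=int)
    center = np.full(n_cells, np.nan)
    width = np.full(n_cells, np.nan)
    ivel = np.full(n_cells, np.nan)
    signal = np.zeros((n_cells, T))

    sigma_factor = 2.0 * np.sqrt(2.0 * np.log(5.0))   # 20%-of-peak full width

    for i in np.flatnonzero(classes == "place_cell"):
        lap0 = int(rng.integers(3, max(last_usable, 4)))
        v0 = behavior.lap_mean_running_velocity(lap0)
        w = max(bp.width_velocity_slope * v0, bp.min_width_cm)
        ind_peak = float(rng.uniform(0, behavior.belt_length))
        c = (ind_peak - bp.backward_shift_cm) % behavior.belt_length
        induction[i], center[i], width[i], ivel[i] = lap0, c, w, v0
        sig_f = w / sigma_factor
        amp = np.zeros(n_laps)
        amp[lap0:] = np.exp(rng.normal(0.0, 0.3, n_laps - lap0)) * bp.peak_dff
        lap_amp = amp[behavior.lap_index]
        # activation centred on the field, shifted earlier by the indicator lag
        # (on the induction lap the activity sits at the plateau site instead)
        cell_center = np.where(behavior.lap_index == lap0, ind_peak, c)
        eff_center = (cell_center - behavior.velocity * lag) % behavior.belt_length
        d = circular_distance(behavior.position, eff_center)
        act = lap_amp * np.exp(-d ** 2 / (2.0 * sig_f ** 2))
        signal[i] = np.convolve(act, kernel)[:T] / kernel.sum()

    for i in np.flatnonzero(classes == "noise_only"):
        n_ev = rng.poisson(noise.transient_rate_hz * T / behavior.frame_rate)
        if n_ev:
            at = rng.integers(0, T, n_ev)
            durs = np.maximum(rng.exponential(0.4, n_ev) * behavior.frame_rate, 3).astype(int)
            amps = np.exp(rng.normal(0.0, 0.3, n_ev)) * noise.transient_amplitude
            act = np.zeros(T)
            for t0, dur, a in zip(at, durs, amps):
                sl = slice(t0, min(t0 + dur, T))
                act[sl] = np.maximum(act[sl], a)
            signal[i] = np.convolve(act, kernel)[:T] / kernel.sum()

    F, _ = _traces_from_signal(signal, rng, noise)
    sizes = rng.integers(80, 200, n_cells)
    traces = RoiTraceSet(F=F, roi_size=sizes, frame_rate=behavior.frame_rate,
                         modality="ca1_soma")
    truth = GroundTruth(cell_class=classes, true_induction_lap=induction,
                        true_field_center=center, true_field_width=width,
                        induction_velocity=ivel)
    return traces, truth


# ---------------------------------------------------------------------------
# EC3 axonal ROIs
# ---------------------------------------------------------------------------

def chain_states_on_frames(population, behavior: BehaviorSession) -> np.ndarray:
    """Resample chain lap/step states onto the imaging frame grid.

    Each behaviour frame is mapped to (lap mod simulated laps, within-lap
    time fraction * steps-per-lap); this keeps the chains' within-lap phase
    structure aligned with the behaviour laps.
    """
    lv = population.lap_view
    n_chains, n_chain_laps, steps = lv.shape
    laps = behavior.lap_index
    # within-lap time fraction per frame
    frac = np.zeros(behavior.n_frames)
    for lap in range(behavior.n_laps):
        m = behavior.lap_mask(lap)
        n = int(m.sum())
        frac[m] = (np.arange(n) + 0.5) / n
    step = np.minimum((frac * steps).astype(int), steps - 1)
    return lv[:, laps % n_chain_laps, step]


def generate_ec3_rois(chains, behavior: BehaviorSession,
                      rois_per_axon=(0.5, 0.35, 0.15),
                      kernel: np.ndarray | None = None,
                      noise_params: NoiseParams | None = None,
                      seed: int = 0) -> tuple[RoiTraceSet, GroundTruth]:
    """EC3 axonal ROI fluorescence from a simulated chain population.

    Each chain is one parent axon; its binary state trace is convolved
    with the transient kernel and split into one or more ROI traces that
    share the signal but carry independent noise.  ``rois_per_axon`` is a
    fixed integer or a probability vector over counts 1..k.
    """
    if chains.states.size == 0 or chains.config.n_chains == 0:
        raise ValueError("empty chain population")
    noise = noise_params or NoiseParams(dff_sigma=0.15)
    rng = np.random.default_rng(seed)
    kernel = transient_kernel(behavior.frame_rate) if kernel is None else kernel

    from scipy.signal import fftconvolve

    states = chain_states_on_frames(chains, behavior).astype(float)
    n_axons, T = states.shape
    axon_signal = fftconvolve(states, kernel[None, :], axes=1)[:, :T] / kernel.sum()

    if np.isscalar(rois_per_axon):
        counts = np.full(n_axons, int(rois_per_axon))
    else:
        p = np.asarray(rois_per_axon, dtype=float)
        counts = rng.choice(np.arange(1, p.size + 1), size=n_axons, p=p / p.sum())
    axon_id = np.repeat(np.arange(n_axons), counts)
    signal = axon_signal[axon_id]
    F, _ = _traces_from_signal(signal, rng, noise)
    sizes = np.maximum(np.rint(np.exp(rng.normal(np.log(60), 0.5, axon_id.size))), 5).astype(int)
    traces = RoiTraceSet(F=F, roi_size=sizes, frame_rate=behavior.frame_rate,
                         modality="ec3_axon")
    n_rois = axon_id.size
    truth = GroundTruth(cell_class=np.array(["axon"] * n_rois),
                        true_induction_lap=np.full(n_rois, -1, dtype=int),
                        true_field_center=np.full(n_rois, np.nan),
                        true_field_width=np.full(n_rois, np.nan),
                        induction_velocity=np.full(n_rois, np.nan),
                        axon_id=axon_id,
                        modulation_phase=chains.config.phase_step.astype(float)
                        / chains.config.steps_per_lap)
    return traces, truth
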