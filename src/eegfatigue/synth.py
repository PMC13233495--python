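"""Seeded synthetic BCI-VR EEG sessions with planted mental-fatigue structure.

Every downstream stage of the pipeline (preprocessing, IRASA features,
N-PLS/PARAFAC modelling, LDA trajectories) is exercised on recordings from
this generator, which emulates the statistical structure the analysis
assumes:

* a 32-channel 10-20 montage recording at a desk-scale sampling rate;
* pre/post eyes-closed (EC) and eyes-open (EO) resting segments around three
  VR blocks of motor-imagery (MI) trials (20 s rest, up to 20 s imagery,
  2-7 s pause);
* a parieto-occipital alpha rhythm whose amplitude grows with time-on-task
  (the planted fatigue effect) and is stronger with eyes closed (Berger
  effect);
* a central mu rhythm near 10.75 Hz that desynchronizes during imagery and
  strengthens slightly with training (so that resting-state models can pick
  up task-related sensorimotor traces, which deflation must then remove);
* 1/f fractal background activity, blink and EMG artifacts with exact ground
  truth;
* 7-item ordinal questionnaire responses correlated with the planted fatigue.

Oscillators are band-pass-filtered Gaussian noise rather than pure sinusoids,
so spectra show realistic peaks with epoch-to-epoch amplitude variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.random import default_rng
from scipy import signal as sps

from .montage import Montage, make_montage

__all__ = [
    "SimulationConfig",
    "Oscillator",
    "ContinuousEEG",
    "Segment",
    "Trial",
    "SessionRecord",
    "ArtifactEvent",
    "QuestionnaireSeries",
    "QUESTIONNAIRE_ITEMS",
    "make_montage",
    "synth_continuous",
    "generate_session",
    "inject_artifacts",
    "generate_questionnaire",
    "stage_fatigue",
]


# --------------------------------------------------------------------------
# configuration and containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic BCI-VR session.

    Defaults follow the emulated study protocol where it states them (three
    blocks of 25 trials; 20 s rest; up to 20 s imagery; 2-7 s pauses;
    per-block sham success probabilities 0.30/0.40/0.35; mu rhythm at
    10.75 Hz).  Quantities the protocol leaves open (sampling rate, resting
    segment length, amplitudes) use documented desk-scale conventions.
    """

    sampling_rate: float = 250.0            # Hz
    n_channels: int = 32
    block_count: int = 3
    trials_per_block: int = 25
    rest_trial_s: float = 20.0              # per-trial resting phase
    mi_max_s: float = 20.0                  # imagery phase cap
    mi_success_min_s: float = 5.0           # earliest detection time on success
    pause_range_s: tuple[float, float] = (2.0, 7.0)
    pre_post_rest_s: float = 120.0          # per EO / EC resting segment
    alpha_center: float = 10.0              # Hz
    alpha_amplitude: float = 6.0            # uV RMS at the peak electrode (EO, rested)
    alpha_fatigue_gain: float = 0.3         # amplitude multiplier per unit fatigue
    mu_center: float = 10.75                # Hz
    mu_amplitude: float = 4.0               # uV RMS at C3/C4
    erd_depth: float = 0.5                  # fractional mu drop during imagery
    mu_post_gain: float = 0.25              # training-induced mu growth per unit fatigue
    ec_eo_ratio: float = 2.0                # EC/EO alpha amplitude ratio
    fractal_exponent: float = 1.3           # 1/f^beta background slope
    noise_rms: float = 10.0                 # uV RMS of the fractal background
    osc_bandwidth: float = 2.0              # Hz, oscillator band width
    recovery_fraction: float = 0.2          # fatigue drop at block breaks
    blink_rate_per_min: float = 10.0
    emg_rate_per_min: float = 4.0
    control_success_probs: tuple[float, ...] = (0.30, 0.40, 0.35)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sampling_rate", "rest_trial_s", "mi_max_s", "pre_post_rest_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pause_range_s[0] <= 0 or self.pause_range_s[1] < self.pause_range_s[0]:
            raise ValueError("pause_range_s must be a positive, ordered interval")
        if not all(0.0 <= p <= 1.0 for p in self.control_success_probs):
            raise ValueError("control_success_probs must lie in [0, 1]")
        if len(self.control_success_probs) < self.block_count:
            raise ValueError("need one control success probability per block")
        if self.ec_eo_ratio < 1.0:
            raise ValueError("ec_eo_ratio must be >= 1")
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must lie in [0, 1]")
        if self.blink_rate_per_min < 0 or self.emg_rate_per_min < 0:
            raise ValueError("artifact rates must be non-negative")


@dataclass(frozen=True)
class Oscillator:
    """A band-limited rhythm projected through a fixed spatial profile.

    ``amplitude`` is the RMS (uV) of the source at a unit profile weight;
    ``envelope``, if given, multiplies the source sample-by-sample.
    """

    center: float                 # Hz
    bandwidth: float              # Hz
    amplitude: float              # uV RMS
    profile: np.ndarray           # (n_channels,)
    envelope: np.ndarray | None = None  # (n_samples,) or None

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("oscillator amplitude must be non-negative")
        if np.asarray(self.profile).size == 0:
            raise ValueError("oscillator profile must cover at least one channel")


@dataclass
class ContinuousEEG:
    """A multichannel recording: channels x samples in microvolts."""

    signal: np.ndarray            # (n_channels, n_samples)
    rate: float                   # Hz
    channel_labels: tuple[str, ...]
    annotations: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.signal.shape[0] != len(self.channel_labels):
            raise ValueError("signal row count must equal the number of channel labels")
        end = self.signal.shape[1] / self.rate
        for onset, duration, _ in self.annotations:
            if onset < -1e-9 or onset + duration > end + 1e-6:
                raise ValueError("annotation lies outside the recording")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def copy(self) -> "ContinuousEEG":
        return ContinuousEEG(self.signal.copy(), self.rate,
                             tuple(self.channel_labels), list(self.annotations))


@dataclass(frozen=True)
class Segment:
    kind: str      # e.g. "pre-EC", "block2-rest", "block2-mi", "post-EO"
    onset: float   # s
    duration: float

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class Trial:
    block: int
    index: int
    rest_onset: float
    mi_onset: float
    mi_duration: float
    pause_duration: float
    success: bool
    erd_attained: float  # fractional mu amplitude drop actually planted


@dataclass(frozen=True)
class ArtifactEvent:
    kind: str                 # "blink" | "emg"
    onset: float              # s
    duration: float           # s
    channels: np.ndarray      # indices into the montage
    waveform: np.ndarray      # (len(channels), n_event_samples), exactly what was added


@dataclass
class SessionRecord:
    """One synthetic session with full ground truth."""

    eeg: ContinuousEEG
    segments: list[Segment]
    trials: list[Trial]
    condition: str                       # "mi" | "control"
    fatigue_truth: np.ndarray            # per-sample planted fatigue in [0, 1]
    artifact_truth: list[ArtifactEvent] = field(default_factory=list)
    montage: Montage | None = None
    config: SimulationConfig | None = None


QUESTIONNAIRE_ITEMS = (
    "nausea",
    "dizziness",
    "instability",
    "visual_fatigue",
    "visual_discomfort",
    "mental_fatigue",
    "motivation",
)


@dataclass
class QuestionnaireSeries:
    """Ordinal 1-7 responses to the 7 fatigue items across session stages."""

    timepoints: np.ndarray               # stage indices
    items: tuple[str, ...]
    responses: np.ndarray                # (n_timepoints, n_items), int in [1, 7]

    def __post_init__(self) -> None:
        if self.responses.shape != (len(self.timepoints), len(self.items)):
            raise ValueError("responses must be (n_timepoints, n_items)")
        if self.responses.min() < 1 or self.responses.max() > 7:
            raise ValueError("responses must lie in [1, 7]")

    def item(self, name: str) -> np.ndarray:
        return self.responses[:, self.items.index(name)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.responses, index=self.timepoints, columns=list(self.items))


# --------------------------------------------------------------------------
# signal synthesis
# --------------------------------------------------------------------------

def _fractal_noise(n_channels: int, n_samples: int, exponent: float,
                   rms: float, rate: float, rng) -> np.ndarray:
    """1/f^exponent background via spectral shaping of white noise.

    The shaping is flat below 1 Hz to keep the low end finite; each channel
    is independently generated and scaled to the requested RMS.
    """
    white = rng.standard_normal((n_channels, n_samples))
    if rms == 0:
        return np.zeros((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate)
    shape = np.ones_like(freqs)
    above = freqs >= 1.0
    shape[above] = freqs[above] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shape, n=n_samples, axis=-1)
    std = x.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    return x / std * rms


def _oscillator_source(n_samples: int, center: float, bandwidth: float,
                       rate: float, rng) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise source."""
    lo = max(center - bandwidth / 2.0, 0.1)
    hi = min(center + bandwidth / 2.0, 0.999 * rate / 2.0)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    src = sps.sosfiltfilt(sos, rng.standard_normal(n_samples))
    std = src.std()
    return src / std if std > 0 else src


def synth_continuous(duration: float, config: SimulationConfig,
                     oscillators: list[Oscillator], seed: int) -> ContinuousEEG:
    """Render a continuous recording: 1/f background plus oscillators.

    Deterministic given ``seed``; ``duration`` must be at least 2 s so that
    band-pass filtering and spectral shaping are well defined.
    """
    if duration < 2.0:
        raise ValueError("duration must be >= 2 s")
    montage = make_montage(config.n_channels)
    rate = config.sampling_rate
    n = int(round(duration * rate))
    rng = default_rng(seed)

    sig = _fractal_noise(config.n_channels, n, config.fractal_exponent,
                         config.noise_rms, rate, rng)
    for osc in oscillators:
        profile = np.asarray(osc.profile, dtype=float)
        if profile.shape != (config.n_channels,):
            raise ValueError("oscillator profile must have one weight per channel")
        src = _oscillator_source(n, osc.center, osc.bandwidth, rate, rng)
        src = src * osc.amplitude
        if osc.envelope is not None:
            env = np.asarray(osc.envelope, dtype=float)
            if env.shape != (n,):
                raise ValueError("oscillator envelope length must match the sample count")
            src = src * env
        sig += profile[:, None] * src[None, :]

    return ContinuousEEG(sig, rate, montage.labels)


def _gaussian_profile(montage: Montage, centers: list[tuple[float, float]],
                      sigma: float) -> np.ndarray:
    pos = montage.positions
    w = np.zeros(montage.n_channels)
    for cx, cy in centers:
        d2 = (pos[:, 0] - cx) ** 2 + (pos[:, 1] - cy) ** 2
        w += np.exp(-d2 / (2.0 * sigma**2))
    return w / w.max()


def alpha_profile(montage: Montage) -> np.ndarray:
    """Parieto-occipital spatial profile of the resting alpha rhythm."""
    return _gaussian_profile(montage, [(0.0, -0.80)], sigma=0.35)


def mu_profile(montage: Montage) -> np.ndarray:
    """Bilateral sensorimotor profile of the mu rhythm (C3/C4 foci)."""
    return _gaussian_profile(montage, [(-0.5, 0.0), (0.5, 0.0)], sigma=0.25)


# --------------------------------------------------------------------------
# session generation
# --------------------------------------------------------------------------

def _round_to_grid(d: float, rate: float) -> float:
    return round(d * rate) / rate


def _build_schedule(config: SimulationConfig, condition: str, rng):
    """Draw the segment table and trial outcomes."""
    segments: list[Segment] = []
    trials: list[Trial] = []
    rate = config.sampling_rate
    t = 0.0

    def add(kind: str, dur: float) -> Segment:
        nonlocal t
        dur = _round_to_grid(dur, rate)
        seg = Segment(kind, t, dur)
        segments.append(seg)
        t += dur
        return seg

    add("pre-EC", config.pre_post_rest_s)
    add("pre-EO", config.pre_post_rest_s)
    for b in range(1, config.block_count + 1):
        for i in range(config.trials_per_block):
            rest = add(f"block{b}-rest", config.rest_trial_s)
            if condition == "mi":
                # Imagery "success" mirrors the closed-loop design: the trial
                # succeeds when the planted mu amplitude drop is deep enough.
                attained = config.erd_depth * rng.uniform(0.3, 1.0)
                success = config.erd_depth > 0 and attained >= 0.6 * config.erd_depth
                mi_dur = (rng.uniform(config.mi_success_min_s, config.mi_max_s)
                          if success else config.mi_max_s)
            else:
                attained = 0.0
                success = rng.uniform() < config.control_success_probs[b - 1]
                mi_dur = config.mi_max_s
            mi = add(f"block{b}-mi", mi_dur)
            pause = add(f"block{b}-pause", rng.uniform(*config.pause_range_s))
            trials.append(Trial(block=b, index=i, rest_onset=rest.onset,
                                mi_onset=mi.onset, mi_duration=mi.duration,
                                pause_duration=pause.duration,
                                success=bool(success), erd_attained=float(attained)))
    add("post-EC", config.pre_post_rest_s)
    add("post-EO", config.pre_post_rest_s)
    return segments, trials


def _fatigue_truth(config: SimulationConfig, segments: list[Segment],
                   n_samples: int) -> np.ndarray:
    """Per-sample planted fatigue: linear rise over the VR phase with partial
    recovery (``recovery_fraction``) at block breaks, normalized to end at 1."""
    rate = config.sampling_rate
    vr = [s for s in segments if s.kind.startswith("block")]
    if not vr:
        return np.zeros(n_samples)
    t0, t1 = vr[0].onset, vr[-1].end
    tt = np.arange(n_samples) / rate
    ramp = np.clip((tt - t0) / (t1 - t0), 0.0, 1.0)
    level = ramp.copy()
    # recovery drops at the starts of blocks 2..B
    block_starts = [s.onset for s in vr if s.kind.endswith("-rest")
                    and not s.kind.startswith("block1")]
    first_rests = {}
    for s in vr:
        if s.kind.endswith("-rest"):
            b = s.kind.split("-")[0]
            first_rests.setdefault(b, s.onset)
    drop_total = 0.0
    for b in sorted(first_rests):
        if b == "block1":
            continue
        onset = first_rests[b]
        level_before = np.interp(onset, tt, level) - 1e-12
        drop = config.recovery_fraction * max(level_before, 0.0)
        level = np.where(tt >= onset, level - drop, level)
        drop_total += drop
    idx_end = min(int(round(t1 * rate)), n_samples) - 1
    final = level[idx_end]
    if final > 0:
        level = level / final
    level[idx_end:] = 1.0  # held constant through the post-session rests
    return np.clip(level, 0.0, None)


def generate_session(config: SimulationConfig, condition: str = "mi") -> SessionRecord:
    """Generate one full synthetic session (clean of artifacts).

    The parieto-occipital alpha amplitude scales by
    ``1 + alpha_fatigue_gain * fatigue_truth`` (times ``ec_eo_ratio`` during
    EC segments); the central mu rhythm drops by the trial's attained ERD
    depth during imagery phases (MI condition) and grows by ``mu_post_gain``
    with fatigue, emulating training-induced sensorimotor changes.
    """
    if condition not in ("mi", "control"):
        raise ValueError("condition must be 'mi' or 'control'")
    montage = make_montage(config.n_channels)
    rate = config.sampling_rate
    rng = default_rng(config.seed)

    segments, trials = _build_schedule(config, condition, rng)
    n = int(round(segments[-1].end * rate))
    fatigue = _fatigue_truth(config, segments, n)

    def mask(pred) -> np.ndarray:
        m = np.zeros(n, dtype=bool)
        for s in segments:
            if pred(s.kind):
                i0 = int(round(s.onset * rate))
                i1 = int(round(s.end * rate))
                m[i0:i1] = True
        return m

    alpha_env = 1.0 + config.alpha_fatigue_gain * fatigue
    ec = mask(lambda k: k.endswith("-EC"))
    alpha_env = np.where(ec, alpha_env * config.ec_eo_ratio, alpha_env)

    mu_env = 1.0 + config.mu_post_gain * fatigue
    if condition == "mi":
        erd = np.ones(n)
        for tr in trials:
            if tr.erd_attained > 0:
                i0 = int(round(tr.mi_onset * rate))
                i1 = int(round((tr.mi_onset + tr.mi_duration) * rate))
                erd[i0:i1] = 1.0 - tr.erd_attained
        # quarter-second raised-cosine smoothing avoids envelope clicks
        w = sps.windows.hann(max(int(0.25 * rate), 3))
        erd = np.convolve(erd, w / w.sum(), mode="same")
        mu_env = mu_env * erd

    oscillators = [
        Oscillator(config.alpha_center, config.osc_bandwidth, config.alpha_amplitude,
                   alpha_profile(montage), envelope=alpha_env),
        Oscillator(config.mu_center, config.osc_bandwidth, config.mu_amplitude,
                   mu_profile(montage), envelope=mu_env),
    ]
    eeg = synth_continuous(n / rate, config, oscillators, seed=config.seed)
    eeg.annotations = [(s.onset, s.duration, s.kind) for s in segments]

    return SessionRecord(eeg=eeg, segments=segments, trials=trials,
                         condition=condition, fatigue_truth=fatigue,
                         montage=montage, config=config)


# --------------------------------------------------------------------------
# artifacts
# --------------------------------------------------------------------------

def _blink_waveform(rate: float, amplitude: float) -> np.ndarray:
    """A 0.4 s positive EOG-like transient (Gaussian lobe)."""
    t = np.arange(int(round(0.4 * rate))) / rate
    return amplitude * np.exp(-((t - 0.2) / 0.08) ** 2)


def inject_artifacts(eeg: ContinuousEEG, config: SimulationConfig,
                     seed: int) -> tuple[ContinuousEEG, list[ArtifactEvent]]:
    """Add blink and EMG artifacts; return the artifacted copy plus ground truth.

    Blinks are low-frequency frontal-dominant transients; EMG events are
    high-frequency bursts on small random channel subsets.  Each event's
    exact added waveform is recorded, so ``clean + sum(events) == artifacted``
    holds bit-for-bit.
    """
    rng = default_rng(seed)
    montage = make_montage(eeg.n_channels)
    out = eeg.copy()
    events: list[ArtifactEvent] = []
    minutes = eeg.duration / 60.0
    rate = eeg.rate

    frontal_w = _gaussian_profile(montage, [(0.0, 0.95)], sigma=0.40)
    frontal_idx = np.where(frontal_w >= 0.05)[0]

    n_blinks = rng.poisson(config.blink_rate_per_min * minutes)
    for _ in range(n_blinks):
        dur = 0.4
        onset = rng.uniform(0.0, max(eeg.duration - dur, 0.0))
        onset = _round_to_grid(onset, rate)
        amp = max(rng.normal(150.0, 30.0), 50.0)
        lobe = _blink_waveform(rate, amp)
        i0 = int(round(onset * rate))
        wav = frontal_w[frontal_idx, None] * lobe[None, :]
        out.signal[frontal_idx, i0:i0 + wav.shape[1]] += wav
        events.append(ArtifactEvent("blink", onset, wav.shape[1] / rate,
                                    frontal_idx.copy(), wav))

    n_emg = rng.poisson(config.emg_rate_per_min * minutes)
    hi = min(100.0, 0.45 * rate)
    sos = sps.butter(4, [30.0, hi], btype="bandpass", fs=rate, output="sos")
    for _ in range(n_emg):
        dur = rng.uniform(0.2, 1.0)
        onset = rng.uniform(0.0, max(eeg.duration - dur, 0.0))
        onset = _round_to_grid(onset, rate)
        k = int(rng.integers(1, 5))
        chans = rng.choice(eeg.n_channels, size=k, replace=False)
        chans.sort()
        ns = int(round(dur * rate))
        amp = rng.uniform(15.0, 40.0)
        burst = sps.sosfiltfilt(sos, rng.standard_normal((k, ns + 100)), axis=-1)[:, 50:50 + ns]
        std = burst.std(axis=-1, keepdims=True)
        std[std == 0] = 1.0
        burst = burst / std * amp * sps.windows.hann(ns)[None, :]
        i0 = int(round(onset * rate))
        out.signal[chans, i0:i0 + ns] += burst
        events.append(ArtifactEvent("emg", onset, ns / rate, chans, burst))

    return out, events


# --------------------------------------------------------------------------
# questionnaire
# --------------------------------------------------------------------------

# item -> (baseline g0, slope on fatigue); response = clip(round(1 + 6*g + eps))
_ITEM_LINKS = {
    "nausea": (0.04, 0.05),
    "dizziness": (0.06, 0.08),
    "instability": (0.05, 0.05),
    "visual_fatigue": (0.08, 0.35),
    "visual_discomfort": (0.05, 0.30),
    "mental_fatigue": (0.08, 0.40),
    "motivation": (0.75, -0.25),
}


def generate_questionnaire(fatigue: np.ndarray, seed: int,
                           noise_sd: float = 0.6) -> QuestionnaireSeries:
    """Ordinal 1-7 responses at the given stage fatigue levels.

    Fatigue-type items use a monotone-increasing link to planted fatigue,
    motivation a decreasing one, and nausea/dizziness/instability stay near
    the scale floor; discrete noise is added before rounding and clipping.
    """
    fatigue = np.asarray(fatigue, dtype=float)
    if fatigue.ndim != 1 or fatigue.size < 2:
        raise ValueError("need fatigue levels at >= 2 timepoints")
    rng = default_rng(seed)
    n_t = fatigue.size
    resp = np.empty((n_t, len(QUESTIONNAIRE_ITEMS)), dtype=int)
    for j, item in enumerate(QUESTIONNAIRE_ITEMS):
        g0, slope = _ITEM_LINKS[item]
        g = np.clip(g0 + slope * fatigue, 0.0, 1.0)
        eps = rng.normal(0.0, noise_sd, size=n_t) if noise_sd > 0 else 0.0
        resp[:, j] = np.clip(np.round(1.0 + 6.0 * g + eps), 1, 7).astype(int)
    return QuestionnaireSeries(np.arange(n_t), QUESTIONNAIRE_ITEMS, resp)


def stage_fatigue(record: SessionRecord) -> np.ndarray:
    """Planted fatigue at the questionnaire stages: pre, end of each block, post."""
    rate = record.eeg.rate
    times = [record.segments[0].onset]
    for b in range(1, (record.config.block_count if record.config else 3) + 1):
        block_segs = [s for s in record.segments if s.kind.startswith(f"block{b}-")]
        times.append(block_segs[-1].end)
    times.append(record.segments[-1].end)
    idx = np.clip((np.array(times) * rate).astype(int),
                  0, record.fatigue_truth.size - 1)
    return record.fatigue_truth[idx]
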