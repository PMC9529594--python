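"""Synthetic cEEGrid-like session generator.

Emulates the statistical structure of around-the-ear electrophysiological
recordings during a posed facial-activity protocol, so that every downstream
stage (artifact removal, epoching, features, classification) is testable
without any recorded data:

* 1/f-shaped EEG background with a 10 Hz alpha component,
* per-activity EMG-like bursts — band-limited noise with smooth
  raised-cosine onset/offset ramps and activity-specific spatial gain
  patterns across channels,
* power-line interference (50 Hz by default) with a stationary baseline
  amplitude plus burst-like non-stationary episodes, coupled strongly into
  one designated "open" electrode (covered, recording only interference) and
  weakly into the recording channels,
* slow baseline wander below 0.5 Hz.

The default protocol poses 28 facial activities per round, two of which are
jaw clenches (the bruxism classes), across three sessions — trial order is
re-randomized per session.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import (
    DEFAULT_CHANNELS,
    EventAnnotation,
    Recording,
    ValidationError,
    validate_annotations,
)

logger = logging.getLogger(__name__)

#: 26 non-clench posed facial activities + the two jaw-clench classes
DEFAULT_ACTIVITIES: tuple[str, ...] = (
    "smile",
    "laugh",
    "frown",
    "eyebrows_raise",
    "eyebrows_furrow",
    "wink_left",
    "wink_right",
    "blink",
    "eyes_close",
    "eyes_left",
    "eyes_right",
    "nose_wrinkle",
    "sniff",
    "jaw_open",
    "jaw_left",
    "jaw_right",
    "chew",
    "swallow",
    "tongue_press",
    "lip_purse",
    "lip_smack",
    "cheek_puff",
    "whistle",
    "talk",
    "cough",
    "yawn",
    "clench_short",
    "clench_long",
)

DEFAULT_BRUXISM_LABELS: frozenset[str] = frozenset({"clench_short", "clench_long"})


def _default_durations() -> dict[str, float]:
    d = {label: 2.0 for label in DEFAULT_ACTIVITIES}
    d["clench_long"] = 4.0
    return d


@dataclass
class ProtocolConfig:
    """Posed facial-activity protocol of one study.

    Defaults emulate a 28-activity protocol with exactly two jaw-clench
    (bruxism) classes, repeated over three sessions at 250 Hz. Per-activity
    durations default to 2 s (4 s for the long clench) with 2 s rest between
    trials; ``trials_per_activity=29`` yields roughly 3,300 one-second epochs
    per session.
    """

    activity_labels: tuple[str, ...] = DEFAULT_ACTIVITIES
    bruxism_labels: frozenset[str] = DEFAULT_BRUXISM_LABELS
    trials_per_activity: int = 29
    activity_duration_s: dict[str, float] = field(default_factory=_default_durations)
    rest_duration_s: float = 2.0
    n_sessions: int = 3
    sampling_rate_hz: float = 250.0

    def __post_init__(self) -> None:
        if self.trials_per_activity > 0 and not self.activity_labels:
            raise ValidationError("empty activity list with trials_per_activity > 0")
        if self.trials_per_activity < 0:
            raise ValidationError("trials_per_activity must be >= 0")
        unknown = self.bruxism_labels - set(self.activity_labels)
        if unknown:
            raise ValidationError(f"bruxism labels not in activity list: {sorted(unknown)}")
        for label in self.activity_labels:
            if self.activity_duration_s.get(label, 0) <= 0:
                raise ValidationError(f"non-positive duration for activity {label!r}")
        if self.rest_duration_s <= 0:
            raise ValidationError("rest_duration_s must be > 0")
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling_rate_hz must be > 0")

    @property
    def n_activities(self) -> int:
        return len(self.activity_labels)

    @property
    def session_duration_s(self) -> float:
        """Total session duration: Σ over trials of (activity + rest)."""
        return self.trials_per_activity * sum(
            self.activity_duration_s[a] + self.rest_duration_s for a in self.activity_labels
        )

    def is_bruxism(self, label: str) -> bool:
        return label in self.bruxism_labels


def default_emg_gains(
    config: ProtocolConfig,
    n_channels: int = len(DEFAULT_CHANNELS),
    rng_seed: int = 0,
    bruxism_scale: float = 3.0,
) -> np.ndarray:
    """Build an (activity × channel) EMG gain matrix in µV per unit RMS.

    Each activity gets a random spatial pattern; each jaw-clench row is
    rescaled so its summed channel gain equals ``bruxism_scale`` times the
    median non-clench row sum — jaw clenching produces the largest-amplitude,
    most widespread muscle potentials around the ear, which is what makes
    the detection problem learnable. Any ``bruxism_scale`` > 1 therefore
    satisfies the learnability invariant by construction.
    """
    rng = np.random.default_rng(rng_seed)
    n_act = config.n_activities
    base = rng.uniform(3.0, 8.0, size=(n_act, n_channels))
    overall = rng.uniform(0.6, 1.4, size=(n_act, 1))
    gains = base * overall
    brux = [i for i, a in enumerate(config.activity_labels) if config.is_bruxism(a)]
    other = [i for i, a in enumerate(config.activity_labels) if not config.is_bruxism(a)]
    if brux and other:
        med_sum = float(np.median(gains[other].sum(axis=1)))
        for i in brux:
            gains[i] *= bruxism_scale * med_sum / gains[i].sum()
    return gains


@dataclass
class NoiseConfig:
    """Amplitudes (µV) and structure of the synthetic signal components."""

    eeg_background_rms: float = 5.0
    alpha_amplitude: float = 2.0
    line_freq_hz: float = 50.0
    line_baseline_amplitude: float = 2.0
    line_burst_amplitude: float = 20.0
    line_burst_schedule: tuple[tuple[float, float], ...] = ()
    open_channel_gain: float = 20.0
    baseline_wander_rms: float = 5.0
    emg_band_hz: tuple[float, float] = (20.0, 100.0)
    emg_gain_matrix: np.ndarray | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "eeg_background_rms",
            "alpha_amplitude",
            "line_baseline_amplitude",
            "line_burst_amplitude",
            "open_channel_gain",
            "baseline_wander_rms",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        lo, hi = self.emg_band_hz
        if not 0 < lo < hi:
            raise ValidationError("emg_band_hz must satisfy 0 < low < high")
        for onset, offset in self.line_burst_schedule:
            if offset <= onset:
                raise ValidationError("line burst offset must exceed onset")

    def gains_for(self, config: ProtocolConfig, n_channels: int) -> np.ndarray:
        """Resolve the gain matrix, building the default pattern if unset."""
        if self.emg_gain_matrix is None:
            g = default_emg_gains(config, n_channels, rng_seed=self.rng_seed)
        else:
            g = np.asarray(self.emg_gain_matrix, dtype=float)
        if g.shape != (config.n_activities, n_channels):
            raise ValidationError(
                f"emg_gain_matrix shape {g.shape} != "
                f"({config.n_activities}, {n_channels})"
            )
        self._check_learnability(g, config)
        return g

    @staticmethod
    def _check_learnability(gains: np.ndarray, config: ProtocolConfig) -> None:
        if not gains.any():
            return  # degenerate "no EMG" condition (e.g. background-only checks)
        brux = [i for i, a in enumerate(config.activity_labels) if config.is_bruxism(a)]
        other = [i for i, a in enumerate(config.activity_labels) if not config.is_bruxism(a)]
        if not brux or not other:
            return
        brux_sum = gains[brux].sum(axis=1)
        med_other = float(np.median(gains[other].sum(axis=1)))
        if not (brux_sum > med_other).all():
            raise ValidationError(
                "bruxism activities must have strictly larger summed channel gain "
                "than the median non-bruxism activity"
            )


def build_protocol(config: ProtocolConfig, seed: int) -> list[EventAnnotation]:
    """Lay out one session: a seeded random permutation of all trials.

    Each trial is preceded by ``rest_duration_s`` of rest, so consecutive
    activity annotations are separated by exactly one rest period and the
    total duration equals ``config.session_duration_s``.
    """
    rng = np.random.default_rng(seed)
    trials = [a for a in config.activity_labels for _ in range(config.trials_per_activity)]
    if not trials:
        return []
    order = rng.permutation(len(trials))
    annotations: list[EventAnnotation] = []
    t = 0.0
    for idx in order:
        label = trials[idx]
        onset = t + config.rest_duration_s
        offset = onset + config.activity_duration_s[label]
        annotations.append(
            EventAnnotation(
                label=label,
                is_bruxism=config.is_bruxism(label),
                onset_s=onset,
                offset_s=offset,
            )
        )
        t = offset
    return validate_annotations(annotations, config.session_duration_s)


def _one_over_f_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise with power ∝ 1/f, flat below 1 Hz."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    shaping[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shaping, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _lowpass_noise(n: int, fs: float, cutoff_hz: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise band-limited below ``cutoff_hz`` (baseline wander)."""
    white = rng.standard_normal(n)
    sos = sps.butter(2, cutoff_hz, btype="low", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _band_noise(n: int, fs: float, band: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-limited noise; the EMG surrogate."""
    lo, hi = band
    hi = min(hi, 0.999 * fs / 2)  # clip to Nyquist
    white = rng.standard_normal(n + 2 * int(fs))  # pad for filter warm-up
    sos = sps.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    x = sps.sosfilt(sos, white)[int(fs) : int(fs) + n]
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _raised_cosine_envelope(n: int, fs: float, ramp_s: float = 0.05) -> np.ndarray:
    """Unit-plateau envelope with raised-cosine on/off ramps."""
    env = np.ones(n)
    ramp = min(int(round(ramp_s * fs)), n // 2)
    if ramp > 0:
        up = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[:ramp] = up
        env[-ramp:] = up[::-1]
    return env


def synthesize_recording(
    protocol: list[EventAnnotation],
    noise: NoiseConfig,
    config: ProtocolConfig,
    seed: int,
    session_id: str = "S1",
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS,
    open_channel: str | None = "L7",
) -> Recording:
    """Render one session as a Recording; fully reproducible from ``seed``.

    The open channel (covered electrode) receives only line noise (at
    ``open_channel_gain``) and baseline wander — no physiological signal.
    """
    fs = config.sampling_rate_hz
    duration = config.session_duration_s
    protocol = validate_annotations(list(protocol), duration)
    n = int(round(duration * fs))
    if n < 1:
        raise ValidationError("session duration too short to synthesize")
    n_ch = len(channel_labels)
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs

    label_to_idx = {a: i for i, a in enumerate(config.activity_labels)}
    any_emg = any(a.label in label_to_idx for a in protocol)
    gains = noise.gains_for(config, n_ch) if any_emg else np.zeros((config.n_activities, n_ch))

    data = np.zeros((n_ch, n))
    open_idx = channel_labels.index(open_channel) if open_channel else -1

    # EEG background: 1/f noise + alpha, absent on the covered electrode
    for ch in range(n_ch):
        bg = noise.eeg_background_rms * _one_over_f_noise(n, fs, rng)
        alpha = noise.alpha_amplitude * np.sin(2 * np.pi * 10.0 * t + rng.uniform(0, 2 * np.pi))
        if ch != open_idx:
            data[ch] += bg + alpha

    # EMG bursts per annotation, spatial pattern from the gain matrix
    for ann in protocol:
        i0 = int(round(ann.onset_s * fs))
        i1 = min(int(round(ann.offset_s * fs)), n)
        if i1 > n or i0 < 0:
            raise ValidationError(f"annotation {ann.label!r} outside session bounds")
        seg = i1 - i0
        if seg <= 0:
            continue
        burst = _band_noise(seg, fs, noise.emg_band_hz, rng)
        burst *= _raised_cosine_envelope(seg, fs)
        row = gains[label_to_idx[ann.label]] if ann.label in label_to_idx else np.zeros(n_ch)
        for ch in range(n_ch):
            if ch == open_idx:
                continue
            data[ch, i0:i1] += row[ch] * burst

    # Line noise: baseline amplitude plus burst episodes, common phase
    line_env = np.full(n, noise.line_baseline_amplitude)
    for onset_s, offset_s in noise.line_burst_schedule:
        j0, j1 = int(round(onset_s * fs)), min(int(round(offset_s * fs)), n)
        if j1 > j0:
            line_env[j0:j1] += noise.line_burst_amplitude
    line = line_env * np.sin(2 * np.pi * noise.line_freq_hz * t + rng.uniform(0, 2 * np.pi))
    for ch in range(n_ch):
        gain = noise.open_channel_gain if ch == open_idx else 1.0
        data[ch] += gain * line

    # slow drift, independent per channel
    if noise.baseline_wander_rms > 0:
        for ch in range(n_ch):
            data[ch] += noise.baseline_wander_rms * _lowpass_noise(n, fs, 0.5, rng)

    return Recording(
        data=data,
        fs=fs,
        channel_labels=list(channel_labels),
        session_id=session_id,
        open_channel=open_channel,
    )


def generate_study(
    config: ProtocolConfig,
    noise: NoiseConfig,
    seeds: list[int],
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS,
    open_channel: str | None = "L7",
) -> list[tuple[Recording, list[EventAnnotation]]]:
    """Generate ``n_sessions`` independent sessions ("S1".."Sn").

    Trial order is re-randomized per session from that session's seed.
    Duplicate seeds are legal but logged, since the sessions would be
    correlated.
    """
    if len(seeds) != config.n_sessions:
        raise ValidationError(
            f"need {config.n_sessions} seeds (one per session), got {len(seeds)}"
        )
    if len(set(seeds)) < len(seeds):
        warnings.warn("duplicate session seeds: sessions will be correlated", stacklevel=2)
        logger.warning("duplicate session seeds: sessions will be correlated")
    study = []
    for i, seed in enumerate(seeds):
        session_id = f"S{i + 1}"
        protocol = build_protocol(config, seed)
        rec = synthesize_recording(
            protocol,
            noise,
            config,
            seed=seed + 1_000_003,  # decorrelate synthesis noise from trial order
            session_id=session_id,
            channel_labels=channel_labels,
            open_channel=open_channel,
        )
        study.append((rec, protocol))
    return study
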