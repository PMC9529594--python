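"""Spectral estimation and artifact handling.

Power-line interference couples into around-the-ear recordings both as a
low-amplitude stationary component and as large non-stationary bursts (e.g.
when the wearer touches mains-powered appliances). A conventional notch
filter removes the 50 Hz component but carves a "band hole" around the notch
frequency, degrading high-frequency EEG/EMG bands. The alternative here is a
normalized least-mean-squares (NLMS) adaptive filter: a covered ("open")
electrode records only the interference, and a tapped-delay-line model is
trained on-line to predict the contaminated channel from that reference; the
prediction is subtracted, removing both stationary and burst-like line noise
without a spectral hole.

NLMS update (weights w, reference regressor r(n), primary p(n)):

    ŷ(n) = wᵀ(n) · r(n)
    e(n) = p(n) − ŷ(n)
    w(n+1) = w(n) + mu · e(n) · r(n) / (‖r(n)‖² + eps)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import ValidationError


@dataclass
class NLMSConfig:
    """Adaptive reference-filter settings.

    ``window_s`` sets the tapped-delay-line length (n_taps = round(window_s ×
    fs)); default 0.25 s. ``mu`` is the normalized step size, stable for
    0 < mu ≤ 2; default 1. In ``rolling`` mode the weights are reset every
    ``rolling_window_s`` so slow drifts (baseline wander) are not learned and
    subtracted along with the line noise.
    """

    window_s: float = 0.25
    mu: float = 1.0
    eps: float = 1e-8
    mode: str = "full"
    rolling_window_s: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.mu <= 2:
            raise ValidationError("mu must satisfy 0 < mu <= 2")
        if self.window_s <= 0:
            raise ValidationError("window_s must be positive")
        if self.eps <= 0:
            raise ValidationError("eps must be positive")
        if self.mode not in ("full", "rolling"):
            raise ValidationError("mode must be 'full' or 'rolling'")
        if self.mode == "rolling" and self.rolling_window_s <= 0:
            raise ValidationError("rolling_window_s must be positive")

    def n_taps(self, fs: float) -> int:
        taps = int(round(self.window_s * fs))
        if taps < 1:
            raise ValidationError("window shorter than one sample")
        return taps


@dataclass
class FilterSpec:
    """One of the pipeline's frequency-selective filters.

    ``bandpass_iir`` — Butterworth band-pass of the given order, default the
    5–62 Hz preprocessing band. ``notch_iir`` — second-order IIR notch with
    quality factor Q = notch_hz / bandwidth. ``notch_fir`` — linear-phase FIR
    band-stop (firwin) centred on the notch frequency. Zero-phase filters are
    applied forward–backward.
    """

    kind: str = "bandpass_iir"
    band_hz: tuple[float, float] = (5.0, 62.0)
    notch_hz: float = 50.0
    order: int = 4
    taps: int = 251
    quality: float = 30.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("bandpass_iir", "notch_iir", "notch_fir"):
            raise ValidationError(f"unknown filter kind {self.kind!r}")


def apply_filter(x: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    """Filter a single-channel signal; output has the input's length.

    Zero-phase variants run the filter forward then backward, doubling the
    effective order but cancelling group delay — important here because epoch
    labels are aligned to the stimulus clock.
    """
    x = np.asarray(x, dtype=float)
    nyq = fs / 2
    if spec.kind == "bandpass_iir":
        lo, hi = spec.band_hz
        if not 0 < lo < hi < nyq:
            raise ValidationError(f"band edges {spec.band_hz} invalid for fs={fs}")
        sos = sps.butter(spec.order, [lo, hi], btype="band", fs=fs, output="sos")
        warmup = 3 * (2 * spec.order)
        if len(x) <= warmup:
            raise ValidationError(f"signal length {len(x)} <= filter warm-up {warmup}")
        return sps.sosfiltfilt(sos, x) if spec.zero_phase else sps.sosfilt(sos, x)
    if spec.kind == "notch_iir":
        if not 0 < spec.notch_hz < nyq:
            raise ValidationError(f"notch frequency {spec.notch_hz} >= Nyquist")
        b, a = sps.iirnotch(spec.notch_hz, spec.quality, fs=fs)
        warmup = 3 * max(len(a), len(b))
        if len(x) <= warmup:
            raise ValidationError(f"signal length {len(x)} <= filter warm-up {warmup}")
        return sps.filtfilt(b, a, x) if spec.zero_phase else sps.lfilter(b, a, x)
    # notch_fir: linear-phase band-stop around the notch frequency
    if not 0 < spec.notch_hz < nyq:
        raise ValidationError(f"notch frequency {spec.notch_hz} >= Nyquist")
    half_width = 1.0
    b = sps.firwin(
        spec.taps,
        [spec.notch_hz - half_width, spec.notch_hz + half_width],
        fs=fs,
        pass_zero="bandstop",
    )
    if len(x) <= 3 * spec.taps:
        raise ValidationError(f"signal length {len(x)} <= filter warm-up {3 * spec.taps}")
    if spec.zero_phase:
        return sps.filtfilt(b, [1.0], x)
    return sps.lfilter(b, [1.0], x)


def nlms_clean(
    primary: np.ndarray,
    reference: np.ndarray,
    fs: float,
    cfg: NLMSConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the reference-predicted interference from ``primary``.

    Returns ``(cleaned, estimate)`` where ``estimate`` is the adaptive
    prediction of the interference and ``cleaned = primary − estimate``.
    Weights start at zero; the first ``n_taps`` samples are passed through
    unchanged (estimate forced to 0) because the regressor window is not yet
    defined. In rolling mode, weights reset every ``rolling_window_s``.
    """
    cfg = cfg or NLMSConfig()
    p = np.asarray(primary, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.shape != r.shape or p.ndim != 1:
        raise ValidationError("primary and reference must be 1-D and equal length")
    taps = cfg.n_taps(fs)
    n = len(p)
    if n < taps:
        raise ValidationError(f"signal length {n} < n_taps {taps}")

    w = np.zeros(taps)
    estimate = np.zeros(n)
    reset_every = int(round(cfg.rolling_window_s * fs)) if cfg.mode == "rolling" else 0
    for i in range(taps, n):
        if reset_every and i % reset_every == 0:
            w[:] = 0.0
        window = r[i - taps + 1 : i + 1][::-1]  # r(n), r(n−1), … r(n−taps+1)
        y = float(w @ window)
        e = p[i] - y
        estimate[i] = y
        w += cfg.mu * e * window / (float(window @ window) + cfg.eps)
    return p - estimate, estimate


@dataclass
class PSDConfig:
    """Welch spectral-estimation settings: 1 s Hann windows, 0.5 s overlap."""

    window_s: float = 1.0
    overlap_s: float = 0.5
    window_fn: str = "hann"

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_s < self.window_s:
            raise ValidationError("need 0 <= overlap_s < window_s")


def welch_psd(
    x: np.ndarray, fs: float, cfg: PSDConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density of a single-channel signal."""
    cfg = cfg or PSDConfig()
    x = np.asarray(x, dtype=float)
    nperseg = int(round(cfg.window_s * fs))
    noverlap = int(round(cfg.overlap_s * fs))
    if len(x) < nperseg:
        raise ValidationError(f"signal length {len(x)} < one window ({nperseg} samples)")
    freqs, psd = sps.welch(
        x, fs=fs, window=cfg.window_fn, nperseg=nperseg, noverlap=noverlap
    )
    return freqs, psd


def _band_mean(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    mask = (freqs >= lo) & (freqs <= hi)
    return float(psd[mask].mean())


def _bin_power(freqs: np.ndarray, psd: np.ndarray, f0: float) -> float:
    return float(psd[int(np.argmin(np.abs(freqs - f0)))])


def compare_line_noise_removal(
    primary: np.ndarray,
    reference: np.ndarray,
    fs: float,
    line_hz: float = 50.0,
    nlms_cfg: NLMSConfig | None = None,
    psd_cfg: PSDConfig | None = None,
    exclude_s: float = 1.0,
) -> dict:
    """Contrast notch filtering against NLMS cleaning on one channel.

    Returns PSDs of the raw, FIR-notch-filtered and NLMS-cleaned primary
    channel together with scalar summaries: the line-frequency bin power of
    each and the mean PSD over line ± 5 Hz (the region where the notch digs
    its band hole). The first ``exclude_s`` seconds are dropped from the PSD
    estimates so NLMS convergence transients do not dominate.
    """
    p = np.asarray(primary, dtype=float)
    notch = apply_filter(p, fs, FilterSpec(kind="notch_fir", notch_hz=line_hz))
    cleaned, _ = nlms_clean(p, reference, fs, nlms_cfg)

    skip = int(round(exclude_s * fs))
    freqs, psd_raw = welch_psd(p[skip:], fs, psd_cfg)
    _, psd_notch = welch_psd(notch[skip:], fs, psd_cfg)
    _, psd_nlms = welch_psd(cleaned[skip:], fs, psd_cfg)

    return {
        "freqs": freqs,
        "psd_raw": psd_raw,
        "psd_notch": psd_notch,
        "psd_nlms": psd_nlms,
        "line_hz": line_hz,
        "line_bin_raw": _bin_power(freqs, psd_raw, line_hz),
        "line_bin_notch": _bin_power(freqs, psd_notch, line_hz),
        "line_bin_nlms": _bin_power(freqs, psd_nlms, line_hz),
        "band_mean_raw": _band_mean(freqs, psd_raw, line_hz - 5, line_hz + 5),
        "band_mean_notch": _band_mean(freqs, psd_notch, line_hz - 5, line_hz + 5),
        "band_mean_nlms": _band_mean(freqs, psd_nlms, line_hz - 5, line_hz + 5),
    }
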