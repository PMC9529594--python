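"""Per-channel epoch features for facial-activity detection.

Seven time-domain descriptors are computed on each mean-centered epoch
channel, chosen to capture the broadband, high-amplitude character of jaw
EMG against ongoing EEG background:

* Hjorth activity — signal variance (power),
* Hjorth mobility — sqrt(var(Δx)/var(x)), a mean-frequency proxy,
* Hjorth complexity — mobility(Δx)/mobility(x), a bandwidth proxy,
* absolute amplitude maximum and absolute amplitude sum,
* Higuchi fractal dimension — curve-length scaling across lags k=1..k_max,
* Petrosian fractal dimension — from sign changes of the first difference.

With the 16-channel ear montage this yields a 16 × 7 = 112-column feature
matrix per epoch set. All variances are population-normalized (divide by n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FEATURE_NAMES, EpochSet, FeatureMatrix, ValidationError


@dataclass
class HiguchiConfig:
    """Maximum lag of the Higuchi curve-length construction.

    k_max = 10 is a common choice for epochs of a few hundred samples; the
    construction needs len(x) > 2·k_max.
    """

    k_max: int = 10

    def __post_init__(self) -> None:
        if self.k_max < 2:
            raise ValidationError("k_max must be >= 2")


def mean_center(x: np.ndarray) -> np.ndarray:
    """Remove the mean of a single epoch channel."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValidationError("empty signal")
    return x - x.mean()


def hjorth(x: np.ndarray) -> tuple[float, float, float]:
    """Hjorth activity, mobility and complexity of a signal.

    A constant signal has zero variance; all three parameters are defined
    as 0 in that degenerate case.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValidationError("hjorth needs at least 3 samples")
    var_x = float(np.var(x))
    if var_x == 0:
        return 0.0, 0.0, 0.0
    dx = np.diff(x)
    var_dx = float(np.var(dx))
    mobility = float(np.sqrt(var_dx / var_x))
    if var_dx == 0:
        return var_x, 0.0, 0.0
    ddx = np.diff(dx)
    mobility_dx = float(np.sqrt(np.var(ddx) / var_dx))
    complexity = mobility_dx / mobility
    return var_x, mobility, complexity


def abs_amplitude(x: np.ndarray) -> tuple[float, float]:
    """Absolute amplitude maximum and absolute amplitude sum."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValidationError("empty signal")
    ax = np.abs(x)
    return float(ax.max()), float(ax.sum())


def _sign_changes(dx: np.ndarray) -> int:
    """Sign changes in a sequence, ignoring exact zeros.

    Zeros in the difference carry no direction; a change is counted between
    the nearest nonzero neighbors, which removes the measure-zero ambiguity
    of plateaus.
    """
    s = np.sign(dx)
    s = s[s != 0]
    if len(s) < 2:
        return 0
    return int(np.count_nonzero(s[1:] != s[:-1]))


def petrosian_fd(x: np.ndarray) -> float:
    """Petrosian fractal dimension.

    PFD = log10(n) / (log10(n) + log10(n / (n + 0.4·N_δ))) with N_δ the
    number of sign changes in the first difference. A strictly monotone
    signal has N_δ = 0 and PFD exactly 1.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValidationError("petrosian_fd needs at least 2 samples")
    n_delta = _sign_changes(np.diff(x))
    if n_delta == 0:
        return 1.0
    log_n = np.log10(n)
    return float(log_n / (log_n + np.log10(n / (n + 0.4 * n_delta))))


def higuchi_fd(x: np.ndarray, cfg: HiguchiConfig | None = None) -> float:
    """Higuchi fractal dimension via curve-length scaling.

    For each lag k and offset m, the normalized curve length is

        L_m(k) = (n−1) / (⌊(n−m)/k⌋ · k²) · Σ_i |x(m+ik) − x(m+(i−1)k)|

    (indices 1-based); L(k) averages over m and the FD is the slope of the
    least-squares fit of ln L(k) against ln(1/k). A constant signal has no
    curve-length scaling; its FD is defined as 1.
    """
    cfg = cfg or HiguchiConfig()
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n <= 2 * cfg.k_max:
        raise ValidationError(f"higuchi_fd needs more than {2 * cfg.k_max} samples")
    if np.ptp(x) == 0:
        return 1.0
    lengths = np.empty(cfg.k_max)
    for k in range(1, cfg.k_max + 1):
        lm = []
        for m in range(1, k + 1):
            # 0-based: samples x[m-1], x[m-1+k], x[m-1+2k], ...
            idx = np.arange(m - 1, n, k)
            if len(idx) < 2:
                continue
            n_intervals = (n - m) // k
            norm = (n - 1) / (n_intervals * k * k)
            lm.append(norm * np.abs(np.diff(x[idx])).sum())
        lengths[k - 1] = np.mean(lm)
    k_vals = np.arange(1, cfg.k_max + 1)
    # FD = slope of ln L(k) vs ln(1/k)
    slope = np.polyfit(np.log(1.0 / k_vals), np.log(lengths), 1)[0]
    return float(slope)


def channel_features(x: np.ndarray, cfg: HiguchiConfig | None = None) -> np.ndarray:
    """The 7 features of one epoch channel, in the fixed package order."""
    xc = mean_center(x)
    act, mob, comp = hjorth(xc)
    amax, asum = abs_amplitude(xc)
    return np.array([act, comp, mob, amax, asum, higuchi_fd(xc, cfg), petrosian_fd(xc)])


def feature_columns(channel_labels: list[str]) -> list[str]:
    """Column names ``<channel>_<feature>`` in channel-major order."""
    return [f"{ch}_{feat}" for ch in channel_labels for feat in FEATURE_NAMES]


def extract_features(epochs: EpochSet, cfg: HiguchiConfig | None = None) -> FeatureMatrix:
    """Per-epoch feature matrix: mean-center each channel, then 7 features.

    Column order is channel-major with the fixed feature order
    (activity, complexity, mobility, abs_max, abs_sum, higuchi_fd,
    petrosian_fd); 16 channels therefore give 112 columns.
    """
    cfg = cfg or HiguchiConfig()
    n_epochs, n_channels, _ = epochs.data.shape
    values = np.empty((n_epochs, n_channels * len(FEATURE_NAMES)))
    for e in range(n_epochs):
        for c in range(n_channels):
            values[e, c * 7 : (c + 1) * 7] = channel_features(epochs.data[e, c], cfg)
    return FeatureMatrix(
        values=values,
        column_names=feature_columns(epochs.channel_labels),
        labels=epochs.labels,
        session_id=epochs.session_id,
    )
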