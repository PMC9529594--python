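"""Shared data containers for the ear-electrode analysis pipeline.

Everything downstream of acquisition transforms one of these objects:
a :class:`Recording` (multichannel signal matrix), a list of
:class:`EventAnnotation` (posed facial activities), an :class:`EpochSet`
(non-overlapping 1-s windows with binary jaw-clench labels), a
:class:`FeatureMatrix` (per-epoch, per-channel feature table) and an
:class:`EvalReport` (confusion counts and derived metrics for a held-out
session).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_CHANNELS: tuple[str, ...] = tuple(
    f"{side}{i}" for side in ("L", "R") for i in range(1, 9)
)

#: fixed per-channel feature order used throughout the package
FEATURE_NAMES: tuple[str, ...] = (
    "activity",
    "complexity",
    "mobility",
    "abs_max",
    "abs_sum",
    "higuchi_fd",
    "petrosian_fd",
)


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


@dataclass
class Recording:
    """A multichannel electrophysiological recording in microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal matrix in µV.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        One label per row of ``data`` (default cEEGrid montage L1–L8, R1–R8).
    session_id : str
        Identifier of the recording session.
    open_channel : str or None
        Label of an electrode isolated from the skin (covered) so that it
        records only environmental interference; used as the adaptive-filter
        reference. Must name an existing channel when set.
    aux : DataFrame or None
        Auxiliary columns (sample index, accelerometer, timestamps) parsed
        from a source file but not part of the data channels.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=lambda: list(DEFAULT_CHANNELS))
    session_id: str = "S1"
    open_channel: str | None = None
    aux: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("data must be a (n_channels, n_samples) matrix")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValidationError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if not np.isfinite(self.data).all():
            raise ValidationError("recording contains non-finite samples")
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        if self.open_channel is not None and self.open_channel not in self.channel_labels:
            raise ValidationError(f"open_channel {self.open_channel!r} not in channel labels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return the 1-D signal for ``label``."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel {label!r}") from None
        return self.data[idx]


@dataclass(frozen=True)
class EventAnnotation:
    """One posed facial activity: class label, jaw-clench flag, on/offset."""

    label: str
    is_bruxism: bool
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if not (0 <= self.onset_s < self.offset_s):
            raise ValidationError(
                f"annotation {self.label!r}: need 0 <= onset < offset, "
                f"got [{self.onset_s}, {self.offset_s}]"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


def validate_annotations(
    annotations: list[EventAnnotation], duration_s: float | None = None
) -> list[EventAnnotation]:
    """Sort annotations by onset and check they do not overlap.

    Raises :class:`ValidationError` on overlap or on an annotation running
    past ``duration_s`` (when given).
    """
    out = sorted(annotations, key=lambda a: a.onset_s)
    for prev, nxt in zip(out, out[1:]):
        if nxt.onset_s < prev.offset_s:
            raise ValidationError(
                f"annotations overlap: {prev.label!r} [{prev.onset_s}, {prev.offset_s}] "
                f"and {nxt.label!r} [{nxt.onset_s}, {nxt.offset_s}]"
            )
    if duration_s is not None and out and out[-1].offset_s > duration_s + 1e-9:
        raise ValidationError(
            f"annotation {out[-1].label!r} ends at {out[-1].offset_s} s, "
            f"after the recording end ({duration_s} s)"
        )
    return out


@dataclass
class EpochSet:
    """Non-overlapping fixed-length windows with binary jaw-clench labels.

    ``data`` has shape (n_epochs, n_channels, n_samples_per_epoch); ``labels``
    is a {0,1} vector (1 = bruxism epoch); ``activity_of_epoch`` records the
    dominant activity label of each epoch, or "rest".
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    activity_of_epoch: list[str]
    channel_labels: list[str]
    session_id: str = "S1"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ValidationError("epoch data must be (n_epochs, n_channels, n_samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValidationError("one label per epoch required")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("epoch labels must be binary")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValidationError("channel label count mismatch")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class FeatureMatrix:
    """Per-epoch feature table with ``<channel>_<feature>`` column names."""

    values: np.ndarray
    column_names: list[str]
    labels: np.ndarray
    session_id: str = "S1"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.column_names):
            raise ValidationError("values must be (n_epochs, n_columns)")
        if not np.isfinite(self.values).all():
            raise ValidationError("feature matrix contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_names)
        df.insert(0, "session_id", self.session_id)
        df["label"] = np.asarray(self.labels, dtype=int)
        return df


@dataclass
class EvalReport:
    """Confusion counts plus precision/recall/F1/MCC for one evaluation."""

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    mcc: float
    prevalence: float

    def __post_init__(self) -> None:
        for name in ("precision", "recall", "f1"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if not -1 <= self.mcc <= 1:
            raise ValidationError(f"mcc={self.mcc} outside [-1, 1]")

    @property
    def n_test(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "mcc": self.mcc,
            "prevalence": self.prevalence,
        }
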