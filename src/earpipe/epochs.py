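"""Epoch extraction and jaw-clench labeling.

Annotated recordings are converted into non-overlapping 1-second windows the
way an online detector would see them: the epoch grid is anchored at sample 0
of the session (not at trial onsets), annotation on/offsets are shifted by
350 ms to compensate for the wearer's reaction time to the cue, and an epoch
counts as a bruxism (jaw-clench) event when at least half of its samples fall
inside a shifted clench annotation. This collapses the 28-class experiment
into the binary detection problem the classifier solves.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, floor

import numpy as np

from .core import EpochSet, EventAnnotation, Recording, ValidationError, validate_annotations


@dataclass
class LabelingConfig:
    """Shift, epoch length and the epoch-level labeling threshold.

    ``shift_s`` delays both the onset and the offset of every annotation
    (reaction-time compensation); ``bruxism_fraction`` is the inclusive
    minimum fraction of clench-labeled samples that makes an epoch positive.
    ``shift_applies_to`` may restrict the shift to "onset" or "offset".
    """

    shift_s: float = 0.350
    epoch_s: float = 1.0
    bruxism_fraction: float = 0.5
    shift_applies_to: str = "both"

    def __post_init__(self) -> None:
        if self.shift_s < 0:
            raise ValidationError("shift_s must be >= 0")
        if not 0 < self.bruxism_fraction <= 1:
            raise ValidationError("bruxism_fraction must be in (0, 1]")
        if self.epoch_s <= 0:
            raise ValidationError("epoch_s must be positive")
        if self.shift_applies_to not in ("both", "onset", "offset"):
            raise ValidationError("shift_applies_to must be 'both', 'onset' or 'offset'")

    def shifted(self, ann: EventAnnotation) -> tuple[float, float]:
        onset = ann.onset_s + (self.shift_s if self.shift_applies_to in ("both", "onset") else 0.0)
        offset = ann.offset_s + (
            self.shift_s if self.shift_applies_to in ("both", "offset") else 0.0
        )
        return onset, offset


def _interval_to_samples(start_s: float, end_s: float, fs: float, n: int) -> tuple[int, int]:
    """Half-open [start, end) interval → sample index range, clipped to [0, n).

    Sample i is inside iff i/fs ∈ [start_s, end_s), so the first index is
    ceil(start_s·fs) and the end index (exclusive) is ceil(end_s·fs).
    """
    i0 = max(int(ceil(start_s * fs - 1e-9)), 0)
    i1 = min(int(ceil(end_s * fs - 1e-9)), n)
    return i0, i1


def label_samples(
    recording: Recording,
    annotations: list[EventAnnotation],
    cfg: LabelingConfig | None = None,
) -> np.ndarray:
    """Per-sample binary vector: 1 inside any shifted bruxism annotation."""
    cfg = cfg or LabelingConfig()
    validate_annotations(list(annotations), recording.duration_s)
    labels = np.zeros(recording.n_samples, dtype=np.int8)
    for ann in annotations:
        if not ann.is_bruxism:
            continue
        onset, offset = cfg.shifted(ann)
        i0, i1 = _interval_to_samples(onset, offset, recording.fs, recording.n_samples)
        labels[i0:i1] = 1
    return labels


def activity_per_sample(
    recording: Recording,
    annotations: list[EventAnnotation],
    cfg: LabelingConfig | None = None,
) -> np.ndarray:
    """Per-sample activity label ('rest' outside shifted annotations)."""
    cfg = cfg or LabelingConfig()
    out = np.full(recording.n_samples, "rest", dtype=object)
    for ann in annotations:
        onset, offset = cfg.shifted(ann)
        i0, i1 = _interval_to_samples(onset, offset, recording.fs, recording.n_samples)
        out[i0:i1] = ann.label
    return out


def make_epochs(
    recording: Recording,
    sample_labels: np.ndarray,
    annotations: list[EventAnnotation],
    cfg: LabelingConfig | None = None,
) -> EpochSet:
    """Tile the session into non-overlapping epochs and label each one.

    Epochs are tiled from sample 0; a trailing partial epoch is discarded.
    An epoch is positive when the fraction of clench-labeled samples is at
    least ``bruxism_fraction`` (inclusive: exactly 50% counts).
    """
    cfg = cfg or LabelingConfig()
    sample_labels = np.asarray(sample_labels)
    if len(sample_labels) != recording.n_samples:
        raise ValidationError("sample_labels length must match the recording")
    epoch_len = int(round(cfg.epoch_s * recording.fs))
    n_epochs = recording.n_samples // epoch_len
    if n_epochs < 1:
        raise ValidationError(
            f"recording ({recording.n_samples} samples) shorter than one epoch ({epoch_len})"
        )
    used = n_epochs * epoch_len
    data = recording.data[:, :used].reshape(recording.n_channels, n_epochs, epoch_len)
    data = np.transpose(data, (1, 0, 2))

    frac = sample_labels[:used].reshape(n_epochs, epoch_len).mean(axis=1)
    labels = (frac >= cfg.bruxism_fraction - 1e-12).astype(int)

    acts = activity_per_sample(recording, annotations, cfg)[:used].reshape(n_epochs, epoch_len)
    activity_of_epoch = []
    for row in acts:
        values, counts = np.unique(row.astype(str), return_counts=True)
        activity_of_epoch.append(str(values[np.argmax(counts)]))

    return EpochSet(
        data=data,
        labels=labels,
        fs=recording.fs,
        activity_of_epoch=activity_of_epoch,
        channel_labels=list(recording.channel_labels),
        session_id=recording.session_id,
    )
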