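"""Reading and writing recordings and annotation tables.

Two on-disk dialects are supported so that real OpenBCI GUI exports and
synthetic sessions flow through one code path:

* ``openbci_gui_txt`` — the OpenBCI GUI text export: ``%``-prefixed comment
  header lines, comma-separated values, first column a sample index counting
  modulo 256, then the data channels, then any auxiliary columns
  (accelerometer, timestamps). Values are taken as µV with no rescaling.
* ``plain_csv`` — a simple header row of channel labels followed by one row
  per sample; the format the package writes by default.

Annotations travel as CSV with the header ``label,is_bruxism,onset_s,offset_s``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DEFAULT_CHANNELS, EventAnnotation, Recording, ValidationError, validate_annotations

ANNOTATION_HEADER = ["label", "is_bruxism", "onset_s", "offset_s"]


class FormatError(ValueError):
    """A file does not match the declared dialect."""


@dataclass
class RecordingFileSpec:
    """Expected dialect, channel count and sampling rate of a recording file."""

    dialect: str = "plain_csv"
    expected_channels: int = len(DEFAULT_CHANNELS)
    fs_hz: float = 250.0
    channel_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.dialect not in ("openbci_gui_txt", "plain_csv"):
            raise ValidationError(f"unknown dialect {self.dialect!r}")
        if self.expected_channels <= 0:
            raise ValidationError("expected_channels must be > 0")
        if self.fs_hz <= 0:
            raise ValidationError("fs_hz must be > 0")

    def labels(self) -> list[str]:
        if self.channel_labels is not None:
            if len(self.channel_labels) != self.expected_channels:
                raise ValidationError("channel_labels length != expected_channels")
            return list(self.channel_labels)
        if self.expected_channels == len(DEFAULT_CHANNELS):
            return list(DEFAULT_CHANNELS)
        return [f"CH{i + 1}" for i in range(self.expected_channels)]


def _parse_numeric_rows(lines: list[tuple[int, str]], path: Path) -> np.ndarray:
    rows = []
    width = None
    for lineno, line in lines:
        cells = [c.strip() for c in line.split(",")]
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise FormatError(
                f"{path}:{lineno}: expected {width} columns, found {len(cells)}"
            )
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    return np.asarray(rows, dtype=float)


def read_recording(path: str | Path, spec: RecordingFileSpec) -> Recording:
    """Read one recording file into a :class:`Recording`.

    For ``openbci_gui_txt``, comment lines starting with ``%`` are skipped,
    the leading sample-index column and any trailing auxiliary columns are
    parsed but stored in ``Recording.aux`` rather than among the data
    channels. A wrong data-channel count raises :class:`FormatError` naming
    the expected and found widths.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = path.read_text().splitlines()

    if spec.dialect == "plain_csv":
        if not raw:
            raise FormatError(f"{path}: empty file")
        header = [c.strip() for c in raw[0].split(",")]
        if len(header) != spec.expected_channels:
            raise FormatError(
                f"{path}: expected {spec.expected_channels} channel columns, "
                f"found {len(header)}"
            )
        body = [(i + 2, ln) for i, ln in enumerate(raw[1:]) if ln.strip()]
        matrix = _parse_numeric_rows(body, path)
        data = matrix.T if matrix.size else np.zeros((spec.expected_channels, 0))
        return Recording(
            data=data, fs=spec.fs_hz, channel_labels=header, session_id=path.stem
        )

    # openbci_gui_txt
    body = [
        (i + 1, ln)
        for i, ln in enumerate(raw)
        if ln.strip() and not ln.lstrip().startswith("%")
    ]
    if not body:
        raise FormatError(f"{path}: no data rows")
    matrix = _parse_numeric_rows(body, path)
    n_cols = matrix.shape[1]
    if n_cols < spec.expected_channels + 1:
        raise FormatError(
            f"{path}: expected at least {spec.expected_channels + 1} columns "
            f"(sample index + channels), found {n_cols}"
        )
    labels = spec.labels()
    data = matrix[:, 1 : 1 + spec.expected_channels].T
    aux_cols = {"sample_index": matrix[:, 0]}
    for j in range(1 + spec.expected_channels, n_cols):
        aux_cols[f"aux{j - spec.expected_channels}"] = matrix[:, j]
    return Recording(
        data=data,
        fs=spec.fs_hz,
        channel_labels=labels,
        session_id=path.stem,
        aux=pd.DataFrame(aux_cols),
    )


def write_recording(recording: Recording, path: str | Path, spec: RecordingFileSpec) -> None:
    """Write a recording in the given dialect (inverse of :func:`read_recording`)."""
    path = Path(path)
    if recording.n_channels != spec.expected_channels:
        raise FormatError(
            f"recording has {recording.n_channels} channels, "
            f"spec expects {spec.expected_channels}"
        )
    if spec.dialect == "plain_csv":
        with path.open("w", newline="") as fh:
            fh.write(",".join(recording.channel_labels) + "\n")
            np.savetxt(fh, recording.data.T, delimiter=",", fmt="%.6f")
        return
    with path.open("w", newline="") as fh:
        fh.write("%OpenBCI-style export\n")
        fh.write(f"%Sample Rate = {spec.fs_hz} Hz\n")
        fh.write("%Columns: sample_index," + ",".join(recording.channel_labels) + "\n")
        idx = np.arange(recording.n_samples) % 256
        block = np.column_stack([idx, recording.data.T])
        np.savetxt(fh, block, delimiter=",", fmt="%.6f")


def read_annotations(path: str | Path) -> list[EventAnnotation]:
    """Read and validate an annotation CSV (sorted, non-overlapping)."""
    path = Path(path)
    annotations: list[EventAnnotation] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != ANNOTATION_HEADER:
            raise FormatError(
                f"{path}: expected header {','.join(ANNOTATION_HEADER)}, "
                f"found {reader.fieldnames}"
            )
        for row in reader:
            annotations.append(
                EventAnnotation(
                    label=row["label"],
                    is_bruxism=row["is_bruxism"].strip().lower() in ("true", "1", "yes"),
                    onset_s=float(row["onset_s"]),
                    offset_s=float(row["offset_s"]),
                )
            )
    return validate_annotations(annotations)


def write_annotations(annotations: list[EventAnnotation], path: str | Path) -> None:
    """Write annotations as CSV with the standard header."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ANNOTATION_HEADER)
        for ann in annotations:
            writer.writerow([ann.label, ann.is_bruxism, f"{ann.onset_s:.6f}", f"{ann.offset_s:.6f}"])
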