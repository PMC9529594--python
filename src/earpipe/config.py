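"""YAML/JSON configuration loading.

A study config file mirrors the dataclass field names, e.g.::

    protocol:
      trials_per_activity: 4
      rest_duration_s: 2.0
      n_sessions: 3
      sampling_rate_hz: 250
    noise:
      eeg_background_rms: 5.0
      line_baseline_amplitude: 2.0
      line_burst_schedule: [[10.0, 15.0]]
    labeling:
      shift_s: 0.35
    smote:
      k_neighbors: 5
    model:
      n_estimators: 100

Unknown keys raise a config error rather than being silently ignored.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .core import ValidationError
from .epochs import LabelingConfig
from .features import HiguchiConfig
from .model import ModelConfig, SmoteConfig
from .synthdata import NoiseConfig, ProtocolConfig


class ConfigError(ValueError):
    """The configuration file is malformed or violates an invariant."""


_SECTIONS = {
    "protocol": ProtocolConfig,
    "noise": NoiseConfig,
    "labeling": LabelingConfig,
    "higuchi": HiguchiConfig,
    "smote": SmoteConfig,
    "model": ModelConfig,
}


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{cls.__name__}: unknown keys {sorted(unknown)}")
    coerced = dict(data)
    # YAML produces lists where the dataclasses expect tuples/frozensets
    for f in dataclasses.fields(cls):
        if f.name in coerced and isinstance(coerced[f.name], list):
            if f.name in ("activity_labels", "emg_band_hz", "channel_labels"):
                coerced[f.name] = tuple(coerced[f.name])
            elif f.name == "bruxism_labels":
                coerced[f.name] = frozenset(coerced[f.name])
            elif f.name == "line_burst_schedule":
                coerced[f.name] = tuple(tuple(b) for b in coerced[f.name])
    try:
        return cls(**coerced)
    except (TypeError, ValidationError) as exc:
        raise ConfigError(f"{cls.__name__}: {exc}") from exc


def load_study_config(path: str | Path) -> dict:
    """Parse a study config file into a dict of config objects.

    Returns a mapping with keys from {protocol, noise, labeling, higuchi,
    smote, model}; sections absent from the file get default-constructed
    objects.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: cannot parse ({exc})") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"{path}: unknown sections {sorted(unknown)}")
    return {name: _build(cls, raw.get(name, {}) or {}) for name, cls in _SECTIONS.items()}
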