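"""Readers and writers for recordings, traces and pipeline configs.

A recording is stored as a CSV (one row per sample, columns
``t,<20 channel names>,activity,label``) plus a JSON sidecar
``<name>.meta.json`` carrying the sampling rate, seed and simulation config.
Signals are written with 9 significant digits, enough to round-trip every
float32 value exactly, so write-then-read is lossless at single precision.
All sample indexing is 0-based and episode intervals are half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import CHANNEL_NAMES, GaitRecording, SimConfig

__all__ = [
    "write_recording",
    "read_recording",
    "PipelineConfig",
    "sidecar_path",
]

_FLOAT_FMT = "%.9g"  # round-trips float32 exactly
_ACTIVITIES = {"walk", "stand", "turn", "fog"}


def sidecar_path(path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".meta.json")


def write_recording(recording: GaitRecording, path, config: SimConfig | None = None) -> None:
    """Write a recording CSV and its JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(recording.signals, columns=list(recording.channel_names))
    df.insert(0, "t", np.arange(recording.n_samples))
    df["activity"] = recording.activity
    df["label"] = recording.labels
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta = {
        "sampling_rate_hz": recording.sampling_rate_hz,
        "channel_names": list(recording.channel_names),
        "n_samples": recording.n_samples,
    }
    if config is not None:
        meta["seed"] = config.seed
        meta["sim_config"] = config.to_dict()
    sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_recording(path) -> GaitRecording:
    """Read a recording CSV (+ sidecar) back, validating the schema."""
    path = Path(path)
    df = pd.read_csv(path)
    expected = ["t", *CHANNEL_NAMES, "activity", "label"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"recording CSV is missing column(s): {missing}")
    labels = df["label"].to_numpy()
    if not np.isin(labels, (0, 1)).all():
        bad = sorted(set(labels) - {0, 1})
        raise ValueError(f"label column must be binary; found values {bad}")
    activity = df["activity"].to_numpy()
    unknown = sorted(set(activity) - _ACTIVITIES)
    if unknown:
        raise ValueError(f"unknown activity value(s): {unknown}")
    signals = df[list(CHANNEL_NAMES)].to_numpy(dtype=np.float64)
    if not np.isfinite(signals).all():
        raise ValueError("recording contains non-finite signal values")

    meta_file = sidecar_path(path)
    if not meta_file.exists():
        raise ValueError(f"missing sidecar metadata file {meta_file}")
    meta = json.loads(meta_file.read_text())
    return GaitRecording(
        signals=signals.astype(np.float32),
        labels=labels.astype(np.uint8),
        activity=activity,
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
    )


@dataclass
class PipelineConfig:
    """End-to-end run configuration (simulation, model, training, detector)."""

    sim: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    detector: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        # cross-field consistency: ps and fs must agree wherever stated
        ps_model = self.model.get("ps")
        fs_sim = self.sim.get("sampling_rate_hz")
        fs_det = self.detector.get("sampling_rate_hz")
        if fs_sim is not None and fs_det is not None and fs_sim != fs_det:
            raise ValueError(
                f"sampling_rate_hz mismatch: sim={fs_sim} vs detector={fs_det}"
            )
        if ps_model is not None and ps_model < 0:
            raise ValueError("model.ps must be non-negative")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)
        return cls(**(data or {}))

    def to_file(self, path) -> None:
        path = Path(path)
        data = {
            "sim": self.sim,
            "model": self.model,
            "detector": self.detector,
            "paths": self.paths,
            "log_level": self.log_level,
        }
        if path.suffix in {".yml", ".yaml"}:
            path.write_text(yaml.safe_dump(data, sort_keys=False))
        else:
            path.write_text(json.dumps(data, indent=1))
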