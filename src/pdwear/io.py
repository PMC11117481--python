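"""Plain-text readers/writers and the run configuration.

Recordings travel as CSV with header ``time_s,ax_g,ay_g,az_g,label`` (one
row per sample; the label column is omitted for unlabeled field data),
with an events sidecar ``state,start_s,end_s`` and a one-row-per-subject
covariates CSV.  The configuration is a YAML-serializable dataclass whose
defaults are the device's printed constants; any override is echoed to the
log and carried into output metadata.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import STATE_NAMES, LabeledRecording

log = logging.getLogger("pdwear")


@dataclass
class RunConfig:
    sampling_rate: float = 50.0
    frame_s: float = 3.2
    overlap: float = 0.5
    dys_window_s: float = 600.0
    fog_minute_s: float = 60.0
    dys_min_duration_s: float = 6.0
    min_bout_frames: int = 3
    min_steps_per_minute: int = 8
    gate_fog: bool = True
    train_seed: int = 12345
    train_duration_s: float = 3600.0
    n_train_subjects: int = 6

    def non_default(self) -> dict:
        ref = RunConfig()
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)
                if getattr(self, f.name) != getattr(ref, f.name)}

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        overrides = cfg.non_default()
        if overrides:
            log.info("non-default config overrides: %s", overrides)
        return cfg


def write_recording(recording: LabeledRecording, path) -> None:
    """Write one recording as a per-sample CSV."""
    df = pd.DataFrame({
        "time_s": recording.time,
        "ax_g": recording.accel[:, 0],
        "ay_g": recording.accel[:, 1],
        "az_g": recording.accel[:, 2],
    })
    if recording.labels is not None:
        df["label"] = [STATE_NAMES[int(k)] for k in recording.labels]
    df.to_csv(path, index=False)


def read_recording(path, subject_id: str | None = None,
                   expected_fs: float | None = None) -> LabeledRecording:
    """Read a recording CSV; lossless round trip with write_recording."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"time_s", "ax_g", "ay_g", "az_g"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: fewer than 2 samples")
    dt = np.diff(t)
    bad = np.flatnonzero(dt <= 0)
    if len(bad):
        raise ValueError(f"{path}: non-monotonic time at line {bad[0] + 2}")
    fs = 1.0 / np.median(dt)
    if np.abs(dt - np.median(dt)).max() > 0.25 * np.median(dt):
        raise ValueError(f"{path}: irregular sampling interval")
    if expected_fs is not None and abs(fs - expected_fs) > 0.01 * expected_fs:
        raise ValueError(f"{path}: sampling rate {fs:.2f} Hz != expected {expected_fs}")
    accel = df[["ax_g", "ay_g", "az_g"]].to_numpy(dtype=float)
    labels = None
    if "label" in df.columns:
        try:
            labels = np.array([STATE_NAMES.index(s) for s in df["label"]],
                              dtype=np.int8)
        except ValueError as exc:
            raise ValueError(f"{path}: unknown label value ({exc})") from None
    return LabeledRecording(subject_id=subject_id or path.stem, accel=accel,
                            sampling_rate=float(round(fs, 6)), labels=labels)


def write_events(events: list[tuple[str, float, float]], path) -> None:
    pd.DataFrame(events, columns=["state", "start_s", "end_s"]).to_csv(
        path, index=False)


def read_events(path) -> list[tuple[str, float, float]]:
    df = pd.read_csv(path)
    return [(str(r.state), float(r.start_s), float(r.end_s))
            for r in df.itertuples()]


def write_covariates(covariates: pd.DataFrame, path) -> None:
    covariates.to_csv(path, index=False)


def read_covariates(path) -> pd.DataFrame:
    return pd.read_csv(path)
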