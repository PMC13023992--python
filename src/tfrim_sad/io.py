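"""File formats: recording CSV, manifest CSV, TFRIM HDF5 container, YAML
configuration, and run manifests.  Field layouts are documented in
docs/formats.md."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .labels import LabelConfig
from .simulate import BreathingPattern, ExcitationSpec, IOSRecording, SubjectRecord
from .tfrim import TFRIMConfig, TFRIMTensor
from .train_eval import TrainConfig

__all__ = [
    "read_recording", "write_recording", "read_manifest", "write_manifest",
    "write_tfrim_h5", "read_tfrim_h5", "PipelineConfig", "load_config",
    "dump_config", "write_run_manifest",
]

MANIFEST_COLUMNS = [
    "subject_id", "age_years", "sex", "height_cm", "weight_kg",
    "fef2575_ratio", "fef50_ratio", "fef75_ratio", "recording_path",
]


# --------------------------------------------------------------------------
# recordings

def write_recording(rec: IOSRecording, path: str | Path) -> None:
    """Two-column CSV (pressure_kpa, flow_lps) with '#'-prefixed metadata
    header; samples stored at float32 precision."""
    path = Path(path)
    header = (f"# fs_hz={rec.fs:g}\n# subject_id={rec.subject_id}\n"
              "pressure_kpa,flow_lps\n")
    body = np.stack([rec.pressure, rec.flow], axis=1).astype(np.float32)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, delimiter=",", fmt="%.8g")


def read_recording(path: str | Path) -> IOSRecording:
    path = Path(path)
    fs = None
    subject_id = ""
    n_meta = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_meta += 1
            key, _, value = line[1:].strip().partition("=")
            if key.strip() == "fs_hz":
                fs = float(value)
            elif key.strip() == "subject_id":
                subject_id = value.strip()
    if fs is None:
        raise ValueError(f"{path}: missing '# fs_hz=' metadata header")
    df = pd.read_csv(path, skiprows=n_meta)
    expected = ["pressure_kpa", "flow_lps"]
    if list(df.columns) != expected:
        raise ValueError(
            f"{path}: expected columns {expected}, got {list(df.columns)}")
    arr = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{path}: non-finite samples in recording")
    return IOSRecording(pressure=arr[:, 0], flow=arr[:, 1], fs=fs,
                        subject_id=subject_id)


# --------------------------------------------------------------------------
# manifest

def write_manifest(records: list[SubjectRecord], path: str | Path) -> None:
    rows = [{
        "subject_id": r.subject_id, "age_years": r.age, "sex": r.sex,
        "height_cm": r.height, "weight_kg": r.weight,
        "fef2575_ratio": r.v1, "fef50_ratio": r.v2, "fef75_ratio": r.v3,
        "recording_path": r.recording_path,
    } for r in records]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def _parse_sex(value, line: int) -> int:
    text = str(value).strip().upper()
    if text in ("1", "M", "MALE"):
        return 1
    if text in ("0", "F", "FEMALE"):
        return 0
    raise ValueError(f"manifest line {line}: sex must be M/F or 1/0, got {value!r}")


def read_manifest(path: str | Path) -> list[SubjectRecord]:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing manifest columns {missing}")
    records: list[SubjectRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        sid = str(row["subject_id"])
        if sid in seen:
            raise ValueError(
                f"manifest line {line}: duplicate subject_id {sid!r}; "
                "only one record per subject is allowed")
        seen.add(sid)
        v = [float(row["fef2575_ratio"]), float(row["fef50_ratio"]),
             float(row["fef75_ratio"])]
        if min(v) <= 0:
            raise ValueError(f"manifest line {line}: non-positive spirometry ratio")
        try:
            records.append(SubjectRecord(
                subject_id=sid, age=float(row["age_years"]),
                sex=_parse_sex(row["sex"], line), height=float(row["height_cm"]),
                weight=float(row["weight_kg"]), v1=v[0], v2=v[1], v3=v[2],
                recording_path=str(row["recording_path"])))
        except ValueError as exc:
            raise ValueError(f"manifest line {line}: {exc}") from exc
    return records


# --------------------------------------------------------------------------
# TFRIM HDF5 container

def write_tfrim_h5(tensors: list[TFRIMTensor], path: str | Path,
                   config: TFRIMConfig = TFRIMConfig(), fs: float = 400.0) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("tfrim", data=np.stack([t.values for t in tensors])
                          .astype(np.float32))
        fh.create_dataset("freqs_hz", data=np.stack([t.freqs for t in tensors]))
        fh.create_dataset("times_s", data=tensors[0].times)
        fh.create_dataset("mean_coherence",
                          data=np.stack([t.mean_coherence for t in tensors]))
        fh.create_dataset("subject_ids",
                          data=np.array([t.subject_id for t in tensors], dtype="S"))
        fh.attrs.update({"fs_hz": fs, "gamma_th": config.gamma_th,
                         "window_s": config.window_s, "hop_s": config.hop_s})


def read_tfrim_h5(path: str | Path) -> dict:
    with h5py.File(path, "r") as fh:
        return {
            "tfrim": fh["tfrim"][:].astype(float),
            "freqs_hz": fh["freqs_hz"][:],
            "times_s": fh["times_s"][:],
            "mean_coherence": fh["mean_coherence"][:],
            "subject_ids": [s.decode() for s in fh["subject_ids"][:]],
            "attrs": dict(fh.attrs),
        }


# --------------------------------------------------------------------------
# configuration

@dataclass
class PipelineConfig:
    """Nested configuration; every default matches the published pipeline
    constant where one exists."""

    fs_hz: float = 400.0
    duration_s: float = 30.0
    sad_fraction: float = 0.423
    breathing: BreathingPattern = BreathingPattern()
    excitation_harmonics: int = 24
    tfrim: TFRIMConfig = TFRIMConfig()
    labels: LabelConfig = LabelConfig()
    training: TrainConfig = TrainConfig()
    folds: int = 5

    def validate(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if not (0 < self.sad_fraction < 1):
            raise ValueError("sad_fraction must lie in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        # nested dataclasses validate themselves in __post_init__


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig(
        fs_hz=raw.get("fs_hz", 400.0),
        duration_s=raw.get("duration_s", 30.0),
        sad_fraction=raw.get("sad_fraction", 0.423),
        breathing=BreathingPattern(**raw.get("breathing", {})),
        excitation_harmonics=raw.get("excitation_harmonics", 24),
        tfrim=TFRIMConfig(**raw.get("tfrim", {})),
        labels=LabelConfig(**raw.get("labels", {})),
        training=TrainConfig(**raw.get("training", {})),
        folds=raw.get("folds", 5),
    )
    cfg.validate()
    return cfg


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    payload = {
        "fs_hz": cfg.fs_hz, "duration_s": cfg.duration_s,
        "sad_fraction": cfg.sad_fraction,
        "breathing": asdict(cfg.breathing),
        "excitation_harmonics": cfg.excitation_harmonics,
        "tfrim": asdict(cfg.tfrim), "labels": asdict(cfg.labels),
        "training": asdict(cfg.training), "folds": cfg.folds,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps({
        "fs_hz": cfg.fs_hz, "duration_s": cfg.duration_s,
        "sad_fraction": cfg.sad_fraction, "breathing": asdict(cfg.breathing),
        "excitation_harmonics": cfg.excitation_harmonics,
        "tfrim": asdict(cfg.tfrim), "labels": asdict(cfg.labels),
        "training": asdict(cfg.training), "folds": cfg.folds,
    }, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_run_manifest(path: str | Path, cfg: PipelineConfig, seed: int,
                       stage: str, inputs: dict | None = None) -> None:
    from . import __version__

    payload = {"stage": stage, "seed": seed, "config_hash": config_hash(cfg),
               "package_version": __version__, "inputs": inputs or {}}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
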