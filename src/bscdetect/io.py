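"""Session CSV format, cohort manifests and run configuration.

Session files are plain CSV with header ``time_s,<channel>...,state,phase``,
one row per second; states are AC/AG/AP/RE and phase is
baseline/stimulation.  A native 5 Hz skin-conductance trace travels in a
``<stem>.gsr5hz.csv`` sidecar and is routed through the block-mean
down-sampler on load.  A cohort manifest is a YAML file listing session
paths with metadata.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import ValidationError, downsample_gsr
from .synthdata import GSR_NATIVE_HZ, STATES, PhysioSession

_META_COLS = ("time_s", "state", "phase")


class SchemaError(ValidationError):
    pass


def write_session(session: PhysioSession, path) -> Path:
    """Write a session (and its optional 5 Hz GSR sidecar) to CSV."""
    path = Path(path)
    df = session.data.reset_index()
    df["state"] = session.states
    df["phase"] = session.phase
    df.to_csv(path, index=False, float_format="%.10g")
    if session.gsr_5hz is not None:
        side = pd.DataFrame({
            "time_s": np.arange(len(session.gsr_5hz)) / GSR_NATIVE_HZ,
            "GSR": session.gsr_5hz,
        })
        side.to_csv(_sidecar_path(path), index=False, float_format="%.10g")
    return path


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".gsr5hz.csv")


def read_session(path, subject: str | None = None) -> PhysioSession:
    """Read a session CSV (validating the schema) into a PhysioSession.

    A ``<stem>.gsr5hz.csv`` sidecar, when present, replaces the GSR column
    with the block-mean down-sampled native trace.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in _META_COLS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    channels = [c for c in df.columns if c not in _META_COLS]
    if not channels:
        raise SchemaError(f"{path}: no channel columns")
    t = df["time_s"].to_numpy()
    if not np.all(np.diff(t) > 0):
        bad = int(np.nonzero(np.diff(t) <= 0)[0][0]) + 2
        raise SchemaError(f"{path}: non-monotone time at line {bad}")
    bad_state = ~df["state"].isin(STATES)
    if bad_state.any():
        line = int(bad_state.idxmax()) + 2
        raise SchemaError(f"{path}: unknown state at line {line}")
    if df[channels].isna().any().any():
        row = int(df[channels].isna().any(axis=1).idxmax()) + 2
        raise SchemaError(f"{path}: missing channel value at line {row}")
    stim = (df["phase"] == "stimulation").to_numpy()
    if not stim.any():
        raise SchemaError(f"{path}: no stimulation phase")
    boundary = int(np.argmax(stim))

    gsr_5hz = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        side = pd.read_csv(sidecar)
        if "GSR" not in side.columns:
            raise SchemaError(f"{sidecar}: missing GSR column")
        if "GSR" not in channels:
            raise SchemaError(f"{path}: sidecar present but no GSR channel")
        gsr_5hz = side["GSR"].to_numpy(dtype=float)
        df["GSR"] = downsample_gsr(gsr_5hz, GSR_NATIVE_HZ)[: len(df)]

    data = df[channels].copy()
    data.index = pd.RangeIndex(len(df), name="time_s")
    sess = PhysioSession(
        data=data, states=df["state"].to_numpy(dtype=object),
        boundary=boundary, subject=subject or path.stem, gsr_5hz=gsr_5hz)
    sess.validate()
    return sess


def write_manifest(paths: list[Path], manifest_path, seed: int | None = None,
                   extra: dict | None = None) -> Path:
    """Write a cohort manifest (YAML) listing session files."""
    manifest_path = Path(manifest_path)
    doc = {"sessions": [str(Path(p).name) for p in paths]}
    if seed is not None:
        doc["seed"] = seed
    if extra:
        doc.update(extra)
    manifest_path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return manifest_path


def read_manifest(manifest_path) -> list[PhysioSession]:
    """Load every session listed in a manifest (paths relative to it)."""
    manifest_path = Path(manifest_path)
    doc = yaml.safe_load(manifest_path.read_text())
    if not isinstance(doc, dict) or "sessions" not in doc:
        raise SchemaError(f"{manifest_path}: not a cohort manifest")
    return [read_session(manifest_path.parent / p) for p in doc["sessions"]]


@dataclass
class RunConfig:
    """Validated run configuration (unknown keys rejected)."""

    detector: str = "ocsvm"
    cW: int = 70
    nu: float = 0.1
    seed: int = 0
    epochs: int | None = None
    scaled: bool = True
    output_dir: str = "."
    extra: dict = field(default_factory=dict)

    _KNOWN = ("detector", "cW", "nu", "seed", "epochs", "scaled", "output_dir")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(doc) - set(cls._KNOWN)
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "extra"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def stamp_artifact(path, seed: int, config_hash: str) -> None:
    """Write a ``<path>.meta.json`` sidecar recording seed + config hash."""
    meta = {"seed": seed, "config_hash": config_hash}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))
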