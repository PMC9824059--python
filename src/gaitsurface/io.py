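"""On-disk formats: recording CSVs with JSON sidecars, feature tables.

Recording CSV schema: columns ``time_s,x,y,z,label`` (9 significant digits
for numerics), one file per subject x location, with a sidecar
``<stem>.meta.json`` holding ``subject_id``, ``location`` and
``sampling_rate_hz``.  Writer and reader round-trip bit-exactly at the
written precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .features import FeatureMatrix
from .simulate import LOCATIONS, SURFACE_LABELS, AccelerometerRecording

RECORDING_COLUMNS = ("time_s", "x", "y", "z", "label")
_FLOAT_FMT = "%.9g"


def recording_filename(subject_id: str, location: str) -> str:
    return f"{subject_id}_{location}.csv"


def write_recording_csv(recording: AccelerometerRecording, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": recording.timestamps,
            "x": recording.xyz[:, 0],
            "y": recording.xyz[:, 1],
            "z": recording.xyz[:, 2],
            "label": recording.sample_labels,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta = {
        "subject_id": recording.subject_id,
        "location": recording.location,
        "sampling_rate_hz": recording.sampling_rate,
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))
    return path


def read_recording_csv(path: str | Path) -> AccelerometerRecording:
    """Read and validate a recording CSV (uniform sampling within 1%)."""
    path = Path(path)
    meta_path = path.with_suffix(".meta.json")
    if not meta_path.exists():
        raise SchemaError(f"missing sidecar metadata file {meta_path}")
    meta = json.loads(meta_path.read_text())
    for key in ("subject_id", "location", "sampling_rate_hz"):
        if key not in meta:
            raise SchemaError(f"{meta_path}: missing metadata key {key!r}")
    if meta["location"] not in LOCATIONS:
        raise SchemaError(f"{meta_path}: unknown location {meta['location']!r}")

    df = pd.read_csv(path)
    missing = set(RECORDING_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    bad = ~df["label"].isin(SURFACE_LABELS)
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2  # header + 1-based
        raise SchemaError(
            f"{path}: unknown label {df['label'][bad.idxmax()]!r} at line {line}"
        )
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise SchemaError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        line = int(np.flatnonzero(dt <= 0)[0]) + 3
        raise SchemaError(f"{path}: non-increasing time at line {line}")
    fs = float(meta["sampling_rate_hz"])
    nominal = 1.0 / fs
    gaps = np.flatnonzero(dt > 2.0 * nominal)
    if len(gaps):
        raise SchemaError(
            f"{path}: time gap of {dt[gaps[0]]:.6g} s after "
            f"t={t[gaps[0]]:.6g} s (> 2 samples)"
        )
    if np.any(np.abs(dt - nominal) > 0.01 * nominal):
        line = int(np.flatnonzero(np.abs(dt - nominal) > 0.01 * nominal)[0]) + 3
        raise SchemaError(
            f"{path}: sampling interval deviates from 1/{fs:g} s by more "
            f"than 1% at line {line}"
        )
    return AccelerometerRecording(
        timestamps=t,
        xyz=df[["x", "y", "z"]].to_numpy(dtype=float),
        location=meta["location"],
        subject_id=str(meta["subject_id"]),
        sample_labels=df["label"].to_numpy(dtype=object),
        sampling_rate=fs,
    )


def write_feature_table(fm: FeatureMatrix, path: str | Path) -> Path:
    path = Path(path)
    fm.to_frame().to_csv(path, index=False, float_format="%.12g")
    return path


def read_feature_table(path: str | Path) -> FeatureMatrix:
    return FeatureMatrix.from_frame(pd.read_csv(Path(path)))
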