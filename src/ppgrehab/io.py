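"""File formats: record CSV + sidecar metadata, cohort containers, hashing.

A record is stored as CSV with header ``t,green,red,ir`` (time in seconds,
then three intensity columns) plus a JSON sidecar carrying subject_id,
stage, fs and a config hash.  Whole cohorts go into a single ``.npz``
container with embedded metadata.  All floats are written at fixed
precision so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import PpgRecord

__all__ = [
    "write_record_csv",
    "read_record_csv",
    "write_cohort",
    "read_cohort",
    "config_hash",
    "file_sha256",
]

_FLOAT_FMT = "%.6f"
_COLUMNS = ["t", "green", "red", "ir"]


def config_hash(config_dict: dict) -> str:
    """Stable hash of a configuration mapping (sorted-key JSON, sha256)."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_record_csv(record: PpgRecord, path: str | Path,
                     config_digest: str | None = None) -> Path:
    path = Path(path)
    df = pd.DataFrame({
        "t": record.t, "green": record.green,
        "red": record.red, "ir": record.ir,
    })
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta = {
        "subject_id": record.subject_id,
        "stage": record.stage,
        "fs": record.fs,
        "n_samples": record.n_samples,
        "config_hash": config_digest,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_record_csv(path: str | Path) -> PpgRecord:
    """Read a record CSV; fs is inferred from the time column and
    cross-checked against the sidecar metadata when present."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    t = df["t"].to_numpy(dtype=float)
    if len(t) > 1:
        dt = np.diff(t)
        bad = np.flatnonzero(dt <= 0)
        if bad.size:
            raise ValueError(
                f"{path}: non-monotone time column at line {bad[0] + 2}"
            )
        fs = 1.0 / float(np.median(dt))
    else:
        fs = float("nan")
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if len(t) > 1 and abs(fs - meta["fs"]) > 0.01 * meta["fs"]:
            raise ValueError(
                f"{path}: inferred fs {fs:.3f} Hz disagrees with sidecar "
                f"fs {meta['fs']} Hz"
            )
        fs = float(meta["fs"])
    return PpgRecord(
        subject_id=meta.get("subject_id", path.stem),
        stage=meta.get("stage", "VII"),
        fs=fs,
        green=df["green"].to_numpy(dtype=float),
        red=df["red"].to_numpy(dtype=float),
        ir=df["ir"].to_numpy(dtype=float),
        t0=float(t[0]) if len(t) else 0.0,
    )


def write_cohort(records: list[PpgRecord], path: str | Path,
                 config_dict: dict | None = None) -> Path:
    """Single-file binary container for a whole cohort (.npz)."""
    path = Path(path)
    arrays = {}
    meta = []
    for i, rec in enumerate(records):
        arrays[f"rec{i}"] = rec.channels()
        meta.append({"subject_id": rec.subject_id, "stage": rec.stage,
                     "fs": rec.fs, "t0": rec.t0})
    arrays["meta"] = np.frombuffer(
        json.dumps({"records": meta, "config": config_dict},
                   sort_keys=True).encode(), dtype=np.uint8,
    )
    np.savez_compressed(path, **arrays)
    return path


def read_cohort(path: str | Path) -> list[PpgRecord]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        records = []
        for i, m in enumerate(meta["records"]):
            chans = data[f"rec{i}"]
            records.append(PpgRecord(
                subject_id=m["subject_id"], stage=m["stage"], fs=m["fs"],
                green=chans[0], red=chans[1], ir=chans[2], t0=m["t0"],
            ))
    return records
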