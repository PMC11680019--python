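"""Delimited-text input/output.

Waveforms travel as CSV (``time,green,red,nir``, red and nir optional)
with a YAML key-value sidecar (``<name>.meta.yaml``) holding subject id,
group, posture, cooling state, wrist SBP and the sampling rate. Output
tables are CSV with the full configuration echoed in ``#``-prefixed
header lines so any run can be reproduced exactly.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .config import PipelineConfig
from .errors import LoadError
from .records import KNOWN_CHANNELS, RecordMetadata, WaveformRecord

__all__ = ["read_record", "write_record", "sidecar_path",
           "write_table", "read_table"]

_JITTER_TOL = 0.01  # 1% allowed deviation of any sampling interval


def sidecar_path(csv_path) -> Path:
    return Path(csv_path).with_suffix(".meta.yaml")


def read_record(path) -> WaveformRecord:
    """Load a waveform CSV (+ optional metadata sidecar) into a record.

    Validates strictly monotone time and uniform sampling within 1%;
    irregular input is rejected rather than resampled.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise LoadError(f"{path}: cannot read CSV ({exc})") from exc
    if "time" not in df.columns:
        raise LoadError(f"{path}: missing required 'time' column")
    channels = {c: df[c].to_numpy(dtype=float)
                for c in KNOWN_CHANNELS if c in df.columns}
    if not channels:
        raise LoadError(
            f"{path}: no channel columns found (expected some of "
            f"{KNOWN_CHANNELS})")
    t = df["time"].to_numpy(dtype=float)
    if t.size < 2:
        raise LoadError(f"{path}: fewer than 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise LoadError(f"{path}: time column is not strictly increasing")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > _JITTER_TOL * med:
        raise LoadError(
            f"{path}: sampling jitter exceeds {_JITTER_TOL:.0%} of the "
            f"median interval; irregularly sampled input is rejected")
    meta = RecordMetadata()
    fs = 1.0 / med
    side = sidecar_path(path)
    if side.exists():
        try:
            raw = yaml.safe_load(side.read_text()) or {}
        except yaml.YAMLError as exc:
            raise LoadError(f"{side}: bad sidecar ({exc})") from exc
        fs = float(raw.pop("sampling_rate", fs))
        if abs(fs - 1.0 / med) > _JITTER_TOL * fs:
            raise LoadError(
                f"{side}: sampling_rate {fs} Hz disagrees with the time "
                f"column ({1.0 / med:.3f} Hz)")
        wrist = raw.pop("wrist_sbp", None)
        meta = RecordMetadata(
            subject_id=str(raw.pop("subject_id", "unknown")),
            group=str(raw.pop("group", "unknown")),
            posture=str(raw.pop("posture", "other")),
            cooled=bool(raw.pop("cooled", False)),
            wrist_sbp=None if wrist is None else float(wrist),
            record_id=str(raw.pop("record_id", path.stem)),
            extra=raw)
    else:
        meta.record_id = path.stem
    return WaveformRecord(channels=channels, sampling_rate=fs,
                          t0=float(t[0]), metadata=meta)


def write_record(record: WaveformRecord, path) -> Path:
    """Write a record as CSV plus metadata sidecar; returns the CSV path."""
    path = Path(path)
    cols = {"time": record.times()}
    for name in KNOWN_CHANNELS:
        if name in record.channels:
            cols[name] = record.channels[name]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")
    m = record.metadata
    side = {
        "record_id": m.record_id, "subject_id": m.subject_id,
        "group": m.group, "posture": m.posture, "cooled": m.cooled,
        "wrist_sbp": m.wrist_sbp, "sampling_rate": record.sampling_rate,
    }
    side.update(m.extra)
    sidecar_path(path).write_text(yaml.safe_dump(side, sort_keys=False))
    return path


def write_table(df: pd.DataFrame, path,
                config: Optional[PipelineConfig] = None) -> Path:
    """Write a result table as CSV with the config echoed in the header."""
    path = Path(path)
    buf = _io.StringIO()
    if config is not None:
        for line in yaml.safe_dump(config.to_dict(),
                                   sort_keys=False).splitlines():
            buf.write(f"# {line}\n")
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue())
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
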