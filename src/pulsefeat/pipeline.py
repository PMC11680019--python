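"""End-to-end processing: records in, feature/QC tables out.

``measure_record`` runs one record through filtering, derivative
computation, beat segmentation, landmark detection, feature
aggregation, cross-channel delay pairing and QC. ``run_pipeline`` maps
it over many inputs and applies the exclusion rules, producing the
record-level feature table (kept records only) and the QC table (all
records). Both are deterministic for fixed inputs and configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import LoadError, PulsefeatError
from .fiducials import (FEATURE_COLUMNS, DelaySeries, aggregate_record,
                        channel_delay, corrected_height_S, extract_beats)
from .io import read_record
from .quality import QualityReport, apply_exclusions, compute_snr, noise_rms
from .records import WaveformRecord
from .signal_processing import (bandpass_filter, derive, highpass_detrend,
                                iter_beats, segment_beats)

logger = logging.getLogger("pulsefeat")

__all__ = ["RecordResult", "measure_record", "run_pipeline",
           "TABLE_COLUMNS"]

TABLE_COLUMNS = ("record_id", "subject_id", "group", "posture", "cooled",
                 "wrist_sbp") + FEATURE_COLUMNS + ("delay_green_nir",
                                                   "n_beats")


@dataclass
class RecordResult:
    record_id: str
    features: Dict[str, Optional[float]] = field(default_factory=dict)
    quality: QualityReport = field(default_factory=QualityReport)
    delays: Optional[DelaySeries] = None
    status: str = "processed"


def _channel_S(ppg: np.ndarray, index, fs: float,
               aggregate: str) -> Optional[float]:
    vals = [s for i0, i1 in iter_beats(index)
            for s, ok in [corrected_height_S(ppg, i0, i1, fs)] if ok]
    if not vals:
        return None
    agg = np.median if aggregate == "median" else np.mean
    return float(agg(vals))


def measure_record(record: WaveformRecord,
                   config: Optional[PipelineConfig] = None) -> RecordResult:
    """Full single-record measurement.

    Morphology features come from ``config.feature_channel`` (green by
    default — the channel the steepness features are defined on); the
    a-wave delay pairs the green and NIR channels; SNR is computed for
    every configured QC channel on its 0.5 Hz high-passed raw trace so
    broadband noise is counted at full RMS.
    """
    config = config or PipelineConfig()
    config.validate()
    fs = record.sampling_rate
    rid = record.metadata.record_id
    result = RecordResult(record_id=rid)
    result.quality.record_id = rid

    filtered = bandpass_filter(record, config.filter)
    derived, indices, fiducials, features = {}, {}, {}, {}
    for ch in record.channels:
        if ch == "red":
            continue  # red is carried for oximetry hardware, not analyzed
        d = derive(filtered.channels[ch], fs, config.smoothing_window)
        idx = segment_beats(d, fs, config.hr_bounds, config.refractory)
        derived[ch] = d
        indices[ch] = idx
        fids, feats = extract_beats(d, idx, t0=record.t0)
        fiducials[ch] = fids
        features[ch] = feats

    fch = config.feature_channel
    if fch not in features:
        result.status = "feature_channel_missing"
        row = {k: None for k in FEATURE_COLUMNS}
        row.update({"delay_green_nir": None, "n_beats": 0,
                    "_any_valid": False})
        result.features = row
        return result

    delays: Optional[DelaySeries] = None
    if "green" in fiducials and "nir" in fiducials:
        delays = channel_delay(fiducials["green"], fiducials["nir"],
                               config.pairing_window, config.aggregate)
    result.delays = delays
    result.features = aggregate_record(features[fch], delays,
                                       config.aggregate)

    # --- QC: per-channel SNR on the detrended raw signal ---------------
    qc = result.quality
    worst = None
    for ch in config.qc_channels:
        if ch not in record.channels or ch not in indices:
            continue
        detrended = highpass_detrend(record.channels[ch], fs,
                                     cutoff=config.filter.low_cut)
        rms, _ = noise_rms(detrended, indices[ch])
        s_ch = _channel_S(derived[ch].ppg, indices[ch], fs, config.aggregate)
        snr, capped = compute_snr(s_ch, rms)
        qc.per_channel[ch] = snr
        if snr is not None and (worst is None or snr < worst[1]):
            worst = (ch, snr, s_ch, rms, capped)
    if worst is not None:
        ch, snr, s_ch, rms, capped = worst
        qc.signal_intensity = s_ch
        qc.noise_rms = rms
        qc.snr = snr
        qc.snr_capped = capped
    if not result.features.get("_any_valid", False):
        result.status = "no_valid_beats"
    return result


def run_pipeline(inputs: Sequence[Union[str, WaveformRecord]],
                 config: Optional[PipelineConfig] = None
                 ) -> Tuple[pd.DataFrame, pd.DataFrame, List[str]]:
    """Process many records and apply the exclusion rules.

    ``inputs`` may mix file paths and in-memory records. Returns
    ``(features, qc, logs)``: ``features`` holds one row per *kept*
    record, ``qc`` one row per input (including load failures), and
    ``logs`` a human-readable account of the run. Raises only if every
    input fails to load.
    """
    config = config or PipelineConfig()
    config.validate()
    logs: List[str] = [f"pulsefeat run: {len(inputs)} input(s)"]
    results: List[RecordResult] = []
    records: Dict[str, WaveformRecord] = {}
    n_load_failures = 0
    for item in inputs:
        if isinstance(item, WaveformRecord):
            record = item
        else:
            try:
                record = read_record(item)
            except LoadError as exc:
                n_load_failures += 1
                logs.append(f"SKIP {item}: {exc}")
                continue
        try:
            res = measure_record(record, config)
        except PulsefeatError as exc:
            res = RecordResult(record_id=record.metadata.record_id,
                               status=f"error: {exc}")
            res.features = {"_any_valid": False}
        results.append(res)
        records[res.record_id] = record
        logs.append(f"OK {res.record_id}: {res.status}")
    if not results:
        raise LoadError("all inputs failed to load")

    qc_rows = []
    for res in results:
        meta = records[res.record_id].metadata
        qc_rows.append({
            "record_id": res.record_id,
            "S": res.quality.signal_intensity,
            "noise_rms": res.quality.noise_rms,
            "snr": res.quality.snr,
            "wrist_sbp": meta.wrist_sbp,
            "features_ok": bool(res.features.get("_any_valid", False)),
        })
    qc = apply_exclusions(pd.DataFrame(qc_rows), config.snr_threshold)

    kept = set(qc.loc[~qc["excluded"], "record_id"])
    feat_rows = []
    for res in results:
        if res.record_id not in kept:
            continue
        meta = records[res.record_id].metadata
        row = {"record_id": res.record_id, "subject_id": meta.subject_id,
               "group": meta.group, "posture": meta.posture,
               "cooled": meta.cooled, "wrist_sbp": meta.wrist_sbp}
        row.update({k: v for k, v in res.features.items()
                    if not k.startswith("_")})
        feat_rows.append(row)
    features = pd.DataFrame(feat_rows, columns=list(TABLE_COLUMNS))
    n_excluded = int(qc["excluded"].sum())
    logs.append(f"kept {len(feat_rows)} record(s), excluded {n_excluded}, "
                f"load failures {n_load_failures}")
    for reason, count in _reason_counts(qc).items():
        logs.append(f"  excluded for {reason}: {count}")
    return features, qc, logs


def _reason_counts(qc: pd.DataFrame) -> Dict[str, int]:
    counts: Dict[str, int] = {}
    for r in qc.loc[qc["excluded"], "reasons"]:
        for reason in str(r).split(";"):
            if reason:
                counts[reason] = counts.get(reason, 0) + 1
    return counts
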