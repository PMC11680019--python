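"""Signal-to-noise quality control and record exclusion rules.

SNR is defined as the pulse height S divided by the RMS of what remains
after removing the repeating pulse component from the signal. The pulse
component is estimated as the ensemble-average beat template: beats are
time-normalized to the median beat length, averaged, and the template is
mapped back onto each beat before subtraction. Records are excluded when

* the SNR of any analyzed channel is strictly below 200,
* wrist blood pressure is missing, or
* the feature set could not be computed (e.g. no detectable beats).

The threshold is strict: SNR exactly 200 is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .signal_processing import BeatIndex

__all__ = ["QualityReport", "noise_rms", "compute_snr", "apply_exclusions",
           "SNR_CAP"]

SNR_CAP = 1e6

REASON_SNR = "snr_below_200"
REASON_BP = "missing_bp"
REASON_FEATURE = "feature_failure"


@dataclass
class QualityReport:
    """Per-record QC summary.

    ``signal_intensity``, ``noise_rms`` and ``snr`` refer to the worst
    (lowest-SNR) analyzed channel; per-channel values are kept alongside.
    """

    record_id: str = "unknown"
    signal_intensity: Optional[float] = None
    noise_rms: Optional[float] = None
    snr: Optional[float] = None
    snr_capped: bool = False
    per_channel: Dict[str, Optional[float]] = field(default_factory=dict)
    excluded: bool = False
    reasons: List[str] = field(default_factory=list)


def _onsets_from_anchors(anchors: np.ndarray,
                         gamma: float) -> np.ndarray:
    """Beat-onset times reconstructed from the upstroke anchors.

    The upstroke anchor sits at a fixed phase ``gamma`` of its beat, so
    ``a_k = (1 - gamma) * o_k + gamma * o_(k+1)`` where ``o_k`` are the
    onset times; given gamma this bidiagonal relation is solved by
    backward substitution. Solving through the (sharp, noise-robust)
    anchors gives far more precise onsets than the boundary minima
    themselves, which wander across the flat inter-beat valley under
    noise.
    """
    n = anchors.size
    onsets = np.empty(n + 1)
    onsets[n] = anchors[-1] + (1.0 - gamma) * (anchors[-1] - anchors[-2])
    for k in range(n - 1, -1, -1):
        onsets[k] = (anchors[k] - gamma * onsets[k + 1]) / (1.0 - gamma)
    return onsets


def noise_rms(ppg_channel: np.ndarray, index: BeatIndex,
              min_beats: int = 3,
              edge_margin: float = 3.0) -> Tuple[Optional[float], int]:
    """RMS of the residual after ensemble-template subtraction.

    Beats are delimited by onset times reconstructed from the
    sub-sample systolic-upstroke anchors of ``index`` (falling back to
    the boundary minima when anchors are absent), linearly
    time-normalized to a common phase axis, and averaged into a
    template; the residual is then evaluated at the original integer
    samples against the interpolated template, so broadband noise keeps
    its full RMS. Beats within ``edge_margin`` seconds of the record
    edges are skipped: zero-phase filter transients at a 0.5 Hz corner
    need a few seconds to die out and would otherwise leak into the
    template.

    Returns ``(rms, n_beats_used)``; ``rms`` is ``None`` with fewer than
    ``min_beats`` usable beats (the record is flagged, SNR absent).
    """
    x = np.asarray(ppg_channel, dtype=float)
    fs = index.sampling_rate
    lo_bpm, hi_bpm = index.hr_bounds
    min_len, max_len = 60.0 / hi_bpm * fs, 60.0 / lo_bpm * fs
    margin = edge_margin * fs
    # short records cannot afford the full settle-in margin; shrink it
    # until enough beats survive (their estimate is slightly pessimistic)
    probe = (index.anchors if index.anchors.size >= 2
             else index.boundaries.astype(float))
    while margin > 0.4 * fs:
        n_ok = sum(1 for a0, a1 in zip(probe[:-1], probe[1:])
                   if a0 >= margin and a1 <= x.size - 1 - margin)
        if n_ok >= max(min_beats, 5):
            break
        margin /= 2.0

    def _detrended_sq(r: np.ndarray) -> float:
        # per-beat linear detrend: slow baseline modulation (e.g.
        # pulse-rate-dependent DC level) is not noise and cannot be
        # represented by a single template; two parameters per beat
        # cannot absorb broadband noise
        n = r.size
        if n > 8:
            w = np.arange(n) - (n - 1) / 2.0
            r = r - r.mean() - (float(w @ r) / float(w @ w)) * w
        return float(r @ r)

    def residual(edges: np.ndarray,
                 gn_rounds: int = 1) -> Tuple[Optional[float], int]:
        spans = [[a0, a1] for a0, a1 in zip(edges[:-1], edges[1:])
                 if min_len <= a1 - a0 <= max_len
                 and a0 >= margin and a1 <= x.size - 1 - margin]
        if len(spans) < min_beats:
            return None, len(spans)

        def build(spans_now):
            m = int(np.median([a1 - a0 for a0, a1 in spans_now]))
            grid = np.arange(m) / m  # phase in [0, 1), one cycle per span
            core, padded = [], []
            for a0, a1 in spans_now:
                idx = np.arange(int(np.ceil(a0)), int(np.ceil(a1)))
                core.append((idx, (idx - a0) / (a1 - a0)))
                # extra samples per side so the template is interpolated,
                # never flat-extrapolated, at the span ends
                pad = np.arange(max(0, idx[0] - 4), min(x.size, idx[-1] + 5))
                padded.append((pad, (pad - a0) / (a1 - a0)))
            template = np.mean(
                [np.interp(grid, u, x[idx]) for idx, u in padded], axis=0)
            return grid, template, core

        # per-beat time-shift refinement (Gauss-Newton on the template
        # gradient): the span edges inherit timing jitter from the
        # upstroke anchors, worst for slow-rising pulses; one shift
        # parameter per ~1000 samples cannot absorb random noise
        for _ in range(gn_rounds):
            grid, template, core = build(spans)
            for k, (idx, u) in enumerate(core):
                tq = np.interp(u, grid, template)
                dt = np.gradient(tq)
                denom = float(dt @ dt)
                if denom <= 0:
                    continue
                delta = -float((x[idx] - tq) @ dt) / denom
                delta = float(np.clip(delta, -10.0, 10.0))
                spans[k][0] += delta
                spans[k][1] += delta
        grid, template, core = build(spans)
        sq_sum = 0.0
        n_tot = 0
        for idx, u in core:
            sq_sum += _detrended_sq(x[idx] - np.interp(u, grid, template))
            n_tot += idx.size
        return float(np.sqrt(sq_sum / n_tot)), len(spans)

    if index.anchors.size < 3:
        if index.boundaries.size < 2:
            return None, 0
        return residual(index.boundaries.astype(float), gn_rounds=2)
    # the anchor phase gamma is the single free alignment parameter of
    # the onset reconstruction; pick it by minimizing the residual
    # (template registration) — one scalar cannot absorb broadband noise
    gammas = np.linspace(0.04, 0.6, 9)
    out = [residual(_onsets_from_anchors(index.anchors, g)) for g in gammas]
    vals = [np.inf if rms is None else rms for rms, _ in out]
    k = int(np.argmin(vals))
    if not np.isfinite(vals[k]):
        return None, out[k][1]
    rms, nb = residual(_onsets_from_anchors(index.anchors, gammas[k]),
                       gn_rounds=2)
    if rms is not None and rms <= vals[k]:
        return rms, nb
    return out[k]


def compute_snr(signal_intensity: float,
                noise: Optional[float]) -> Tuple[Optional[float], bool]:
    """SNR = S / noise RMS. Zero noise reports the configured cap with a
    flag; missing noise reports ``None``."""
    if noise is None or signal_intensity is None:
        return None, False
    if noise <= 0:
        return SNR_CAP, True
    return float(signal_intensity) / float(noise), False


def apply_exclusions(table: pd.DataFrame,
                     snr_threshold: float = 200.0) -> pd.DataFrame:
    """Apply the exclusion rules to a per-record QC table.

    ``table`` needs columns ``snr`` (worst-channel SNR; NaN when it could
    not be computed), ``wrist_sbp`` (NaN when the cuff measurement
    failed) and ``features_ok`` (bool). Returns a copy with ``excluded``
    and ``reasons`` columns; exclusion is data, not an error, and a
    record is excluded iff at least one rule fires. SNR strictly below
    the threshold excludes; exactly at the threshold keeps.
    """
    out = table.copy()
    reasons: List[str] = []
    excluded: List[bool] = []
    for _, row in out.iterrows():
        r = []
        snr = row.get("snr", np.nan)
        if pd.isna(snr) or snr < snr_threshold:
            # an uncomputable SNR means the pulse component itself failed
            if pd.isna(snr):
                r.append(REASON_FEATURE)
            else:
                r.append(REASON_SNR)
        if pd.isna(row.get("wrist_sbp", np.nan)):
            r.append(REASON_BP)
        if not bool(row.get("features_ok", True)):
            if REASON_FEATURE not in r:
                r.append(REASON_FEATURE)
        reasons.append(";".join(r))
        excluded.append(bool(r))
    out["excluded"] = excluded
    out["reasons"] = reasons
    return out
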