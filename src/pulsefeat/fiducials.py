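"""Per-beat landmarks and the pulse-wave feature set.

For each beat this module locates the classical landmarks: PPG bounding
minima and maximum, the VPG systolic maximum, and the APG a–e waves
(a, c, e positive peaks; b, d negative troughs). From them it computes:

* ``S`` — PPG pulse height after subtracting the straight line joining
  the beat's bounding minima (baseline slope correction), and ``1/S``;
* ``FWHM_VPG`` — full width at half maximum of the VPG systolic peak,
  and its reciprocal, an index of upstroke steepness;
* ``a``, ``a/S`` — APG a-wave height, absolute and normalized by S;
* ``ab`` time (a-to-b peak interval) and its reciprocal;
* normalized ``a-b`` and ``a-d`` amplitude drops (APG scaled so the
  a-wave is 1) and their ratio;
* the per-beat green-vs-near-infrared a-wave peak delay, interpreted as
  the pulse transit time from deeper arterioles to skin capillaries.

Peak times are refined by three-point parabolic interpolation so that
delays well below one sample period remain resolvable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .signal_processing import (BeatIndex, DerivedSignals, iter_beats,
                                parabolic_refine as _parabolic_refine)

__all__ = [
    "FiducialPoint", "BeatFiducials", "BeatFeatures", "DelaySeries",
    "corrected_height_S", "detect_apg_waves", "fwhm_vpg", "beat_features",
    "channel_delay", "aggregate_record", "extract_beats",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = (
    "S", "inv_S", "a", "a_over_S", "fwhm_vpg", "inv_fwhm_vpg",
    "ab_time", "inv_ab_time", "norm_ab", "norm_ad", "ab_over_ad",
)


@dataclass(frozen=True)
class FiducialPoint:
    time: float      # seconds, on the record time axis
    amplitude: float


@dataclass
class BeatFiducials:
    """Landmark times/amplitudes for one beat of one channel."""

    ppg_min_start: Optional[FiducialPoint] = None
    ppg_max: Optional[FiducialPoint] = None
    ppg_min_end: Optional[FiducialPoint] = None
    vpg_max: Optional[FiducialPoint] = None
    apg_a: Optional[FiducialPoint] = None
    apg_b: Optional[FiducialPoint] = None
    apg_c: Optional[FiducialPoint] = None
    apg_d: Optional[FiducialPoint] = None
    apg_e: Optional[FiducialPoint] = None
    valid: bool = True
    reason: Optional[str] = None

    def invalidate(self, reason: str) -> None:
        self.valid = False
        self.reason = self.reason or reason


@dataclass
class BeatFeatures:
    """Feature values for one beat; ``None`` marks an uncomputable one."""

    S: Optional[float] = None
    inv_S: Optional[float] = None
    a: Optional[float] = None
    a_over_S: Optional[float] = None
    fwhm_vpg: Optional[float] = None
    inv_fwhm_vpg: Optional[float] = None
    ab_time: Optional[float] = None
    inv_ab_time: Optional[float] = None
    norm_ab: Optional[float] = None
    norm_ad: Optional[float] = None
    ab_over_ad: Optional[float] = None

    def as_dict(self) -> Dict[str, Optional[float]]:
        return {k: getattr(self, k) for k in FEATURE_COLUMNS}


@dataclass
class DelaySeries:
    """Per-beat green-minus-NIR a-wave delays with their pairing."""

    delays: np.ndarray                  # seconds, one per matched pair
    pairs: List[Tuple[int, int]]        # (nir beat idx, green beat idx)
    summary: Optional[float] = None
    aggregate: str = "median"
    flagged: bool = False


def corrected_height_S(ppg: np.ndarray, i0: int, i1: int,
                       sampling_rate: float) -> Tuple[Optional[float], bool]:
    """Baseline-corrected pulse height S of the beat ``ppg[i0:i1+1]``.

    The straight line joining the two bounding minima is subtracted
    (equivalently, the beat is tilted so that line is horizontal) and S
    is the maximum of the residual. Returns ``(S, valid)``; a beat whose
    maximum sits on a boundary, or whose S is non-positive, is invalid.
    """
    seg = np.asarray(ppg[i0:i1 + 1], dtype=float)
    if seg.size < 3:
        return None, False
    line = np.linspace(seg[0], seg[-1], seg.size)
    resid = seg - line
    k = int(np.argmax(resid))
    if k == 0 or k == seg.size - 1:
        return None, False
    s = float(resid[k])
    if s <= 0:
        return None, False
    return s, True


def _alternating_extrema(apg: np.ndarray, start: int, stop: int,
                         fs: float, t0: float
                         ) -> List[Tuple[str, FiducialPoint]]:
    """Local max/min sequence of the APG on [start, stop), time-refined."""
    seg = apg[start:stop]
    if seg.size < 3:
        return []
    maxima, _ = sps.find_peaks(seg)
    minima, _ = sps.find_peaks(-seg)
    tagged = sorted([(i, "max") for i in maxima] + [(i, "min") for i in minima])
    out = []
    for i, kind in tagged:
        idx, amp = _parabolic_refine(apg, start + i)
        out.append((kind, FiducialPoint(time=t0 + idx / fs, amplitude=amp)))
    return out


def detect_apg_waves(apg: np.ndarray, vpg: np.ndarray, ppg: np.ndarray,
                     i0: int, i1: int, sampling_rate: float,
                     t0: float = 0.0,
                     cde_fraction: float = 0.8) -> BeatFiducials:
    """Locate the APG a–e waves (and PPG/VPG landmarks) for one beat.

    The a-wave is the APG global maximum in the systolic-rise window
    (beat onset to the PPG maximum); b is the first trough after a; c, d
    and e are the subsequent alternating extrema, searched only within
    the first ``cde_fraction`` of the beat so that late-diastolic noise
    never masquerades as a wave. Beats lacking a or b are flagged invalid; missing c/d/e only
    suppress the features that need them.
    """
    fs = sampling_rate
    fid = BeatFiducials()
    n = i1 - i0
    if n < 3:
        fid.invalidate("beat too short")
        return fid
    fid.ppg_min_start = FiducialPoint(t0 + i0 / fs, float(ppg[i0]))
    fid.ppg_min_end = FiducialPoint(t0 + i1 / fs, float(ppg[i1]))
    kmax = i0 + int(np.argmax(ppg[i0:i1 + 1]))
    if kmax in (i0, i1):
        fid.invalidate("no interior PPG maximum")
        return fid
    idx, amp = _parabolic_refine(ppg, kmax)
    fid.ppg_max = FiducialPoint(t0 + idx / fs, amp)

    kv = i0 + int(np.argmax(vpg[i0:i1 + 1]))
    idx, amp = _parabolic_refine(vpg, kv)
    fid.vpg_max = FiducialPoint(t0 + idx / fs, amp)

    # a-wave: global APG max during the systolic rise
    rise_end = max(kmax, i0 + 2)
    ka = i0 + int(np.argmax(apg[i0:rise_end + 1]))
    idx, amp = _parabolic_refine(apg, ka)
    if amp <= 0:
        fid.invalidate("a-wave not positive")
        return fid
    fid.apg_a = FiducialPoint(t0 + idx / fs, amp)

    stop = i0 + max(int(math.ceil(cde_fraction * n)), 3)
    stop = min(stop, i1 + 1)
    extrema = _alternating_extrema(apg, ka, stop, fs, t0)
    # first trough after a is b; then alternate c (max), d (min), e (max)
    want = iter(("min:apg_b", "max:apg_c", "min:apg_d", "max:apg_e"))
    target = next(want)
    for kind, pt in extrema:
        k, name = target.split(":")
        if kind == k and pt.time > fid.apg_a.time:
            setattr(fid, name, pt)
            try:
                target = next(want)
            except StopIteration:
                break
    if fid.apg_b is None:
        fid.invalidate("b-wave not found")
    return fid


def fwhm_vpg(vpg: np.ndarray, i0: int, i1: int,
             sampling_rate: float) -> Optional[float]:
    """Full width at half maximum of the VPG systolic peak, in seconds.

    The half level is half the parabola-refined peak amplitude; each
    crossing is located by linear interpolation between the adjacent
    samples. Returns ``None`` when the half level is not crossed on both
    sides within the beat.
    """
    seg = np.asarray(vpg[i0:i1 + 1], dtype=float)
    if seg.size < 3:
        return None
    m = int(np.argmax(seg))
    if seg[m] <= 0 or m == 0 or m == seg.size - 1:
        return None
    _, peak = _parabolic_refine(seg, m)
    half = 0.5 * peak
    below_left = np.nonzero(seg[:m] < half)[0]
    if below_left.size == 0:
        return None
    j = below_left[-1]
    xl = j + (half - seg[j]) / (seg[j + 1] - seg[j])
    below_right = np.nonzero(seg[m:] < half)[0]
    if below_right.size == 0:
        return None
    j = m + below_right[0] - 1
    xr = j + (half - seg[j]) / (seg[j + 1] - seg[j])
    width = (xr - xl) / sampling_rate
    return width if width > 0 else None


def _safe_div(num: Optional[float], den: Optional[float]) -> Optional[float]:
    if num is None or den is None or den <= 0:
        return None
    return num / den


def beat_features(fid: BeatFiducials, S: Optional[float],
                  fwhm: Optional[float]) -> BeatFeatures:
    """Assemble the per-beat feature vector from landmarks, S and FWHM.

    A missing denominator suppresses only the features that need it; the
    beat is retained for everything else.
    """
    f = BeatFeatures()
    if S is not None and S > 0:
        f.S = S
        f.inv_S = 1.0 / S
    if fwhm is not None and fwhm > 0:
        f.fwhm_vpg = fwhm
        f.inv_fwhm_vpg = 1.0 / fwhm
    a = fid.apg_a
    if a is not None and a.amplitude > 0:
        f.a = a.amplitude
        f.a_over_S = _safe_div(a.amplitude, S)
        b = fid.apg_b
        if b is not None:
            ab = b.time - a.time
            if ab > 0:
                f.ab_time = ab
                f.inv_ab_time = 1.0 / ab
            f.norm_ab = (a.amplitude - b.amplitude) / a.amplitude
        d = fid.apg_d
        if d is not None:
            f.norm_ad = (a.amplitude - d.amplitude) / a.amplitude
            f.ab_over_ad = _safe_div(f.norm_ab, f.norm_ad)
    return f


def extract_beats(derived: DerivedSignals, index: BeatIndex,
                  t0: float = 0.0) -> Tuple[List[BeatFiducials], List[BeatFeatures]]:
    """Run landmark detection and feature computation over every valid beat."""
    fids: List[BeatFiducials] = []
    feats: List[BeatFeatures] = []
    fs = derived.sampling_rate
    for i0, i1 in iter_beats(index):
        fid = detect_apg_waves(derived.apg, derived.vpg, derived.ppg,
                               i0, i1, fs, t0=t0)
        s_val, s_ok = corrected_height_S(derived.ppg, i0, i1, fs)
        if not s_ok:
            fid.invalidate("non-positive corrected height")
        width = fwhm_vpg(derived.vpg, i0, i1, fs)
        fids.append(fid)
        feats.append(beat_features(fid, s_val if s_ok else None, width)
                     if fid.valid else BeatFeatures())
    return fids, feats


def channel_delay(green_fids: Sequence[BeatFiducials],
                  nir_fids: Sequence[BeatFiducials],
                  pairing_window: float = 0.3,
                  aggregate: str = "median") -> DelaySeries:
    """Per-beat delay of the green a-wave peak behind the NIR a-wave peak.

    For each NIR a-peak the nearest green a-peak within
    ``pairing_window`` seconds is paired (ties broken toward the earlier
    green peak); the delay is ``t_green_a - t_nir_a``, positive when the
    green peak lags. Unpaired peaks are dropped. The summary is the
    configured aggregate of per-beat delays; an empty series flags the
    record.
    """
    g = [(i, f.apg_a.time) for i, f in enumerate(green_fids)
         if f.valid and f.apg_a is not None]
    n = [(i, f.apg_a.time) for i, f in enumerate(nir_fids)
         if f.valid and f.apg_a is not None]
    delays, pairs = [], []
    g_times = np.array([t for _, t in g]) if g else np.empty(0)
    for ni, nt in n:
        if g_times.size == 0:
            break
        diff = np.abs(g_times - nt)
        j = int(np.argmin(diff))
        # tie toward the earlier green peak
        if j > 0 and diff[j - 1] == diff[j]:
            j -= 1
        if diff[j] <= pairing_window:
            delays.append(g_times[j] - nt)
            pairs.append((ni, g[j][0]))
    delays = np.asarray(delays, dtype=float)
    if delays.size == 0:
        return DelaySeries(delays=delays, pairs=pairs, summary=None,
                           aggregate=aggregate, flagged=True)
    agg = np.median if aggregate == "median" else np.mean
    return DelaySeries(delays=delays, pairs=pairs,
                       summary=float(agg(delays)), aggregate=aggregate)


def aggregate_record(feats: Sequence[BeatFeatures],
                     delays: Optional[DelaySeries] = None,
                     aggregate: str = "median") -> Dict[str, Optional[float]]:
    """Record-level feature vector: aggregate of per-beat values.

    The median (default) resists occasional outlier beats; the mean is
    available via configuration. Beats missing a feature simply do not
    contribute to it; per-feature counts are not part of the row but the
    total valid beat count is.
    """
    agg = np.median if aggregate == "median" else np.mean
    out: Dict[str, Optional[float]] = {}
    n_valid = 0
    any_valid = False
    for col in FEATURE_COLUMNS:
        vals = [getattr(f, col) for f in feats if getattr(f, col) is not None]
        out[col] = float(agg(vals)) if vals else None
    n_valid = sum(1 for f in feats if f.S is not None or f.a is not None)
    any_valid = n_valid > 0
    out["delay_green_nir"] = (delays.summary if delays is not None else None)
    out["n_beats"] = n_valid
    out["_any_valid"] = any_valid
    return out
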