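"""From raw PPG to velocity/acceleration plethysmograms and beats.

The processing chain follows standard pulse-wave practice: band-pass the
raw trace to the pulsatile band, differentiate once (with a short
centered moving average) to obtain the velocity plethysmogram (VPG),
differentiate again to obtain the acceleration plethysmogram (APG), and
split the trace into beats at the PPG minima that precede each systolic
upstroke.

All steps are strictly time-symmetric (zero-phase filtering, central
differences, centered smoothing), so applying the same chain to two
channels preserves any inter-channel time shift — a prerequisite for
measuring sub-10-ms a-wave delays between wavelengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Tuple

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .config import FilterSpec
from .errors import ConfigurationError
from .records import WaveformRecord

__all__ = [
    "DerivedSignals", "BeatIndex", "bandpass_filter", "differentiate_smooth",
    "derive", "segment_beats", "dc_component", "iter_beats",
    "parabolic_refine",
]


@dataclass
class DerivedSignals:
    """Filtered PPG and its first two smoothed derivatives."""

    ppg: np.ndarray
    vpg: np.ndarray
    apg: np.ndarray
    sampling_rate: float
    smoothing_window: float


@dataclass
class BeatIndex:
    """Beat boundaries: sample indices of the PPG minima delimiting beats.

    ``anchors`` are the sub-sample (parabola-refined) positions of the
    systolic-upstroke VPG maxima used to locate the boundaries; they are
    far sharper landmarks than the flat minima and are reused by the
    noise estimator for precise beat alignment. ``flagged`` is set when
    fewer than two beats could be found; this is data (the record will
    fail QC), not an exception.
    """

    boundaries: np.ndarray
    sampling_rate: float
    hr_bounds: Tuple[float, float] = (30.0, 180.0)
    flagged: bool = False
    anchors: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.anchors is None:
            self.anchors = np.empty(0)

    @property
    def beat_count(self) -> int:
        return sum(1 for _ in iter_beats(self))


def iter_beats(index: BeatIndex) -> Iterator[Tuple[int, int]]:
    """Yield (start, end) sample indices of beats whose duration is
    physiologically plausible under ``index.hr_bounds``."""
    lo_bpm, hi_bpm = index.hr_bounds
    min_len = 60.0 / hi_bpm * index.sampling_rate
    max_len = 60.0 / lo_bpm * index.sampling_rate
    b = index.boundaries
    for i0, i1 in zip(b[:-1], b[1:]):
        if min_len <= (i1 - i0) <= max_len:
            yield int(i0), int(i1)


def parabolic_refine(y: np.ndarray, i: int) -> Tuple[float, float]:
    """Sub-sample extremum position via a 3-point parabola around index i.

    Returns (fractional index, refined amplitude). Falls back to the
    sample itself at array edges or for degenerate curvature.
    """
    if i <= 0 or i >= y.size - 1:
        return float(i), float(y[i])
    y0, y1, y2 = float(y[i - 1]), float(y[i]), float(y[i + 1])
    denom = y0 - 2.0 * y1 + y2
    if denom == 0.0:
        return float(i), y1
    delta = 0.5 * (y0 - y2) / denom
    if not -1.0 < delta < 1.0:
        return float(i), y1
    amp = y1 - 0.25 * (y0 - y2) * delta
    return i + delta, amp


def bandpass_filter(record: WaveformRecord, spec: FilterSpec | None = None) -> WaveformRecord:
    """Band-pass every channel of a record with identical coefficients.

    Zero-phase (forward-backward) application guarantees that the filter
    contributes no inter-channel timing bias; because all channels share
    the same coefficients, any residual amplitude effect cancels in
    timing comparisons.
    """
    spec = spec or FilterSpec()
    spec.validate(record.sampling_rate)
    sos = sps.butter(spec.order, (spec.low_cut, spec.high_cut),
                     btype="bandpass", fs=record.sampling_rate, output="sos")
    out = {}
    for name, x in record.channels.items():
        if spec.zero_phase:
            out[name] = sps.sosfiltfilt(sos, x)
        else:
            out[name] = sps.sosfilt(sos, x)
    return record.with_channels(out)


def highpass_detrend(x: np.ndarray, sampling_rate: float,
                     cutoff: float = 0.5, order: int = 2) -> np.ndarray:
    """Zero-phase high-pass used to detrend a raw channel before noise
    estimation: removes offset and baseline drift while keeping the full
    RMS of broadband noise (unlike the analysis band-pass)."""
    sos = sps.butter(order, cutoff, btype="highpass",
                     fs=sampling_rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def _smooth(x: np.ndarray, n: int) -> np.ndarray:
    # centered moving average, odd length, reflect-padded edges
    return uniform_filter1d(x, size=n, mode="reflect")


def _window_samples(window: float, sampling_rate: float, n_signal: int) -> int:
    n = int(round(window * sampling_rate))
    n = max(n, 1)
    if n % 2 == 0:
        n += 1
    if n > n_signal:
        raise ConfigurationError(
            f"smoothing window of {n} samples exceeds signal length {n_signal}")
    return n


def differentiate_smooth(x: np.ndarray, sampling_rate: float,
                         window: float = 0.05) -> np.ndarray:
    """Central-difference derivative followed by a centered moving average.

    Parameters
    ----------
    x
        Input samples.
    sampling_rate
        Hz; the derivative is returned in input-units per second.
    window
        Moving-average length in seconds (rounded to an odd number of
        samples, minimum 1). Output length equals input length; edges use
        one-sided differences and reflect padding.
    """
    x = np.asarray(x, dtype=float)
    n = _window_samples(window, sampling_rate, x.size)
    if x.size < 2:
        raise ConfigurationError("signal too short to differentiate")
    d = np.gradient(x, 1.0 / sampling_rate)
    return _smooth(d, n)


def derive(ppg: np.ndarray, sampling_rate: float,
           smoothing_window: float = 0.05) -> DerivedSignals:
    """Compute VPG and APG from a filtered PPG channel."""
    vpg = differentiate_smooth(ppg, sampling_rate, smoothing_window)
    apg = differentiate_smooth(vpg, sampling_rate, smoothing_window)
    return DerivedSignals(ppg=np.asarray(ppg, dtype=float), vpg=vpg, apg=apg,
                          sampling_rate=sampling_rate,
                          smoothing_window=smoothing_window)


def segment_beats(derived: DerivedSignals, sampling_rate: float | None = None,
                  hr_bounds: Tuple[float, float] = (30.0, 180.0),
                  refractory: float = 0.3) -> BeatIndex:
    """Divide a record into beats at PPG minima.

    Systolic upstrokes are the robust anchor: they appear as dominant VPG
    maxima. Each beat boundary is then the PPG minimum between two
    consecutive upstrokes (plus a leading/trailing minimum found within
    ~60% of the typical beat period of the first/last upstroke).
    Implausible inter-boundary spacings are rejected downstream via
    ``hr_bounds``.
    """
    fs = sampling_rate or derived.sampling_rate
    ppg, vpg = derived.ppg, derived.vpg
    empty = BeatIndex(boundaries=np.empty(0, dtype=int), sampling_rate=fs,
                      hr_bounds=hr_bounds, flagged=True)
    if ppg.size < fs:  # under a second of data
        return empty
    scale = float(np.max(np.abs(ppg))) if ppg.size else 0.0
    top = float(np.percentile(vpg, 98))
    if top <= 0 or np.max(vpg) < 1e-9 * max(scale, 1e-300):
        return empty  # no upstrokes (flat or non-pulsatile input)
    distance = max(int(round(refractory * fs)), 1)
    peaks, _ = sps.find_peaks(vpg, height=0.5 * top, distance=distance)
    if peaks.size < 2:
        return empty
    med_gap = int(np.median(np.diff(peaks)))
    # second pass with an adaptive refractory period: for slow-rising
    # pulses the diastolic shoulder can clear the amplitude threshold,
    # but never at more than ~half the typical beat spacing
    distance2 = max(distance, int(0.6 * med_gap))
    if distance2 > distance:
        peaks, _ = sps.find_peaks(vpg, height=0.5 * top, distance=distance2)
        if peaks.size < 2:
            return empty
        med_gap = int(np.median(np.diff(peaks)))
    # search backward from each upstroke for the preceding PPG minimum;
    # a window much shorter than the beat period avoids the band-pass
    # undershoot that follows the previous systolic peak
    back = max(int(0.45 * med_gap), 2)
    boundaries = []
    for k, p in enumerate(peaks):
        if k == 0:
            if p - back < 0:
                continue  # no full pre-onset window before the first rise
            lo = p - back
        else:
            lo = max(peaks[k - 1], p - back)
        if lo < p:
            boundaries.append(lo + int(np.argmin(ppg[lo:p + 1])))
    # trailing boundary: the minimum preceding where the next upstroke
    # would fall, so the last complete beat is closed
    nxt = peaks[-1] + med_gap
    lo, hi = nxt - back, min(ppg.size, nxt + int(0.1 * med_gap))
    if hi - lo > 3 and lo > peaks[-1]:
        boundaries.append(lo + int(np.argmin(ppg[lo:hi])))
    boundaries = np.unique(np.asarray(boundaries, dtype=int))
    anchors = np.array([parabolic_refine(vpg, int(p))[0] for p in peaks])
    index = BeatIndex(boundaries=boundaries, sampling_rate=fs,
                      hr_bounds=hr_bounds, flagged=False, anchors=anchors)
    if index.beat_count < 2:
        index.flagged = True
    return index


def dc_component(raw_channel: np.ndarray, sampling_rate: float,
                 window: float = 2.0) -> np.ndarray:
    """Slowly varying baseline of the *unfiltered* channel.

    A centered moving average over ``window`` seconds. The DC trace rises
    when pulsatile light absorption falls (e.g. when external pressure
    squeezes blood out of the tissue under the sensor).
    """
    x = np.asarray(raw_channel, dtype=float)
    n = _window_samples(window, sampling_rate, x.size)
    return _smooth(x, n)
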