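"""Processing configuration.

Every tunable parameter of the pipeline lives in :class:`PipelineConfig`
and can be loaded from / dumped to a YAML file, so a run is fully
described by (inputs, config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Tuple

import yaml

from .errors import ConfigurationError


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass filter design for the pulsatile PPG band.

    The defaults (0.5–20 Hz) bracket the cardiac fundamental and the
    harmonics that shape the acceleration plethysmogram, while rejecting
    baseline wander and high-frequency noise. The filter is a Butterworth
    band-pass applied forward-backward (zero phase) so that inter-channel
    timing is never biased by filter phase.
    """

    low_cut: float = 0.5
    high_cut: float = 20.0
    order: int = 2
    zero_phase: bool = True

    def validate(self, sampling_rate: float) -> None:
        if not 0 < self.low_cut < self.high_cut:
            raise ConfigurationError(
                f"need 0 < low_cut < high_cut, got "
                f"low_cut={self.low_cut}, high_cut={self.high_cut}")
        if self.high_cut >= sampling_rate / 2:
            raise ConfigurationError(
                f"high_cut={self.high_cut} Hz must be below the Nyquist "
                f"frequency {sampling_rate / 2} Hz (sampling_rate="
                f"{sampling_rate} Hz)")
        if self.order < 1:
            raise ConfigurationError(f"order must be >= 1, got {self.order}")


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline parameters with their defaults.

    Attributes
    ----------
    smoothing_window
        Centered moving-average window (s) applied after each numerical
        differentiation.
    hr_bounds
        Plausible heart-rate range (bpm); beat intervals outside it are
        discarded.
    refractory
        Minimum spacing (s) between detected systolic upstrokes.
    pairing_window
        Maximum |green - nir| a-wave time difference (s) accepted when
        pairing beats across channels.
    aggregate
        Per-record aggregation of beat-level features: "median" or "mean".
    snr_threshold
        Records with SNR below this on any QC channel are excluded.
    qc_channels
        Channels whose SNR participates in exclusion.
    feature_channel
        Channel on which morphology features are computed.
    dc_window
        Moving-average window (s) for the DC-component trace.
    """

    filter: FilterSpec = field(default_factory=FilterSpec)
    smoothing_window: float = 0.05
    hr_bounds: Tuple[float, float] = (30.0, 180.0)
    refractory: float = 0.3
    pairing_window: float = 0.3
    aggregate: str = "median"
    snr_threshold: float = 200.0
    qc_channels: Tuple[str, ...] = ("green", "nir")
    feature_channel: str = "green"
    dc_window: float = 2.0
    seed: Optional[int] = None

    def validate(self) -> None:
        lo, hi = self.hr_bounds
        if not 0 < lo < hi:
            raise ConfigurationError(f"invalid hr_bounds {self.hr_bounds}")
        if self.smoothing_window <= 0:
            raise ConfigurationError("smoothing_window must be positive")
        if self.pairing_window <= 0:
            raise ConfigurationError("pairing_window must be positive")
        if self.aggregate not in ("median", "mean"):
            raise ConfigurationError(
                f"aggregate must be 'median' or 'mean', got {self.aggregate!r}")
        if self.snr_threshold < 0:
            raise ConfigurationError("snr_threshold must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "filter" in d and isinstance(d["filter"], dict):
            d["filter"] = FilterSpec(**d["filter"])
        if "hr_bounds" in d:
            d["hr_bounds"] = tuple(d["hr_bounds"])
        if "qc_channels" in d:
            d["qc_channels"] = tuple(d["qc_channels"])
        try:
            cfg = cls(**d)
        except TypeError as exc:
            raise ConfigurationError(f"bad config: {exc}") from exc
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        try:
            data = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"cannot parse config {path}: {exc}")
        if not isinstance(data, dict):
            raise ConfigurationError(f"config {path} is not a mapping")
        return cls.from_dict(data)
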