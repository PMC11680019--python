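"""Waveform containers.

A :class:`WaveformRecord` is the unit of acquisition: one multi-channel
photoplethysmogram (PPG) trace sampled uniformly, with per-record metadata
(subject, group, posture, cooling state, wrist systolic blood pressure).
Channel names follow the LED wavelengths of the measuring device:
``green`` (~525 nm), ``red`` (~660 nm), ``nir`` (~940 nm).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np

from .errors import ConfigurationError

KNOWN_CHANNELS = ("green", "red", "nir")
GROUPS = ("diabetes", "control", "unknown")
POSTURES = ("navel", "chest", "forehead", "other")


@dataclass
class RecordMetadata:
    """Per-record descriptive metadata.

    ``wrist_sbp`` is the wrist-cuff systolic blood pressure in mmHg, or
    ``None`` when the cuff measurement failed (a QC exclusion reason).
    """

    subject_id: str = "unknown"
    group: str = "unknown"
    posture: str = "other"
    cooled: bool = False
    wrist_sbp: Optional[float] = None
    record_id: str = "unknown"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConfigurationError(
                f"group must be one of {GROUPS}, got {self.group!r}")
        if self.posture not in POSTURES:
            raise ConfigurationError(
                f"posture must be one of {POSTURES}, got {self.posture!r}")


@dataclass
class WaveformRecord:
    """Multi-channel PPG trace with uniform sampling.

    Parameters
    ----------
    channels
        Mapping channel name -> 1-D sample array (arbitrary intensity
        units). All arrays must have equal length of at least two seconds
        of samples.
    sampling_rate
        Sampling frequency in Hz.
    t0
        Time of the first sample in seconds.
    metadata
        Per-record metadata; defaults to an anonymous record.
    """

    channels: Dict[str, np.ndarray]
    sampling_rate: float
    t0: float = 0.0
    metadata: RecordMetadata = field(default_factory=RecordMetadata)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if not self.channels:
            raise ConfigurationError("record has no channels")
        lengths = set()
        for name, arr in list(self.channels.items()):
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 1:
                raise ConfigurationError(f"channel {name!r} is not 1-D")
            self.channels[name] = arr
            lengths.add(arr.size)
        if len(lengths) != 1:
            raise ConfigurationError("channel arrays have unequal lengths")
        n = lengths.pop()
        if n < 2 * self.sampling_rate:
            raise ConfigurationError(
                f"record too short: {n} samples < 2 s at "
                f"{self.sampling_rate} Hz")

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate

    def with_channels(self, channels: Dict[str, np.ndarray]) -> "WaveformRecord":
        """Copy of this record with the given channel arrays."""
        return replace(self, channels=dict(channels))
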