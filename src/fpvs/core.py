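"""Core data containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

__all__ = ["RawRecording", "Segment", "Epoch", "AmplitudeSpectrum"]


@dataclass
class RawRecording:
    """Continuous multichannel EEG in microvolts with event markers."""

    data: np.ndarray          # (n_channels, n_samples), μV
    rate_hz: float
    channel_names: list[str]
    events: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("channel_names length must match data rows")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def copy_with(self, **kw: Any) -> "RawRecording":
        return replace(self, **kw)


@dataclass
class Segment:
    """One cropped stimulation sequence (channels x samples, μV)."""

    data: np.ndarray
    rate_hz: float
    channel_names: list[str]
    condition_label: str = ""
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("channel_names length must match data rows")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def copy_with(self, **kw: Any) -> "Segment":
        return replace(self, **kw)


@dataclass
class Epoch:
    """Analysis epoch spanning an exact integer number of oddball cycles."""

    data: np.ndarray
    rate_hz: float
    channel_names: list[str]
    duration_s: float
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = int(round(self.duration_s * self.rate_hz))
        if self.data.shape[1] != n:
            raise ValueError(
                f"epoch has {self.data.shape[1]} samples, expected "
                f"{n} = duration_s * rate_hz"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class AmplitudeSpectrum:
    """Single-sided amplitude spectrum, channels x frequency bins (μV).

    ``kind`` distinguishes raw, baseline-corrected and Z-scored variants.
    """

    amplitudes: np.ndarray    # (n_channels, n_bins)
    bin_width_hz: float
    rate_hz: float
    channel_names: list[str]
    kind: str = "raw"
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.ndim != 2:
            raise ValueError("amplitudes must be channels x bins")
        if self.kind == "raw" and np.any(self.amplitudes < 0):
            raise ValueError("raw amplitudes must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def n_bins(self) -> int:
        return self.amplitudes.shape[1]

    @property
    def freqs_hz(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_width_hz

    def bin_of(self, freq_hz: float) -> int:
        """Index of the bin whose center is closest to ``freq_hz``."""
        b = int(round(freq_hz / self.bin_width_hz))
        if not 0 <= b < self.n_bins:
            raise ValueError(f"{freq_hz} Hz outside spectrum range")
        if abs(b * self.bin_width_hz - freq_hz) > self.bin_width_hz / 2 + 1e-9:
            raise ValueError(f"{freq_hz} Hz does not fall near a bin center")
        return b

    def channel_average(self, channels: list[str] | None = None) -> "AmplitudeSpectrum":
        """Average amplitudes over channels (all by default) into a
        one-channel spectrum labeled ``"avg"``."""
        if channels is None:
            sub = self.amplitudes
        else:
            idx = [self.channel_names.index(c) for c in channels]
            sub = self.amplitudes[idx]
        return AmplitudeSpectrum(
            sub.mean(axis=0, keepdims=True),
            self.bin_width_hz,
            self.rate_hz,
            ["avg"],
            kind=self.kind,
            condition_label=self.condition_label,
        )
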