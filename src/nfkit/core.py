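"""Shared containers and error types for the neurofeedback pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np

from nfkit import config


class NfkitError(Exception):
    """Base class for pipeline errors."""


class ParameterError(NfkitError, ValueError):
    """Invalid parameter or malformed input."""


class ConfigurationError(NfkitError):
    """Recording/configuration mismatch (e.g. a required channel is absent)."""


class CalibrationError(NfkitError):
    """Baseline calibration impossible (too few frames, degenerate range)."""


class UndefinedEpochError(NfkitError):
    """An epoch contains no valid frames; the quantity is undefined, not zero."""


@dataclass
class EegRecording:
    """Uniformly sampled multi-channel EEG (µV) with optional accelerometer trace.

    ``samples`` is a (n_channels, n_samples) float array in microvolts;
    ``accel`` is a (3, n_samples) array in g (x, y, z) or ``None``.
    """

    sample_rate: float
    channel_labels: Tuple[str, ...]
    samples: np.ndarray
    accel: np.ndarray | None = None
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ParameterError("samples must be a (channels, time) matrix")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ParameterError("channel_labels length must match samples rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ParameterError("channel labels must be unique")
        if self.sample_rate <= 0:
            raise ParameterError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("samples must be finite")
        if self.accel is not None:
            self.accel = np.asarray(self.accel, dtype=float)
            if self.accel.shape != (3, self.samples.shape[1]):
                raise ParameterError("accel must be (3, n_samples)")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sample_rate

    @property
    def accel_magnitude(self) -> np.ndarray:
        if self.accel is None:
            raise ConfigurationError("recording carries no accelerometer trace")
        return np.linalg.norm(self.accel, axis=0)

    def channel(self, label: str) -> np.ndarray:
        try:
            i = self.channel_labels.index(label)
        except ValueError:
            raise ParameterError(f"unknown channel label {label!r}") from None
        return self.samples[i]

    def frontal_indices(self, frontal: Sequence[str] = config.FRONTAL_CHANNELS) -> list[int]:
        missing = [ch for ch in frontal if ch not in self.channel_labels]
        if missing:
            raise ConfigurationError(f"missing frontal channel(s): {', '.join(missing)}")
        return [self.channel_labels.index(ch) for ch in frontal]

    def copy(self) -> "EegRecording":
        return EegRecording(
            sample_rate=self.sample_rate,
            channel_labels=self.channel_labels,
            samples=self.samples.copy(),
            accel=None if self.accel is None else self.accel.copy(),
            start_time=self.start_time,
        )


@dataclass
class BandDefinition:
    """Frequency bands of the attention index and the analysis passband (Hz)."""

    theta: Tuple[float, float] = config.THETA_BAND
    alpha: Tuple[float, float] = config.ALPHA_BAND
    beta: Tuple[float, float] = config.BETA_BAND
    passband: Tuple[float, float] = config.ANALYSIS_PASSBAND
    notch_hz: float = config.NOTCH_HZ

    def __post_init__(self) -> None:
        lo, hi = self.passband
        for name in ("theta", "alpha", "beta"):
            b = getattr(self, name)
            if not (lo <= b[0] < b[1] <= hi):
                raise ParameterError(f"{name} band {b} outside passband {self.passband}")
        ordered = [self.theta, self.alpha, self.beta]
        for (a0, a1), (b0, b1) in zip(ordered, ordered[1:]):
            if a1 >= b0:
                raise ParameterError("bands must be non-overlapping and ordered")

    @property
    def bands(self) -> dict[str, Tuple[float, float]]:
        return {"theta": self.theta, "alpha": self.alpha, "beta": self.beta}


@dataclass
class AttentionSeries:
    """4 Hz stream of raw beta/(alpha+theta) ratios and 0-100 indices.

    ``excluded`` marks frames overlapping artifact-gated seconds or frames
    whose ratio is undefined; their ``index`` is NaN and they never enter
    downstream means.
    """

    timestamps: np.ndarray
    raw_ratio: np.ndarray
    index: np.ndarray
    excluded: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.raw_ratio = np.asarray(self.raw_ratio, dtype=float)
        self.index = np.asarray(self.index, dtype=float)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        n = len(self.timestamps)
        if not (len(self.raw_ratio) == len(self.index) == len(self.excluded) == n):
            raise ParameterError("series arrays must have equal length")
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ParameterError("timestamps must be strictly increasing")
        valid = ~self.excluded & np.isfinite(self.index)
        if np.any(self.index[valid] < -1e-9) or np.any(self.index[valid] > 100 + 1e-9):
            raise ParameterError("index out of [0, 100] on a non-excluded frame")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def valid(self) -> np.ndarray:
        return ~self.excluded & np.isfinite(self.index)

    def valid_indices(self) -> np.ndarray:
        return self.index[self.valid]

    def replace(self, **kwargs) -> "AttentionSeries":
        data = {
            "timestamps": self.timestamps,
            "raw_ratio": self.raw_ratio,
            "index": self.index,
            "excluded": self.excluded,
        }
        data.update(kwargs)
        return AttentionSeries(**{k: np.array(v, copy=True) for k, v in data.items()})


@dataclass
class BaselineProfile:
    """Individual baseline normalization anchors for the attention index.

    Ratios at ``ratio_low_anchor`` map to index 0, at ``ratio_high_anchor`` to
    100 (linear in between, clipped outside).  ``eyes_open_mean_index`` is the
    normalized mean ratio of the eyes-open fixation segment and seeds the
    feedback threshold.
    """

    ratio_low_anchor: float
    ratio_high_anchor: float
    eyes_open_mean_index: float

    def __post_init__(self) -> None:
        if not self.ratio_low_anchor < self.ratio_high_anchor:
            raise CalibrationError("degenerate baseline range: low anchor must be < high anchor")
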