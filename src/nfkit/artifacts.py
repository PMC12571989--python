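"""Artifact gating: motion (accelerometer) and high-amplitude exclusion rules.

Two rules operate on 1-s epochs aligned to the recording start (epoch k is the
half-open interval [k, k+1) s):

* motion — the acceleration-vector magnitude deviates by more than 0.5 g from
  baseline for a run exceeding 500 ms; every epoch the run intersects is
  flagged;
* amplitude — any frontal-channel sample (Fp1, Fp2, F3, F4) exceeds ±100 µV
  within the epoch.

All three thresholds are strict inequalities: exactly 0.5 g, exactly 500 ms,
or exactly ±100 µV does not flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from nfkit import config
from nfkit.core import EegRecording, ParameterError

REASON_NONE = ""
REASON_MOTION = "motion"
REASON_AMPLITUDE = "amplitude"
REASON_BOTH = "both"


@dataclass
class ExclusionMask:
    """Per-epoch exclusion flags with reason codes."""

    flagged: np.ndarray
    reasons: np.ndarray
    epoch_length: float = config.GATE_EPOCH_S

    def __post_init__(self) -> None:
        self.flagged = np.asarray(self.flagged, dtype=bool)
        self.reasons = np.asarray(self.reasons, dtype=object)
        if self.flagged.shape != self.reasons.shape:
            raise ParameterError("flags and reasons must have equal length")

    @classmethod
    def empty(cls, n_epochs: int, epoch_length: float = config.GATE_EPOCH_S) -> "ExclusionMask":
        return cls(
            flagged=np.zeros(n_epochs, dtype=bool),
            reasons=np.array([REASON_NONE] * n_epochs, dtype=object),
            epoch_length=epoch_length,
        )

    @property
    def n_epochs(self) -> int:
        return len(self.flagged)

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())


def _n_epochs(n_samples: int, sample_rate: float, epoch_length: float) -> int:
    return int(np.ceil(n_samples / sample_rate / epoch_length))


def accel_baseline(
    magnitude: np.ndarray,
    sample_rate: float,
    window_s: float = config.ACCEL_BASELINE_WINDOW_S,
) -> float:
    """Baseline acceleration magnitude: median of the first 10 s (or whole trace)."""
    mag = np.asarray(magnitude, dtype=float)
    if mag.size < 5 * sample_rate:
        raise ParameterError("need at least 5 s of accelerometer data for a baseline")
    n = min(mag.size, int(round(window_s * sample_rate)))
    return float(np.median(mag[:n]))


def flag_motion(
    magnitude: np.ndarray,
    baseline: float,
    sample_rate: float,
    threshold_g: float = config.MOTION_THRESHOLD_G,
    min_duration_s: float = config.MOTION_MIN_DURATION_S,
    epoch_length: float = config.GATE_EPOCH_S,
) -> ExclusionMask:
    """Flag epochs intersected by motion runs (> threshold for > min duration)."""
    if baseline <= 0:
        raise ParameterError("baseline must be positive")
    mag = np.asarray(magnitude, dtype=float)
    mask = ExclusionMask.empty(_n_epochs(mag.size, sample_rate, epoch_length), epoch_length)
    dev = np.abs(mag - baseline) > threshold_g
    if not dev.any():
        return mask
    edges = np.flatnonzero(np.diff(np.concatenate(([False], dev, [False])).astype(int)))
    for start, stop in edges.reshape(-1, 2):  # run covers samples [start, stop)
        if (stop - start) / sample_rate > min_duration_s:
            e0 = int(start / sample_rate / epoch_length)
            e1 = int((stop - 1) / sample_rate / epoch_length)
            mask.flagged[e0 : e1 + 1] = True
            mask.reasons[e0 : e1 + 1] = REASON_MOTION
    return mask


def flag_amplitude(
    rec: EegRecording,
    threshold_uv: float = config.AMPLITUDE_THRESHOLD_UV,
    epoch_length: float = config.GATE_EPOCH_S,
    frontal: Sequence[str] = config.FRONTAL_CHANNELS,
) -> ExclusionMask:
    """Flag epochs where any frontal-channel sample exceeds ±threshold µV."""
    idx = rec.frontal_indices(frontal)
    n_ep = _n_epochs(rec.n_samples, rec.sample_rate, epoch_length)
    mask = ExclusionMask.empty(n_ep, epoch_length)
    hot = np.any(np.abs(rec.samples[idx]) > threshold_uv, axis=0)
    if not hot.any():
        return mask
    per_sample_epoch = (np.arange(rec.n_samples) / rec.sample_rate / epoch_length).astype(int)
    for e in np.unique(per_sample_epoch[hot]):
        mask.flagged[e] = True
        mask.reasons[e] = REASON_AMPLITUDE
    return mask


def combine(masks: Sequence[ExclusionMask]) -> ExclusionMask:
    """Logical OR of masks; reason codes merge to 'both' where they differ."""
    if not masks:
        raise ParameterError("need at least one mask")
    n = masks[0].n_epochs
    if any(m.n_epochs != n for m in masks):
        raise ParameterError("masks cover different epoch counts")
    out = ExclusionMask.empty(n, masks[0].epoch_length)
    for m in masks:
        for e in np.flatnonzero(m.flagged):
            if not out.flagged[e]:
                out.flagged[e] = True
                out.reasons[e] = m.reasons[e]
            elif out.reasons[e] != m.reasons[e]:
                out.reasons[e] = REASON_BOTH
    return out


def build_mask(rec: EegRecording) -> ExclusionMask:
    """Convenience: accelerometer-motion OR amplitude mask for one recording."""
    amp = flag_amplitude(rec)
    if rec.accel is None:
        return amp
    mag = rec.accel_magnitude
    base = accel_baseline(mag, rec.sample_rate)
    return combine([flag_motion(mag, base, rec.sample_rate), amp])
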