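"""Feedback classification and the Day-1 adaptive-threshold algorithm.

Every 30 s epoch the controller compares the mean attention index of the
epoch's valid frames against the current threshold.  Three consecutive
above-threshold epochs raise the threshold by 5%; three consecutive
below-threshold epochs lower it by 5% (frustration guard).  Counters reset
after each triggered adjustment, a mean exactly at threshold resets both
counters, and a break between training blocks interrupts the "consecutive"
run.  Fully excluded epochs are skipped without resetting counters.

The feedback bar color partitions the index range relative to the threshold T:
red below 0.9 T, yellow within ±10% of T, green above 1.1 T.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Tuple

import numpy as np

from nfkit import config
from nfkit.core import AttentionSeries, BaselineProfile, ParameterError, UndefinedEpochError


@dataclass
class ThresholdState:
    """Current threshold plus the consecutive-epoch run counters."""

    threshold: float
    above_run: int = 0
    below_run: int = 0
    history: List[Tuple[int, float, float]] = field(default_factory=list)
    n_increases: int = 0
    n_decreases: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= config.THRESHOLD_CAP:
            raise ParameterError("threshold must be in (0, 100]")
        if self.above_run < 0 or self.below_run < 0:
            raise ParameterError("run counters must be non-negative")
        if self.above_run and self.below_run:
            raise ParameterError("at most one run counter may be nonzero")

    def reset_runs(self) -> None:
        """A break (or a triggered adjustment) interrupts the consecutive run."""
        self.above_run = 0
        self.below_run = 0


class FeedbackColor:
    RED = "red"
    YELLOW = "yellow"
    GREEN = "green"


def initial_threshold(profile: BaselineProfile) -> float:
    """Initial threshold = mean attention index of the eyes-open fixation segment."""
    v = profile.eyes_open_mean_index
    if not np.isfinite(v):
        raise ParameterError("profile is not calibrated (eyes-open mean undefined)")
    if v <= 0:
        raise ParameterError("eyes-open mean index must be positive to seed the threshold")
    return float(v)


def epoch_mean(
    series: AttentionSeries,
    epoch_start: float,
    epoch_length: float = config.CONTROLLER_EPOCH_S,
) -> float:
    """Mean index over the epoch's non-excluded frames; undefined if none.

    Frames are stamped at their buffer's end, so the epoch starting at t₀
    owns frames with t₀ < t ≤ t₀ + 30 s.
    """
    t = series.timestamps
    sel = (t > epoch_start) & (t <= epoch_start + epoch_length) & series.valid
    if not sel.any():
        raise UndefinedEpochError(
            f"no valid frames in epoch [{epoch_start}, {epoch_start + epoch_length}) s"
        )
    return float(series.index[sel].mean())


def update_threshold(
    state: ThresholdState,
    mean: float,
    run_length: int = config.CONTROLLER_RUN_LENGTH,
    step_pct: float = config.CONTROLLER_STEP_PCT,
    cap: float = config.THRESHOLD_CAP,
) -> ThresholdState:
    """Apply one epoch mean to the adaptive rule; mutates and returns ``state``."""
    step = step_pct / 100.0
    if mean > state.threshold:
        state.above_run += 1
        state.below_run = 0
        if state.above_run >= run_length:
            state.threshold = min(state.threshold * (1.0 + step), cap)
            state.n_increases += 1
            state.reset_runs()
    elif mean < state.threshold:
        state.below_run += 1
        state.above_run = 0
        if state.below_run >= run_length:
            state.threshold = state.threshold * (1.0 - step)
            state.n_decreases += 1
            state.reset_runs()
    else:
        state.reset_runs()
    state.history.append((len(state.history), float(mean), state.threshold))
    return state


def feedback_color(
    index: float,
    threshold: float,
    band_pct: float = config.FEEDBACK_BAND_PCT,
    mode: str = "relative",
) -> str:
    """Map one index frame to the red/yellow/green bar color.

    ``relative`` (default) reads the ±10% yellow band as a fraction of the
    threshold; ``absolute`` reads it as ±10 index points.
    """
    if threshold <= 0:
        raise ParameterError("threshold must be positive")
    if mode == "relative":
        lo = threshold * (1.0 - band_pct / 100.0)
        hi = threshold * (1.0 + band_pct / 100.0)
    elif mode == "absolute":
        lo = threshold - band_pct
        hi = threshold + band_pct
    else:
        raise ParameterError(f"unknown band mode {mode!r}")
    if index > hi:
        return FeedbackColor.GREEN
    if index < lo:
        return FeedbackColor.RED
    return FeedbackColor.YELLOW


def run_training_session(
    learner: Callable[[np.random.Generator, int], np.ndarray],
    initial: float,
    seed: int | None = None,
    n_blocks: int = 3,
    block_s: float = 300.0,
    epoch_s: float = config.CONTROLLER_EPOCH_S,
    frame_rate: float = config.UPDATE_RATE_HZ,
    run_length: int = config.CONTROLLER_RUN_LENGTH,
    step_pct: float = config.CONTROLLER_STEP_PCT,
) -> ThresholdState:
    """Simulate a training session (default: three 5-min blocks, 1-min breaks).

    ``learner(rng, n_frames)`` returns the 4 Hz index stream of one block; NaN
    frames count as excluded.  Breaks neither advance the epoch clock nor
    carry run counters across blocks.
    """
    state = ThresholdState(threshold=float(initial))
    rng = np.random.default_rng(seed)
    frames_per_epoch = int(round(epoch_s * frame_rate))
    epochs_per_block = int(block_s // epoch_s)
    for _ in range(n_blocks):
        stream = np.asarray(learner(rng, frames_per_epoch * epochs_per_block), dtype=float)
        if stream.size < frames_per_epoch * epochs_per_block:
            raise ParameterError("learner produced too few frames for the block")
        for e in range(epochs_per_block):
            chunk = stream[e * frames_per_epoch : (e + 1) * frames_per_epoch]
            valid = chunk[np.isfinite(chunk)]
            if valid.size == 0:
                continue  # fully excluded epoch: skipped, counters untouched
            update_threshold(state, float(valid.mean()), run_length=run_length, step_pct=step_pct)
        state.reset_runs()  # 1-min break interrupts the consecutive-epoch run
    return state
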