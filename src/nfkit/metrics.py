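"""Derived attention, behavioral, and questionnaire outcome measures.

Attention streams are winsorized at mean ± 2 SD, smoothed with a 5-s sliding
average, then summarized as mean focus level and stability (coefficient of
variation).  Behavioral measures cover the semantic-interference task (mean
RTs over correct trials, accuracy, FI−FU and FP−FU interference effects) and
the comprehension test (total = mean of three subscales); subjective workload
follows the raw-TLX convention (unweighted mean of six 0-100 subscales).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import numpy as np
import pandas as pd

from nfkit import config
from nfkit.core import AttentionSeries, ParameterError

TRIAL_TYPES = ("TC", "FI", "FU", "FP")


@dataclass
class AttentionSummary:
    condition: str
    mean_index: float
    cv_pct: float


@dataclass
class InterferenceEffects:
    delta_fi: float  # FI_RT − FU_RT, ms
    delta_fp: float  # FP_RT − FU_RT, ms
    acc_fi: float | None = None  # % correct on false-incongruent trials


@dataclass
class ComprehensionScore:
    basic: float
    applied: float
    higher_order: float
    total: float


@dataclass
class TlxRating:
    mental: float
    temporal: float
    performance: float
    effort: float
    frustration: float
    physical: float
    total: float


def _round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(x).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# attention stream post-processing
# ---------------------------------------------------------------------------

def truncate_outliers(
    series: AttentionSeries,
    n_sd: float = config.TRUNCATION_SD,
    mode: str = "clamp",
) -> AttentionSeries:
    """Truncate index values outside mean ± 2 SD of the valid frames.

    ``clamp`` (default) winsorizes to the nearest bound, preserving the 4 Hz
    time base required by the sliding average; ``drop`` marks outliers
    excluded instead.  Excluded frames are untouched either way.
    """
    valid = series.valid
    if valid.sum() < 3:
        raise ParameterError("need at least 3 valid frames to truncate outliers")
    vals = series.index[valid]
    m, s = vals.mean(), vals.std(ddof=1)
    if s == 0:
        return series.replace()
    lo, hi = m - n_sd * s, m + n_sd * s
    index = series.index.copy()
    if mode == "clamp":
        index[valid] = np.clip(vals, lo, hi)
        return series.replace(index=index)
    if mode == "drop":
        out = valid & ((series.index < lo) | (series.index > hi))
        excluded = series.excluded | out
        index[out] = np.nan
        return series.replace(index=index, excluded=excluded)
    raise ParameterError(f"unknown truncation mode {mode!r}")


def sliding_average(
    series: AttentionSeries,
    window_s: float = config.SMOOTHING_WINDOW_S,
    frame_rate: float = config.UPDATE_RATE_HZ,
) -> AttentionSeries:
    """Centered moving mean over a 5-s window (21 taps at 4 Hz, ±2.5 s).

    Excluded frames are omitted from every window's mean, and windows shrink
    at the series edges.  Frames that were excluded stay excluded.
    """
    half = int(round(window_s * frame_rate)) // 2
    taps = 2 * half + 1
    valid = series.valid.astype(float)
    vals = np.where(series.valid, series.index, 0.0)
    kernel = np.ones(taps)
    num = np.convolve(vals, kernel, mode="same")
    den = np.convolve(valid, kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        smoothed = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    index = np.where(series.excluded, np.nan, smoothed)
    return series.replace(index=index)


def summarize_attention(series: AttentionSeries, condition: str = "") -> AttentionSummary:
    """Mean focus level and CV (sample SD / mean × 100) over valid frames."""
    vals = series.valid_indices()
    if vals.size < 2:
        raise ParameterError("need at least 2 valid frames to summarize")
    m = float(vals.mean())
    if m == 0:
        raise ParameterError("CV undefined: mean index is zero")
    cv = float(vals.std(ddof=1) / m * 100.0)
    return AttentionSummary(condition=condition, mean_index=m, cv_pct=cv)


# ---------------------------------------------------------------------------
# behavioral scoring
# ---------------------------------------------------------------------------

def score_comprehension(basic: float, applied: float, higher_order: float) -> ComprehensionScore:
    """Total comprehension score = mean of the three subscales (1 dp, half-up)."""
    for v in (basic, applied, higher_order):
        if not 0 <= v <= 100:
            raise ParameterError("subscale scores must be in [0, 100]")
    total = _round_half_up((basic + applied + higher_order) / 3.0, 1)
    return ComprehensionScore(basic=basic, applied=applied, higher_order=higher_order, total=total)


def awsit_condition_means(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-trial-type mean RT (correct trials only) and accuracy (%).

    ``trials`` needs columns trial_type, rt_ms, correct.  Returns a frame
    indexed by trial type with columns mean_rt_ms, accuracy_pct, n_trials.
    """
    required = {"trial_type", "rt_ms", "correct"}
    if not required.issubset(trials.columns):
        raise ParameterError(f"trial table must have columns {sorted(required)}")
    bad = set(trials["trial_type"]) - set(TRIAL_TYPES)
    if bad:
        raise ParameterError(f"unknown trial type(s): {sorted(bad)}")
    if (trials["rt_ms"] <= 0).any():
        raise ParameterError("reaction times must be positive")
    rows = {}
    for tt, grp in trials.groupby("trial_type"):
        correct = grp[grp["correct"].astype(bool)]
        rows[tt] = {
            "mean_rt_ms": correct["rt_ms"].mean() if len(correct) else np.nan,
            "accuracy_pct": 100.0 * grp["correct"].astype(bool).mean(),
            "n_trials": len(grp),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def interference_effects(
    mean_rt: Mapping[str, float],
    accuracy: Mapping[str, float] | None = None,
) -> InterferenceEffects:
    """Semantic-interference effects: FI−FU and FP−FU mean-RT differences (ms)."""
    for tt in ("FI", "FU", "FP"):
        if tt not in mean_rt or not np.isfinite(mean_rt[tt]):
            raise ParameterError(f"missing mean RT for trial type {tt}")
    acc = None
    if accuracy is not None and "FI" in accuracy:
        acc = float(accuracy["FI"])
        if not 0 <= acc <= 100:
            raise ParameterError("accuracy must be in [0, 100]")
    return InterferenceEffects(
        delta_fi=float(mean_rt["FI"] - mean_rt["FU"]),
        delta_fp=float(mean_rt["FP"] - mean_rt["FU"]),
        acc_fi=acc,
    )


def percent_reduction(delta_ref: float, delta_nf: float) -> int:
    """Interference reduction vs a reference condition, % (nearest integer)."""
    if delta_ref == 0:
        raise ParameterError("reference interference effect is zero")
    pct = 100.0 * (delta_ref - delta_nf) / delta_ref
    return int(_round_half_up(pct, 0))


def tlx_scores(
    mental: float,
    temporal: float,
    performance: float,
    effort: float,
    frustration: float,
    physical: float,
) -> TlxRating:
    """Raw-TLX workload: total = unweighted mean of the six 0-100 subscales."""
    subs = (mental, temporal, performance, effort, frustration, physical)
    for v in subs:
        if not 0 <= v <= 100:
            raise ParameterError("TLX subscales must be in [0, 100]")
    return TlxRating(*subs, total=float(np.mean(subs)))


# ---------------------------------------------------------------------------
# per-study summary table
# ---------------------------------------------------------------------------

def summary_table(behavioral: pd.DataFrame, trials: pd.DataFrame | None = None) -> pd.DataFrame:
    """Wide per-subject-per-condition summary of all study measures.

    ``behavioral`` is the long table (subject, condition, measure, value);
    ``trials`` optionally adds AWSIT-derived measures recomputed from the
    trial level (mean RTs over correct trials, accuracy, interference deltas).
    """
    required = {"subject", "condition", "measure", "value"}
    if not required.issubset(behavioral.columns):
        raise ParameterError(f"behavioral table must have columns {sorted(required)}")
    wide = behavioral.pivot_table(
        index=["subject", "condition"], columns="measure", values="value"
    )
    if trials is not None:
        rows = []
        for (subj, cond), grp in trials.groupby(["subject", "condition"]):
            means = awsit_condition_means(grp)
            eff = interference_effects(
                means["mean_rt_ms"].to_dict(), means["accuracy_pct"].to_dict()
            )
            rows.append(
                {
                    "subject": subj,
                    "condition": cond,
                    "trial_delta_fi": eff.delta_fi,
                    "trial_delta_fp": eff.delta_fp,
                    "trial_acc_fi": eff.acc_fi,
                }
            )
        extra = pd.DataFrame(rows).set_index(["subject", "condition"])
        wide = wide.join(extra)
    wide.columns.name = None
    return wide.reset_index()
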