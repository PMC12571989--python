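"""Raw EEG to normalized 0-100 attention index.

The attention index is the ratio of beta-band (13-30 Hz) power to the summed
alpha- (8-12 Hz) and theta-band (4-7 Hz) power, computed every 250 ms from the
preceding 500 ms buffer over a frontal composite (mean band power across Fp1,
Fp2, F3, F4), then linearly normalized against the individual's baseline-ratio
range.

Spectral estimation uses Hann-tapered periodograms with density scaling (taper
power normalized by sum(w^2)), so Parseval holds exactly: a pure in-band
sinusoid of amplitude a contributes a^2/2 to its band, and white-noise band
power is proportional to bandwidth.  Band edges are closed intervals on FFT
bin centers; bins in the 7-8 and 12-13 Hz gaps belong to no band.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import scipy.signal as sps

from nfkit import config
from nfkit.core import (
    AttentionSeries,
    BandDefinition,
    BaselineProfile,
    CalibrationError,
    EegRecording,
    ParameterError,
)

DEFAULT_BANDS = BandDefinition()


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def design_filters(sample_rate: float, bands: BandDefinition = DEFAULT_BANDS):
    """4th-order Butterworth bandpass + 2nd-order IIR notch, as SOS sections."""
    if sample_rate <= 2 * bands.passband[1]:
        raise ParameterError("sample rate too low for the analysis passband")
    sos_band = sps.butter(4, bands.passband, btype="bandpass", fs=sample_rate, output="sos")
    b, a = sps.iirnotch(bands.notch_hz, Q=30.0, fs=sample_rate)
    sos_notch = sps.tf2sos(b, a)
    return sos_band, sos_notch


def preprocess(
    rec: EegRecording,
    bands: BandDefinition = DEFAULT_BANDS,
    mode: str = "offline",
) -> EegRecording:
    """Bandpass (4-40 Hz) + 50 Hz notch; removes DC drift and line hum.

    ``mode='offline'`` applies zero-phase (forward-backward) filtering, the
    analysis-path default.  ``mode='causal'`` applies single-pass causal
    filtering, emulating the real-time path (with its phase lag).
    """
    if rec.sample_rate <= 80:
        raise ParameterError("sample_rate must exceed 80 Hz for the 4-40 Hz analysis band")
    sos_band, sos_notch = design_filters(rec.sample_rate, bands)
    sos = np.vstack([sos_band, sos_notch])
    min_samples = int(3 * rec.sample_rate)
    if rec.n_samples < min_samples:
        raise ParameterError(
            f"recording too short for filter settling: {rec.n_samples} samples, "
            f"need >= {min_samples}"
        )
    if mode == "offline":
        filtered = sps.sosfiltfilt(sos, rec.samples, axis=1)
    elif mode == "causal":
        filtered = sps.sosfilt(sos, rec.samples, axis=1)
    else:
        raise ParameterError(f"unknown filter mode {mode!r}")
    return EegRecording(
        sample_rate=rec.sample_rate,
        channel_labels=rec.channel_labels,
        samples=filtered,
        accel=None if rec.accel is None else rec.accel.copy(),
        start_time=rec.start_time,
    )


# ---------------------------------------------------------------------------
# band power
# ---------------------------------------------------------------------------

def band_power(window: np.ndarray, band: Sequence[float], sample_rate: float) -> float:
    """Band power (µV²) of a buffered window, averaged over channels.

    ``window`` is (samples,) or (channels, samples).  Power is the integral of
    the Hann periodogram density over bins whose centers fall inside the
    closed ``band`` interval.
    """
    x = np.atleast_2d(np.asarray(window, dtype=float))
    if x.shape[-1] < 2:
        raise ParameterError("window must contain at least 2 samples")
    lo, hi = float(band[0]), float(band[1])
    if not 0 <= lo < hi:
        raise ParameterError(f"invalid band {band}")
    if hi > sample_rate / 2:
        raise ParameterError(f"band {band} extends beyond Nyquist ({sample_rate / 2} Hz)")
    freqs, pxx = sps.periodogram(
        x, fs=sample_rate, window="hann", scaling="density", detrend=False, axis=-1
    )
    df = freqs[1] - freqs[0]
    sel = (freqs >= lo) & (freqs <= hi)
    return float(pxx[..., sel].sum(axis=-1).mean() * df)


def _batch_band_powers(
    frames: np.ndarray, sample_rate: float, bands: Mapping[str, Sequence[float]]
) -> dict[str, np.ndarray]:
    """Hann periodogram band powers for a batch of windows.

    ``frames`` is (n_frames, n_channels, n_samples); returns, per band, the
    (n_frames,) channel-mean power.  Independent code path from
    :func:`band_power` (hand-normalized rfft) used by the streaming engine.
    """
    n = frames.shape[-1]
    w = sps.get_window("hann", n)
    scale = 2.0 / (sample_rate * np.sum(w**2))
    spec = np.fft.rfft(frames * w, axis=-1)
    pxx = scale * np.abs(spec) ** 2
    pxx[..., 0] /= 2.0
    if n % 2 == 0:
        pxx[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    df = sample_rate / n
    out: dict[str, np.ndarray] = {}
    for name, (lo, hi) in bands.items():
        sel = (freqs >= lo) & (freqs <= hi)
        out[name] = pxx[..., sel].sum(axis=-1).mean(axis=-1) * df
    return out


# ---------------------------------------------------------------------------
# ratio and normalization
# ---------------------------------------------------------------------------

def attention_ratio(theta_p: float, alpha_p: float, beta_p: float) -> float:
    """beta / (alpha + theta); undefined when the denominator is zero."""
    if theta_p < 0 or alpha_p < 0 or beta_p < 0:
        raise ParameterError("band powers must be non-negative")
    denom = alpha_p + theta_p
    if denom == 0:
        raise ParameterError("undefined ratio: alpha + theta power is zero")
    return beta_p / denom


def calibrate_baseline(
    baseline_ratios: np.ndarray,
    eyes_open_ratios: np.ndarray,
    low_pct: float = config.BASELINE_LOW_PERCENTILE,
    high_pct: float = config.BASELINE_HIGH_PERCENTILE,
) -> BaselineProfile:
    """Anchor the 0-100 scale on the pooled Day-1 baseline ratio distribution.

    ``baseline_ratios`` pools all three baseline conditions (eyes closed,
    eyes open, mental arithmetic); anchors are its 1st/99th percentiles.
    ``eyes_open_ratios`` is the eyes-open fixation segment whose normalized
    mean seeds the initial feedback threshold.
    """
    pooled = np.asarray(baseline_ratios, dtype=float)
    pooled = pooled[np.isfinite(pooled)]
    eyes = np.asarray(eyes_open_ratios, dtype=float)
    eyes = eyes[np.isfinite(eyes)]
    if pooled.size < config.MIN_BASELINE_FRAMES:
        raise CalibrationError(
            f"need >= {config.MIN_BASELINE_FRAMES} valid baseline frames, got {pooled.size}"
        )
    if eyes.size == 0:
        raise CalibrationError("eyes-open segment contains no valid frames")
    low, high = np.percentile(pooled, [low_pct, high_pct])
    if not low < high:
        raise CalibrationError("degenerate baseline range: ratio distribution is constant")
    profile = BaselineProfile(
        ratio_low_anchor=float(low),
        ratio_high_anchor=float(high),
        eyes_open_mean_index=0.0,
    )
    profile.eyes_open_mean_index = float(normalize_index(float(eyes.mean()), profile))
    return profile


def normalize_index(ratio, profile: BaselineProfile):
    """Linear map of [low_anchor, high_anchor] onto [0, 100], clipped outside."""
    span = profile.ratio_high_anchor - profile.ratio_low_anchor
    scaled = (np.asarray(ratio, dtype=float) - profile.ratio_low_anchor) / span * 100.0
    return np.clip(scaled, 0.0, 100.0)


# ---------------------------------------------------------------------------
# streaming
# ---------------------------------------------------------------------------

def stream_ratios(
    rec: EegRecording,
    bands: BandDefinition = DEFAULT_BANDS,
    frontal: Sequence[str] = config.FRONTAL_CHANNELS,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw 4 Hz ratio stream (timestamps, ratios); NaN where undefined.

    Frames sit on the 0.25 s grid; each is computed from the preceding 500 ms
    buffer over the frontal composite.  Used both for baseline calibration
    (before a profile exists) and inside :func:`stream_indices`.
    """
    fs = rec.sample_rate
    win = config.FFT_WINDOW_S
    step = 1.0 / config.UPDATE_RATE_HZ
    nwin = int(round(win * fs))
    if rec.n_samples < nwin:
        raise ParameterError("recording shorter than one FFT buffer")
    idx = rec.frontal_indices(frontal)
    n_frames = int(np.floor((rec.duration_s - win) / step + 1e-9)) + 1
    times = win + step * np.arange(n_frames)
    starts = np.round((times - win) * fs).astype(int)
    starts = np.minimum(starts, rec.n_samples - nwin)
    # (n_frames, n_frontal, nwin)
    frames = rec.samples[idx][:, starts[:, None] + np.arange(nwin)].transpose(1, 0, 2)
    powers = _batch_band_powers(frames, fs, bands.bands)
    denom = powers["alpha"] + powers["theta"]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(denom > 0, powers["beta"] / np.where(denom > 0, denom, 1.0), np.nan)
    return rec.start_time + times, ratios


def stream_indices(
    rec: EegRecording,
    profile: BaselineProfile | None,
    exclusion_mask=None,
    bands: BandDefinition = DEFAULT_BANDS,
    frontal: Sequence[str] = config.FRONTAL_CHANNELS,
) -> AttentionSeries:
    """4 Hz AttentionSeries from a preprocessed recording.

    Frames whose 500 ms buffer overlaps any excluded 1-s epoch are flagged and
    omitted from downstream means.  With ``profile=None`` the raw ratios are
    streamed and the index is NaN everywhere (calibration mode).
    """
    times, ratios = stream_ratios(rec, bands=bands, frontal=frontal)
    excluded = ~np.isfinite(ratios)
    if exclusion_mask is not None:
        flags = np.asarray(exclusion_mask.flagged, dtype=bool)
        win = config.FFT_WINDOW_S
        rel = times - rec.start_time
        first = np.floor(rel - win + 1e-9).astype(int)
        last = np.ceil(rel - 1e-9).astype(int) - 1
        for k in range(len(times)):
            lo = max(first[k], 0)
            hi = min(last[k], len(flags) - 1)
            if lo <= hi and np.any(flags[lo : hi + 1]):
                excluded[k] = True
    if profile is not None:
        index = normalize_index(ratios, profile)
    else:
        index = np.full_like(ratios, np.nan)
    index = np.where(excluded, np.nan, index)
    return AttentionSeries(timestamps=times, raw_ratio=ratios, index=index, excluded=excluded)
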