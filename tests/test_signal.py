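"""Signal engine: filtering contracts, band-power oracles, normalization, and
the 4 Hz streaming path."""

import numpy as np
import pytest
import scipy.signal as sps
from hypothesis import given, settings, strategies as hst

from nfkit import signal as sig
from nfkit import synth
from nfkit.core import (
    BandDefinition,
    BaselineProfile,
    CalibrationError,
    ConfigurationError,
    EegRecording,
    ParameterError,
)
from tests.conftest import make_tone_recording


def steady_state_amplitude(x, fs, discard_s=2.0):
    mid = x[int(discard_s * fs) : -int(discard_s * fs)]
    return np.abs(mid).max()


class TestPreprocess:
    def test_dc_offset_rejected(self):
        rec = make_tone_recording(0.0, 0.0)
        rec.samples += 50.0
        out = sig.preprocess(rec)
        assert abs(out.samples[0][500:-500].mean()) < 0.5

    def test_notch_attenuates_50hz_by_20db(self):
        out = sig.preprocess(make_tone_recording(50.0, 10.0))
        assert steady_state_amplitude(out.samples[0], 250) <= 1.0

    def test_passband_unity_at_10hz(self):
        out = sig.preprocess(make_tone_recording(10.0, 10.0))
        assert 9.5 <= steady_state_amplitude(out.samples[0], 250) <= 10.5

    def test_too_short_recording_rejected(self):
        with pytest.raises(ParameterError):
            sig.preprocess(make_tone_recording(10.0, 10.0, duration_s=1.0))

    def test_causal_mode_also_removes_hum(self):
        out = sig.preprocess(make_tone_recording(50.0, 10.0), mode="causal")
        assert steady_state_amplitude(out.samples[0], 250) <= 1.0


class TestBandPower:
    def test_zero_window(self):
        assert sig.band_power(np.zeros(125), (8, 12), 250.0) == 0.0

    def test_sinusoid_parseval(self):
        # 10 Hz, 20 µV, 500 ms buffer → a²/2 = 200 µV² within 15%
        t = np.arange(125) / 250.0
        x = 20.0 * np.sin(2 * np.pi * 10.0 * t + 0.3)
        assert sig.band_power(x, (8, 12), 250.0) == pytest.approx(200.0, rel=0.15)

    def test_white_noise_bandwidth_proportionality(self, rng):
        x = rng.standard_normal(250 * 120)
        alpha = sig.band_power(x, (8, 12), 250.0)
        broad = sig.band_power(x, (4, 30), 250.0)
        assert alpha / broad == pytest.approx(4.0 / 26.0, rel=0.10)

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            sig.band_power(np.zeros(125), (100, 130), 250.0)

    def test_channel_averaging(self, rng):
        win = rng.standard_normal((4, 125))
        per_channel = [sig.band_power(win[i], (8, 12), 250.0) for i in range(4)]
        assert sig.band_power(win, (8, 12), 250.0) == pytest.approx(np.mean(per_channel))


class TestAttentionRatio:
    @pytest.mark.parametrize(
        "theta,alpha,beta,expected",
        [(1.0, 1.0, 2.0, 1.0), (0.7, 0.7, 0.7, 0.5), (0.4, 0.6, 0.0, 0.0)],
    )
    def test_algebra(self, theta, alpha, beta, expected):
        assert sig.attention_ratio(theta, alpha, beta) == pytest.approx(expected)

    def test_zero_denominator_is_undefined(self):
        with pytest.raises(ParameterError):
            sig.attention_ratio(0.0, 0.0, 1.0)


class TestCalibration:
    def test_constant_sequence_degenerate(self):
        with pytest.raises(CalibrationError):
            sig.calibrate_baseline(np.full(100, 0.8), np.full(10, 0.8))

    def test_too_few_frames(self):
        with pytest.raises(CalibrationError):
            sig.calibrate_baseline(np.linspace(0.2, 1.0, 10), np.full(5, 0.5))

    def test_uniform_sample_percentile_anchors(self, rng):
        ratios = rng.uniform(0.2, 1.0, 2000)
        prof = sig.calibrate_baseline(ratios, ratios)
        lo, hi = np.percentile(ratios, [1, 99])  # direct oracle on the sample
        assert prof.ratio_low_anchor == pytest.approx(lo)
        assert prof.ratio_high_anchor == pytest.approx(hi)
        assert prof.ratio_low_anchor == pytest.approx(0.208, abs=0.01)
        assert prof.ratio_high_anchor == pytest.approx(0.992, abs=0.01)

    def test_eyes_open_at_midpoint_maps_to_50(self, rng):
        ratios = rng.uniform(0.2, 1.0, 2000)
        prof = sig.calibrate_baseline(ratios, ratios)
        mid = (prof.ratio_low_anchor + prof.ratio_high_anchor) / 2
        prof2 = sig.calibrate_baseline(ratios, np.full(30, mid))
        assert prof2.eyes_open_mean_index == pytest.approx(50.0, abs=1e-9)


class TestNormalization:
    profile = BaselineProfile(0.4, 1.2, 50.0)

    @pytest.mark.parametrize("ratio,expected", [(0.4, 0.0), (1.2, 100.0), (0.8, 50.0)])
    def test_anchor_mapping(self, ratio, expected):
        assert sig.normalize_index(ratio, self.profile) == pytest.approx(expected)

    def test_clipping(self):
        assert sig.normalize_index(0.0, self.profile) == 0.0
        assert sig.normalize_index(5.0, self.profile) == 100.0

    @settings(derandomize=True, max_examples=60)
    @given(
        r1=hst.floats(-2, 5, allow_nan=False),
        r2=hst.floats(-2, 5, allow_nan=False),
    )
    def test_monotone(self, r1, r2):
        lo, hi = sorted((r1, r2))
        assert sig.normalize_index(lo, self.profile) <= sig.normalize_index(hi, self.profile)


class TestStreaming:
    def test_60s_yields_239_frames(self, session_recording):
        series = sig.stream_indices(session_recording, None)
        assert len(series) == 239
        assert series.timestamps[0] == pytest.approx(0.5)
        assert series.timestamps[-1] == pytest.approx(60.0)

    def test_missing_frontal_channel(self):
        rec = make_tone_recording(10.0, 5.0, channels=("Fp1", "Fp2", "F3"))
        with pytest.raises(ConfigurationError):
            sig.stream_indices(rec, None)

    def test_full_exclusion_mask_excludes_everything(self, session_recording):
        from nfkit.artifacts import ExclusionMask

        mask = ExclusionMask.empty(60)
        mask.flagged[:] = True
        profile = BaselineProfile(0.1, 2.0, 50.0)
        series = sig.stream_indices(session_recording, profile, exclusion_mask=mask)
        assert series.excluded.all()

    def test_balanced_bands_give_unit_ratio(self):
        amp = {"theta": 6.0, "alpha": 6.0, "beta": 6.0 * np.sqrt(2)}
        rec = synth.generate_eeg(
            synth.SynthEegSpec(
                duration_s=60.0, band_amplitudes=amp, noise_scale=0.5,
                line_hum_amplitude=0.0, seed=8,
            )
        )
        series = sig.stream_indices(rec, None)
        assert np.nanmedian(series.raw_ratio) == pytest.approx(1.0, rel=0.15)

    def test_channel_order_invariance(self, session_recording):
        rec = session_recording
        perm = np.array([3, 0, 2, 1, 7, 5, 4, 6])
        shuffled = EegRecording(
            sample_rate=rec.sample_rate,
            channel_labels=tuple(rec.channel_labels[i] for i in perm),
            samples=rec.samples[perm],
            accel=rec.accel,
        )
        a = sig.stream_indices(rec, None)
        b = sig.stream_indices(shuffled, None)
        assert np.allclose(a.raw_ratio, b.raw_ratio, equal_nan=True)

    def test_streaming_matches_whole_window_oracle(self):
        # stationary signal: streaming band powers vs direct periodogram ratio
        amp = {"theta": 5.0, "alpha": 7.0, "beta": 6.0}
        rec = synth.generate_eeg(
            synth.SynthEegSpec(
                duration_s=60.0, band_amplitudes=amp, noise_scale=0.0,
                line_hum_amplitude=0.0, seed=9,
            )
        )
        series = sig.stream_indices(rec, None)
        x = rec.channel("Fp1")
        f, p = sps.periodogram(x, fs=250.0, scaling="density")
        df = f[1] - f[0]

        def bp(lo, hi):
            return p[(f >= lo) & (f <= hi)].sum() * df

        oracle = bp(13, 30) / (bp(8, 12) + bp(4, 7))
        assert np.nanmedian(series.raw_ratio) == pytest.approx(oracle, rel=0.15)

    def test_beta_amplitude_strictly_raises_ratio(self):
        medians = []
        for a_beta in (4.0, 6.0, 8.0):
            rec = synth.generate_eeg(
                synth.SynthEegSpec(
                    duration_s=30.0,
                    band_amplitudes={"theta": 6.0, "alpha": 8.0, "beta": a_beta},
                    noise_scale=0.5, line_hum_amplitude=0.0, seed=10,
                )
            )
            series = sig.stream_indices(rec, None)
            medians.append(np.nanmedian(series.raw_ratio))
        assert medians[0] < medians[1] < medians[2]
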