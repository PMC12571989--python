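"""Synthetic-data generator: spectral fidelity, artifact injection, and the
statistical structure of the simulated behavioral study."""

import numpy as np
import pandas as pd
import pytest
import scipy.signal as sps

from nfkit import synth
from nfkit.core import ParameterError


def periodogram_band_power(x, fs, lo, hi):
    """Independent whole-session band-power oracle (boxcar periodogram)."""
    f, p = sps.periodogram(x, fs=fs, scaling="density")
    df = f[1] - f[0]
    return p[(f >= lo) & (f <= hi)].sum() * df


class TestGenerateEeg:
    def test_zero_spec_gives_zero_signal(self):
        spec = synth.SynthEegSpec(
            duration_s=5.0, band_amplitudes={}, noise_scale=0.0, line_hum_amplitude=0.0
        )
        rec = synth.generate_eeg(spec)
        assert np.all(rec.samples == 0.0)

    def test_single_alpha_component_band_power(self):
        # 10 Hz, 20 µV → alpha power a²/2 = 200 µV²; theta/beta empty
        spec = synth.SynthEegSpec(
            duration_s=60.0,
            band_amplitudes={"alpha": 20.0},
            noise_scale=0.0,
            line_hum_amplitude=0.0,
            seed=7,
        )
        rec = synth.generate_eeg(spec)
        x = rec.channel("Fp1")
        assert periodogram_band_power(x, 250, 8, 12) == pytest.approx(200.0, rel=0.10)
        assert periodogram_band_power(x, 250, 4, 7) < 1.0
        assert periodogram_band_power(x, 250, 13, 30) < 1.0

    def test_all_band_targets_within_ten_percent(self):
        spec = synth.SynthEegSpec(duration_s=60.0, seed=3)  # defaults 6/8/5 µV
        rec = synth.generate_eeg(spec)
        x = rec.channel("F3")
        for (lo, hi), a in zip(((4, 7), (8, 12), (13, 30)), (6.0, 8.0, 5.0)):
            est = periodogram_band_power(x, 250, lo, hi)
            # noise floor contributes, so estimate sits slightly above a²/2
            assert est == pytest.approx(a * a / 2, rel=0.10)

    def test_seed_changes_samples_not_band_power(self):
        base = dict(duration_s=60.0, noise_scale=3.0)
        r1 = synth.generate_eeg(synth.SynthEegSpec(**base, seed=1))
        r2 = synth.generate_eeg(synth.SynthEegSpec(**base, seed=2))
        assert not np.array_equal(r1.samples, r2.samples)
        for (lo, hi) in ((4, 7), (8, 12), (13, 30)):
            p1 = periodogram_band_power(r1.channel("Fp1"), 250, lo, hi)
            p2 = periodogram_band_power(r2.channel("Fp1"), 250, lo, hi)
            assert p1 == pytest.approx(p2, rel=0.10)

    def test_determinism(self):
        spec = synth.SynthEegSpec(duration_s=10.0, seed=5)
        assert np.array_equal(synth.generate_eeg(spec).samples, synth.generate_eeg(spec).samples)

    @pytest.mark.parametrize("bad", [dict(duration_s=0), dict(duration_s=-3), dict(sample_rate=0)])
    def test_invalid_parameters(self, bad):
        with pytest.raises(ParameterError):
            synth.generate_eeg(synth.SynthEegSpec(**{"duration_s": 10.0, **bad}))

    def test_rate_below_nyquist_of_components(self):
        spec = synth.SynthEegSpec(
            duration_s=5.0, sample_rate=40.0, band_amplitudes={"beta": 5.0},
            line_hum_amplitude=0.0,
        )
        with pytest.raises(ParameterError):
            synth.generate_eeg(spec)


class TestInjectArtifacts:
    def test_empty_events_identity(self, session_recording):
        out = synth.inject_artifacts(session_recording, synth.ArtifactEventSpec())
        assert np.array_equal(out.samples, session_recording.samples)
        assert np.array_equal(out.accel, session_recording.accel)

    def test_motion_event_raises_magnitude(self, session_recording):
        ev = synth.ArtifactEventSpec(motion_events=[(10.0, 600.0, 0.6)])
        out = synth.inject_artifacts(session_recording, ev)
        mag = out.accel_magnitude
        dev = np.abs(mag - 1.0)
        over = dev > 0.5
        assert over.sum() >= 0.6 * 250
        assert np.flatnonzero(over)[0] == 10 * 250
        untouched = np.delete(mag, np.s_[10 * 250 : 10 * 250 + 151])
        assert np.allclose(untouched, 1.0)

    def test_amplitude_event_reaches_peak(self, session_recording):
        ev = synth.ArtifactEventSpec(amplitude_events=[(7.0, "Fp1", 120.0)])
        out = synth.inject_artifacts(session_recording, ev)
        sec7 = out.channel("Fp1")[7 * 250 : 8 * 250]
        assert np.abs(sec7).max() >= 120.0
        # only the named channel is touched
        assert np.array_equal(out.channel("Fp2"), session_recording.channel("Fp2"))

    def test_unknown_channel_rejected(self, session_recording):
        ev = synth.ArtifactEventSpec(amplitude_events=[(1.0, "Oz", 120.0)])
        with pytest.raises(ParameterError):
            synth.inject_artifacts(session_recording, ev)

    def test_out_of_bounds_onset_rejected(self, session_recording):
        ev = synth.ArtifactEventSpec(motion_events=[(120.0, 600.0, 0.6)])
        with pytest.raises(ParameterError):
            synth.inject_artifacts(session_recording, ev)


def wide_values(df, measure):
    return df[df["measure"] == measure].pivot(index="subject", columns="condition", values="value")


class TestBehavioralGenerator:
    def test_too_few_subjects_rejected(self):
        with pytest.raises(ParameterError):
            synth.generate_behavioral_dataset(synth.StudyEffectSpec(n_subjects=1))

    def test_null_coupling_gives_no_correlation(self):
        spec = synth.StudyEffectSpec(
            n_subjects=5000, brain_behavior_coupling={c: 0.0 for c in synth.CONDITIONS}, seed=21
        )
        df = synth.generate_behavioral_dataset(spec)
        att = wide_values(df, "attention_mean")["nf"]
        comp = wide_values(df, "comp_total")["nf"]
        assert abs(np.corrcoef(att, comp)[0, 1]) <= 0.05

    def test_condition_means_converge_to_targets(self):
        df = synth.generate_behavioral_dataset(synth.StudyEffectSpec(n_subjects=5000, seed=22))
        att = wide_values(df, "attention_mean")
        for cond, target in (("device", 55.2), ("sham", 59.0), ("nf", 67.4)):
            assert att[cond].mean() == pytest.approx(target, abs=0.5)
        for cond, target in (("device", 7.1), ("sham", 8.4), ("nf", 7.8)):
            assert att[cond].std(ddof=1) == pytest.approx(target, abs=0.5)

    def test_within_subject_correlation_recovered(self):
        df = synth.generate_behavioral_dataset(synth.StudyEffectSpec(n_subjects=5000, seed=23))
        tlx = wide_values(df, "tlx_mental")
        z = (tlx - tlx.mean()) / tlx.std(ddof=1)
        r = np.corrcoef(z["device"], z["sham"])[0, 1]
        assert r == pytest.approx(0.5, abs=0.06)

    def test_nf_coupling_within_fisher_interval(self):
        # target r = 0.63 at n = 200: 99% sampling interval via the Fisher z transform
        n, target = 200, 0.63
        z = np.arctanh(target)
        half = 2.5758 / np.sqrt(n - 3)
        lo, hi = np.tanh(z - half), np.tanh(z + half)
        df = synth.generate_behavioral_dataset(synth.StudyEffectSpec(n_subjects=n, seed=24))
        att = wide_values(df, "attention_mean")["nf"]
        comp = wide_values(df, "comp_total")["nf"]
        r = np.corrcoef(att, comp)[0, 1]
        assert lo <= r <= hi

    def test_comprehension_total_is_subscale_mean(self):
        df = synth.generate_behavioral_dataset(synth.StudyEffectSpec(n_subjects=10, seed=25))
        wide = df.pivot_table(index=["subject", "condition"], columns="measure", values="value")
        expected = wide[["comp_basic", "comp_applied", "comp_higher"]].mean(axis=1)
        assert np.allclose(wide["comp_total"], expected)

    def test_interference_sd_matches_reported_scale(self):
        df = synth.generate_behavioral_dataset(synth.StudyEffectSpec(n_subjects=5000, seed=26))
        delta = wide_values(df, "delta_fi")
        assert delta["device"].std(ddof=1) == pytest.approx(11.0, abs=0.6)
        fi = wide_values(df, "rt_fi")
        assert fi["device"].std(ddof=1) == pytest.approx(32.0, abs=1.5)


class TestAwsitTrials:
    def test_trial_counts_and_schema(self):
        spec = synth.StudyEffectSpec(n_subjects=4, seed=31)
        beh = synth.generate_behavioral_dataset(spec)
        trials = synth.generate_awsit_trials(beh, spec)
        assert len(trials) == 4 * 3 * 4 * synth.TRIALS_PER_CELL
        assert set(trials["trial_type"]) == {"TC", "FI", "FU", "FP"}
        assert (trials["rt_ms"] >= synth.RT_FLOOR_MS).all()

    def test_trial_rts_center_on_cell_means(self):
        spec = synth.StudyEffectSpec(n_subjects=40, seed=32)
        beh = synth.generate_behavioral_dataset(spec)
        trials = synth.generate_awsit_trials(beh, spec)
        fi = trials[(trials["condition"] == "device") & (trials["trial_type"] == "FI")]
        assert fi["rt_ms"].mean() == pytest.approx(782.0, abs=15.0)


class TestFullStudy:
    def test_same_seed_identical_datasets(self):
        a = synth.generate_full_study(9, baseline_s=4.0, learning_s=8.0)
        b = synth.generate_full_study(9, baseline_s=4.0, learning_s=8.0)
        pd.testing.assert_frame_equal(a.behavioral, b.behavioral)
        pd.testing.assert_frame_equal(a.awsit_trials, b.awsit_trials)
        pd.testing.assert_frame_equal(a.condition_orders, b.condition_orders)
        ra = a.realize_session_eeg(1, "nf")[1]
        rb = b.realize_session_eeg(1, "nf")[1]
        assert np.array_equal(ra.samples, rb.samples)

    def test_counterbalanced_orders(self):
        study = synth.generate_full_study(10, baseline_s=4.0, learning_s=8.0)
        counts = study.condition_orders["order"].value_counts()
        assert len(counts) == 6
        assert (counts == 5).all()

    def test_session_eeg_tracks_attention(self):
        study = synth.generate_full_study(12, baseline_s=4.0, learning_s=30.0)
        wide = study.behavioral.pivot_table(
            index=["subject", "condition"], columns="measure", values="value"
        )
        hi = wide["attention_mean"].idxmax()
        lo = wide["attention_mean"].idxmin()
        amp_hi = study.session_specs[hi].eeg.band_amplitudes["beta"]
        amp_lo = study.session_specs[lo].eeg.band_amplitudes["beta"]
        assert amp_hi > amp_lo
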