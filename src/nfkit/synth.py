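"""Seeded synthetic EEG sessions and behavioral datasets.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without recorded data:

* oscillatory EEG built from sinusoids at band-center frequencies (theta
  5.5 Hz, alpha 10 Hz, beta 21.5 Hz) with amplitude envelopes — band-power
  targets are therefore analytic (a²/2 per component) — over a 1/f^α Gaussian
  noise floor and optional 50 Hz line hum;
* motion and high-amplitude artifact injection matching the gating rules
  (accelerometer magnitude steps, frontal-channel voltage excursions);
* a 30-subject × 3-condition (device control / sham / neurofeedback)
  behavioral study with additive Gaussian subject intercepts (within-subject
  correlation ρ), per-condition means/SDs for every reported measure, and a
  condition-specific latent coupling between the attention index and the
  comprehension total.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats as st

from nfkit import config
from nfkit.core import EegRecording, ParameterError

BAND_CENTER_HZ = {"theta": 5.5, "alpha": 10.0, "beta": 21.5}

CONDITIONS = ("device", "sham", "nf")

#: Per-measure (mean, SD) by condition.  Attention, comprehension, FI/FP RTs,
#: FI accuracy, TLX subscales and strategy ratings are the reported cell
#: statistics; FU RTs are reconstructed from FI − ΔRT with SDs chosen so both
#: the FI SDs and the interference-effect SDs are reproduced; TC RTs and
#: TC/FU/FP accuracies are unreported and filled with realistic values.
STUDY_MEASURES: dict[str, dict[str, tuple[float, float]]] = {
    "attention_mean": {"device": (55.2, 7.1), "sham": (59.0, 8.4), "nf": (67.4, 7.8)},
    "attention_cv": {"device": (8.5, 2.1), "sham": (6.9, 2.3), "nf": (5.1, 1.7)},
    "comp_basic": {"device": (74.1, 7.2), "sham": (78.3, 6.7), "nf": (84.6, 5.9)},
    "comp_applied": {"device": (67.8, 8.4), "sham": (74.9, 7.5), "nf": (82.3, 6.8)},
    "comp_higher": {"device": (63.0, 10.1), "sham": (78.5, 9.3), "nf": (82.6, 7.1)},
    "rt_fu": {"device": (730.0, 30.1), "sham": (721.0, 27.6), "nf": (686.0, 25.8)},
    "delta_fi": {"device": (52.0, 11.0), "sham": (47.0, 9.0), "nf": (28.0, 8.0)},
    "rt_tc": {"device": (648.0, 28.0), "sham": (641.0, 27.0), "nf": (622.0, 25.0)},
    "acc_fi": {"device": (78.2, 6.1), "sham": (80.5, 5.7), "nf": (86.3, 4.9)},
    "acc_fu": {"device": (89.6, 4.8), "sham": (90.3, 4.6), "nf": (92.1, 4.0)},
    "acc_fp": {"device": (86.9, 5.4), "sham": (87.8, 5.1), "nf": (90.4, 4.5)},
    "acc_tc": {"device": (93.8, 3.6), "sham": (94.1, 3.4), "nf": (95.0, 3.0)},
    "tlx_mental": {"device": (72.1, 9.3), "sham": (66.4, 8.5), "nf": (55.0, 7.2)},
    "tlx_temporal": {"device": (58.3, 10.2), "sham": (56.7, 9.8), "nf": (54.9, 8.3)},
    "tlx_performance": {"device": (63.5, 7.5), "sham": (60.8, 6.9), "nf": (59.1, 6.3)},
    "tlx_effort": {"device": (68.5, 7.9), "sham": (63.8, 7.0), "nf": (52.4, 6.8)},
    "tlx_frustration": {"device": (61.2, 10.1), "sham": (58.7, 9.3), "nf": (46.5, 8.4)},
    "tlx_physical": {"device": (41.3, 6.5), "sham": (39.8, 5.7), "nf": (38.6, 5.2)},
    "strategy_effectiveness": {"device": (4.1, 1.7), "sham": (4.8, 1.5), "nf": (6.6, 0.5)},
    "strategy_frequency": {"device": (5.0, 1.0), "sham": (5.2, 1.1), "nf": (5.5, 1.3)},
}

#: FP − FU interference (ms): means from the reported FP/FU cells, SDs ≈10 ms
#: implied by the shared processing-speed factor.
DELTA_FP_MEANS = {"device": 15.0, "sham": 11.0, "nf": 17.0}
DELTA_FP_SD = 7.0

#: Target attention-comprehension correlation by condition.
DEFAULT_COUPLING = {"device": 0.12, "sham": 0.19, "nf": 0.63}

COMPREHENSION_SUBSCALES = ("comp_basic", "comp_applied", "comp_higher")
TLX_SUBSCALES = (
    "tlx_mental",
    "tlx_temporal",
    "tlx_performance",
    "tlx_effort",
    "tlx_frustration",
    "tlx_physical",
)

RT_FLOOR_MS = 200.0
TRIALS_PER_CELL = 20  # 2 (judgment) × 4 (type) design, 160 trials total
TRIAL_RT_SD_MS = 90.0


# ---------------------------------------------------------------------------
# EEG generation
# ---------------------------------------------------------------------------

@dataclass
class SynthEegSpec:
    """Recipe for one synthetic EEG session.

    ``band_amplitudes`` maps band name to a µV amplitude (scalar, or an
    envelope array of one value per sample).  Band oscillators are sinusoids
    at the band-center frequencies, so the analytic band-power target of a
    constant amplitude a is a²/2 µV².
    """

    duration_s: float
    sample_rate: float = config.SAMPLE_RATE_HZ
    channels: Tuple[str, ...] = config.DEFAULT_CHANNELS
    band_amplitudes: Mapping[str, float | np.ndarray] = field(
        default_factory=lambda: {"theta": 6.0, "alpha": 8.0, "beta": 5.0}
    )
    noise_exponent: float = 1.0
    noise_scale: float = 3.0
    line_hum_amplitude: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be positive")
        if self.sample_rate <= 0:
            raise ParameterError("sample_rate must be positive")
        top = max(
            [BAND_CENTER_HZ[b] for b, a in self.band_amplitudes.items() if np.any(np.asarray(a) > 0)]
            + ([config.NOTCH_HZ] if self.line_hum_amplitude > 0 else [0.0]),
            default=0.0,
        )
        if self.sample_rate <= 2 * top:
            raise ParameterError(
                f"sample_rate {self.sample_rate} must exceed twice the highest "
                f"synthesized frequency ({top} Hz)"
            )
        for band, amp in self.band_amplitudes.items():
            if band not in BAND_CENTER_HZ:
                raise ParameterError(f"unknown band {band!r}")
            if np.any(np.asarray(amp, dtype=float) < 0):
                raise ParameterError(f"{band} amplitude envelope must be non-negative")


def _pink_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Unit-variance Gaussian noise with a 1/f^exponent power spectrum."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shaping = np.ones_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_eeg(spec: SynthEegSpec) -> EegRecording:
    """Synthesize a multi-channel recording from a :class:`SynthEegSpec`.

    Each channel receives the band sinusoids (independent random phases),
    independent 1/f^α noise, and the common-phase 50 Hz hum.  The
    accelerometer trace is 1.0 g on the vertical axis (gravity) and zero on
    the horizontal axes.
    """
    spec.validate()
    n = int(round(spec.duration_s * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate
    rng = np.random.default_rng(spec.seed)
    samples = np.zeros((len(spec.channels), n))
    for ci in range(len(spec.channels)):
        for band, amp in spec.band_amplitudes.items():
            env = np.broadcast_to(np.asarray(amp, dtype=float), (n,))
            phase = rng.uniform(0, 2 * np.pi)
            samples[ci] += env * np.sin(2 * np.pi * BAND_CENTER_HZ[band] * t + phase)
        if spec.noise_scale > 0:
            samples[ci] += spec.noise_scale * _pink_noise(rng, n, spec.noise_exponent)
    if spec.line_hum_amplitude > 0:
        hum_phase = rng.uniform(0, 2 * np.pi)
        samples += spec.line_hum_amplitude * np.sin(2 * np.pi * config.NOTCH_HZ * t + hum_phase)
    accel = np.zeros((3, n))
    accel[2] = 1.0
    return EegRecording(
        sample_rate=spec.sample_rate,
        channel_labels=spec.channels,
        samples=samples,
        accel=accel,
    )


# ---------------------------------------------------------------------------
# artifact injection
# ---------------------------------------------------------------------------

@dataclass
class ArtifactEventSpec:
    """Motion events (onset s, duration ms, magnitude g) and amplitude events
    (onset s, channel label, peak µV) to inject into a recording."""

    motion_events: Sequence[Tuple[float, float, float]] = ()
    amplitude_events: Sequence[Tuple[float, str, float]] = ()
    seed: int = 0

    def validate(self, duration_s: float) -> None:
        for onset, dur_ms, mag in self.motion_events:
            if mag < 0:
                raise ParameterError("motion magnitude must be non-negative")
            if not 0 <= onset < duration_s:
                raise ParameterError(f"motion onset {onset} s outside session")
            if dur_ms <= 0:
                raise ParameterError("motion duration must be positive")
        for onset, _, peak in self.amplitude_events:
            if not 0 <= onset < duration_s:
                raise ParameterError(f"amplitude onset {onset} s outside session")
            if peak < 0:
                raise ParameterError("amplitude peak must be non-negative")


def inject_artifacts(rec: EegRecording, events: ArtifactEventSpec) -> EegRecording:
    """Return a copy of ``rec`` with the specified artifacts injected.

    Motion events add a step of the given magnitude to the vertical
    accelerometer axis over [onset, onset + duration).  Amplitude events add
    a 250 ms Hann pulse to the named channel scaled so the signal reaches
    exactly the requested peak µV at the pulse center; other samples are
    untouched.
    """
    events.validate(rec.duration_s)
    out = rec.copy()
    fs = rec.sample_rate
    n = rec.n_samples
    for onset, dur_ms, mag in events.motion_events:
        if out.accel is None:
            raise ParameterError("recording has no accelerometer trace")
        i0 = int(round(onset * fs))
        i1 = min(n, i0 + int(round(dur_ms / 1000.0 * fs)))
        out.accel[2, i0:i1] += mag
    for onset, channel, peak in events.amplitude_events:
        if channel not in rec.channel_labels:
            raise ParameterError(f"unknown channel label {channel!r}")
        ci = rec.channel_labels.index(channel)
        width = int(round(0.25 * fs))
        i0 = int(round(onset * fs))
        i1 = min(n, i0 + width)
        pulse = np.hanning(width)[: i1 - i0]
        center = i0 + int(np.argmax(pulse))
        bump = peak - out.samples[ci, center]
        out.samples[ci, i0:i1] += bump * pulse / pulse.max()
    return out


# ---------------------------------------------------------------------------
# behavioral study generation
# ---------------------------------------------------------------------------

@dataclass
class StudyEffectSpec:
    """Statistical recipe for the subject × condition behavioral dataset."""

    n_subjects: int = 30
    conditions: Tuple[str, ...] = CONDITIONS
    measures: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: STUDY_MEASURES
    )
    within_subject_corr: float = 0.5
    brain_behavior_coupling: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_COUPLING
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ParameterError("need at least 2 subjects")
        if not 0 <= self.within_subject_corr < 1:
            raise ParameterError("within-subject correlation must be in [0, 1)")
        for cond, r in self.brain_behavior_coupling.items():
            if not -1 < r < 1:
                raise ParameterError(f"coupling for {cond!r} must be in (-1, 1)")
        for name, cells in self.measures.items():
            for cond in self.conditions:
                if cond not in cells:
                    raise ParameterError(f"measure {name!r} lacks condition {cond!r}")
                if cells[cond][1] <= 0:
                    raise ParameterError(f"SD for {name}/{cond} must be positive")


def _subscale_loading(r_target: float, sds: Sequence[float]) -> float:
    """Latent-factor loading λ so that corr(mean of subscales, anchor) = r.

    Subscale s is λ·Ã + sqrt(1−λ²)·η_s with independent η; solving
    corr(T, A) = r for the total T gives
    λ² = r²·Σσ² / ((Σσ)² − r²·((Σσ)² − Σσ²)).
    """
    sds = np.asarray(sds, dtype=float)
    s1, s2 = sds.sum(), (sds**2).sum()
    denom = s1**2 - r_target**2 * (s1**2 - s2)
    lam2 = r_target**2 * s2 / denom
    return float(np.sign(r_target) * np.sqrt(lam2))


def _rm_standardized(
    rng: np.random.Generator, n: int, k: int, rho: float
) -> np.ndarray:
    """(n, k) unit-variance scores with correlation rho across the k columns
    (additive Gaussian subject intercept)."""
    z = rng.standard_normal(n)[:, None]
    e = rng.standard_normal((n, k))
    return np.sqrt(rho) * z + np.sqrt(1.0 - rho) * e


def generate_behavioral_dataset(spec: StudyEffectSpec) -> pd.DataFrame:
    """Long table (subject, condition, measure, value) for one simulated study.

    Construction: every measure gets unit-variance subject × condition scores
    with within-subject correlation ρ; the comprehension subscales load on
    the standardized attention index with a per-condition λ solved so the
    comprehension *total* correlates with attention at the coupling target;
    FI/FP reaction times share a per-subject processing-speed factor with the
    FU baseline so interference-effect SDs come out near the reported ≈10 ms.
    Derived rows (comp_total, tlx_total, rt_fi, rt_fp, delta_fp) are appended.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, conds = spec.n_subjects, list(spec.conditions)
    k = len(conds)
    rho = spec.within_subject_corr

    u: dict[str, np.ndarray] = {
        m: _rm_standardized(rng, n, k, rho) for m in spec.measures
    }
    # condition-specific latent coupling: comprehension subscales ride on the
    # standardized attention score
    has_subscales = all(s in u for s in COMPREHENSION_SUBSCALES)
    if "attention_mean" in u and has_subscales:
        att = u["attention_mean"]
        for j, cond in enumerate(conds):
            r = spec.brain_behavior_coupling.get(cond, 0.0)
            sds = [spec.measures[s][cond][1] for s in COMPREHENSION_SUBSCALES]
            lam = _subscale_loading(r, sds)
            for s in COMPREHENSION_SUBSCALES:
                u[s][:, j] = lam * att[:, j] + np.sqrt(1 - lam**2) * u[s][:, j]

    values: dict[str, np.ndarray] = {}
    for m, cells in spec.measures.items():
        mu = np.array([cells[c][0] for c in conds])
        sd = np.array([cells[c][1] for c in conds])
        values[m] = mu + sd * u[m]

    # additive RT structure: FI/FP = FU baseline + interference effect, which
    # makes FU the shared processing-speed factor (corr(FI, FU) ≈ 0.94) and
    # keeps interference-effect SDs near the reported ≈10 ms
    if "rt_fu" in values and "delta_fi" in values:
        values["rt_fi"] = values["rt_fu"] + values["delta_fi"]
        dfp_mu = np.array([DELTA_FP_MEANS.get(cnd, 0.0) for cnd in conds])
        delta_fp = dfp_mu + DELTA_FP_SD * _rm_standardized(rng, n, k, rho)
        values["delta_fp"] = delta_fp
        values["rt_fp"] = values["rt_fu"] + delta_fp

    for m in list(values):
        if m.startswith("rt_"):
            values[m] = np.maximum(values[m], RT_FLOOR_MS)
        elif m.startswith(("acc_", "tlx_", "comp_", "attention_mean")):
            values[m] = np.clip(values[m], 0.0, 100.0)

    if has_subscales:
        values["comp_total"] = np.mean([values[s] for s in COMPREHENSION_SUBSCALES], axis=0)
    if all(s in values for s in TLX_SUBSCALES):
        values["tlx_total"] = np.mean([values[s] for s in TLX_SUBSCALES], axis=0)

    records = []
    for m, arr in values.items():
        for i in range(n):
            for j, cond in enumerate(conds):
                records.append((i + 1, cond, m, float(arr[i, j])))
    return pd.DataFrame(records, columns=["subject", "condition", "measure", "value"])


def generate_awsit_trials(
    behavioral: pd.DataFrame,
    spec: StudyEffectSpec,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Trial-level AWSIT table from subject-level cell means.

    20 trials per subject × condition × trial type (160 per session); RTs are
    normal around the subject's cell mean, truncated at ≥ 200 ms; correctness
    is Bernoulli at the subject's cell accuracy.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    wide = behavioral.pivot_table(
        index=["subject", "condition"], columns="measure", values="value"
    )
    rows = []
    type_map = {"TC": ("rt_tc", "acc_tc"), "FI": ("rt_fi", "acc_fi"),
                "FU": ("rt_fu", "acc_fu"), "FP": ("rt_fp", "acc_fp")}
    for (subj, cond), cell in wide.iterrows():
        for tt, (rt_m, acc_m) in type_map.items():
            mu, acc = cell[rt_m], cell[acc_m] / 100.0
            a = (RT_FLOOR_MS - mu) / TRIAL_RT_SD_MS
            rts = st.truncnorm.rvs(
                a, np.inf, loc=mu, scale=TRIAL_RT_SD_MS, size=TRIALS_PER_CELL,
                random_state=rng,
            )
            correct = rng.random(TRIALS_PER_CELL) < acc
            for rt, ok in zip(rts, correct):
                rows.append((subj, cond, tt, float(rt), bool(ok)))
    return pd.DataFrame(rows, columns=["subject", "condition", "trial_type", "rt_ms", "correct"])


# ---------------------------------------------------------------------------
# full-study emulation
# ---------------------------------------------------------------------------

def _attention_to_band_amplitudes(attention_index: float) -> dict[str, float]:
    """Map a target attention index (0-100) to band oscillator amplitudes.

    Alpha/theta amplitudes are fixed; the beta amplitude is set so the
    analytic ratio beta²/(alpha²+theta²) increases linearly with the index.
    """
    a_alpha, a_theta = 8.0, 6.0
    ratio = 0.3 + 0.012 * attention_index
    a_beta = float(np.sqrt(ratio * (a_alpha**2 + a_theta**2)))
    return {"theta": a_theta, "alpha": a_alpha, "beta": a_beta}


@dataclass
class SessionSpec:
    """Per-session EEG recipe (realized lazily by :class:`StudyDataset`)."""

    subject: int
    condition: str
    day: int
    eeg: SynthEegSpec
    baseline_s: float
    artifacts: ArtifactEventSpec


@dataclass
class StudyDataset:
    """One fully reproducible simulated study.

    Behavioral and trial tables are materialized; session EEG is generated on
    demand from per-session seeds via :meth:`realize_session_eeg`.
    """

    seed: int
    condition_orders: pd.DataFrame
    behavioral: pd.DataFrame
    awsit_trials: pd.DataFrame
    session_specs: dict[tuple[int, str], SessionSpec]
    effect_spec: StudyEffectSpec

    def realize_session_eeg(
        self, subject: int, condition: str
    ) -> tuple[EegRecording, EegRecording]:
        """(baseline recording, learning-phase recording with artifacts)."""
        try:
            ss = self.session_specs[(subject, condition)]
        except KeyError:
            raise ParameterError(f"no session for subject {subject}, condition {condition!r}")
        baseline = generate_eeg(replace(ss.eeg, duration_s=ss.baseline_s, seed=ss.eeg.seed + 1))
        learning = inject_artifacts(generate_eeg(ss.eeg), ss.artifacts)
        return baseline, learning


def generate_full_study(
    seed: int,
    n_subjects: int = 30,
    baseline_s: float = 120.0,
    learning_s: float = 1800.0,
    effect_spec: StudyEffectSpec | None = None,
) -> StudyDataset:
    """Simulate the complete three-arm repeated-measures study.

    Condition order is counterbalanced: with n a multiple of 6, each of the 6
    orderings of (device, sham, nf) is assigned to exactly n/6 subjects.
    Each subject × condition session carries an EEG recipe whose beta power
    tracks the subject's sampled attention index, plus seeded motion and
    amplitude artifact events (about 2 per 5 minutes each).
    """
    root = np.random.SeedSequence(seed)
    s_effect, s_orders, s_sessions = root.spawn(3)
    if effect_spec is None:
        effect_spec = StudyEffectSpec(
            n_subjects=n_subjects, seed=int(s_effect.generate_state(1)[0] % 2**31)
        )
    behavioral = generate_behavioral_dataset(effect_spec)
    trials = generate_awsit_trials(behavioral, effect_spec)

    orders = list(itertools.permutations(effect_spec.conditions))
    reps = int(np.ceil(n_subjects / len(orders)))
    assignment = np.tile(np.arange(len(orders)), reps)[:n_subjects]
    rng_orders = np.random.default_rng(s_orders.generate_state(1)[0] % 2**31)
    assignment = rng_orders.permutation(assignment)
    order_rows = [
        {"subject": i + 1, "order": "-".join(orders[assignment[i]]),
         **{f"day{d + 2}": orders[assignment[i]][d] for d in range(3)}}
        for i in range(n_subjects)
    ]
    condition_orders = pd.DataFrame(order_rows)

    wide = behavioral.pivot_table(index=["subject", "condition"], columns="measure", values="value")
    session_specs: dict[tuple[int, str], SessionSpec] = {}
    session_seeds = s_sessions.generate_state(n_subjects * 3 * 2) % 2**31
    si = 0
    for i in range(n_subjects):
        for d, cond in enumerate(orders[assignment[i]]):
            att = float(wide.loc[(i + 1, cond), "attention_mean"])
            eeg = SynthEegSpec(
                duration_s=learning_s,
                band_amplitudes=_attention_to_band_amplitudes(att),
                seed=int(session_seeds[si]),
            )
            ev_rng = np.random.default_rng(int(session_seeds[si + 1]))
            rate = learning_s / 300.0  # ~2 events per 5 min
            motion = [
                (float(ev_rng.uniform(0, learning_s - 2)), float(ev_rng.uniform(520, 1500)),
                 float(ev_rng.uniform(0.55, 1.5)))
                for _ in range(ev_rng.poisson(2 * rate))
            ]
            amplitude = [
                (float(ev_rng.uniform(0, learning_s - 2)),
                 str(ev_rng.choice(config.FRONTAL_CHANNELS)),
                 float(ev_rng.uniform(110, 250)))
                for _ in range(ev_rng.poisson(2 * rate))
            ]
            session_specs[(i + 1, cond)] = SessionSpec(
                subject=i + 1,
                condition=cond,
                day=d + 2,
                eeg=eeg,
                baseline_s=baseline_s,
                artifacts=ArtifactEventSpec(motion_events=motion, amplitude_events=amplitude),
            )
            si += 2
    return StudyDataset(
        seed=seed,
        condition_orders=condition_orders,
        behavioral=behavioral,
        awsit_trials=trials,
        session_specs=session_specs,
        effect_spec=effect_spec,
    )
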