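# Methods

This note records the scientific and numerical choices behind `nfkit`: the
processing model, the synthetic-data generator's assumptions, parameter
defaults, and known limitations. It documents conventions, not results —
every number the package reports is computed at run time by the code.

## Signal path

**Filtering.** The analysis band is 4–40 Hz with a 50 Hz notch. The offline
path uses zero-phase (forward–backward) filtering with a 4th-order
Butterworth bandpass and a 2nd-order IIR notch (Q = 30); a single-pass
causal variant is available to emulate the real-time path, where phase lag
is part of the system being emulated. No filter family was prescribed by the
protocol; Butterworth was chosen for its flat passband (unity ±5% at 10 Hz),
and the notch yields far more than the required 20 dB at 50 Hz. Recordings
shorter than 3 s are rejected rather than filtered with unsettled edges.

**Band power.** Each spectral frame is a Hann-tapered periodogram of a
500 ms buffer with density scaling (normalized by Σw²), so Parseval holds
exactly: a pure in-band sinusoid of amplitude *a* contributes *a*²/2 µV² to
its band and white-noise band power is proportional to bandwidth. Band
edges are closed intervals on FFT bin centers; with 125-sample buffers the
bin spacing is 2 Hz, and bins in the 7–8 and 12–13 Hz gaps belong to no
band. The frontal composite averages band power across Fp1, Fp2, F3, F4
*before* forming the ratio (power averaging is variance-reducing; the
protocol left the composite unspecified).

**Frame clock.** 4 Hz updates with 500 ms buffers imply 50%-overlapping
windows stepped by 250 ms. At 250 Hz the step is 62.5 samples, so frames
are placed on the exact 0.25 s time grid and window start samples are
rounded; a 60 s recording yields 239 frames, the first stamped at t = 0.5 s
(buffer end). A frame whose buffer overlaps any excluded second is flagged
and omitted from every downstream mean. A frame with zero alpha+theta power
is marked invalid rather than given a fabricated ratio.

**Normalization.** The 0–100 index is a linear map of the individual's
baseline ratio range, clipped outside. Anchors are the 1st/99th percentiles
of the pooled Day-1 baseline ratio distribution (eyes closed + eyes open +
mental arithmetic) rather than min/max, which a single artifactual frame
would otherwise own. A constant baseline is a calibration error, not a
degenerate profile.

## Artifact gating

Two rules on 1 s epochs aligned to recording start (epoch k = [k, k+1) s):
accelerometer-magnitude deviation from baseline > 0.5 g sustained > 500 ms,
and |x| > 100 µV on any frontal channel. All three thresholds are strict
("more than", "exceeding"), so exact-boundary events do not flag. A motion
run flags every epoch it intersects, however slightly — conservative
exclusion is the simplest unambiguous rule. The accelerometer baseline is
the median of the first 10 s (the protocol says "baseline" without
definition; the median resists transient spikes). Gating operates on the
*recorded* signal, before the analysis bandpass, because the amplitude rule
refers to measured voltages that the bandpass would attenuate.

## Adaptive threshold controller

The initial threshold is the mean index of the eyes-open fixation segment.
Every 30 s epoch: mean above threshold increments the above-run (and zeroes
the below-run); three consecutive epochs above multiply the threshold by
1.05, three below by 0.95; a mean exactly at threshold resets both
counters. Thresholds are capped at 100. Choices the protocol left open:

* counters reset after a triggered adjustment — a new adjustment needs three
  fresh epochs, preventing oscillating double-triggers;
* a between-block break interrupts the "consecutive" run, so a constantly
  above-threshold learner triggers exactly ⌊10/3⌋ = 3 increases per 5-min
  block (10 epochs);
* fully excluded epochs are skipped without resetting counters — artifact
  gaps should not erase progress;
* days 2–4 freeze the Day-1 threshold; adaptation is described only for the
  Day-1 training session.

The feedback color reads the ±10% yellow band as *relative* to the
threshold (0.9·T to 1.1·T); red below, green above. The three-zone
partition takes precedence over a strict above/below reading, since
otherwise yellow would be unreachable from above. An absolute-points mode
(`band_mode="absolute"`) is available as a configuration switch.

## Outcome metrics

Truncation at mean ± 2 SD is implemented as winsorization (clamping) by
default: it preserves the 4 Hz time base that the subsequent 5 s sliding
average needs. A `drop` mode marks outliers excluded instead. Truncation
precedes smoothing. The sliding average is a centered 21-tap window
(±2.5 s inclusive at 4 Hz — an even tap count cannot be centered), shrinking
at edges and omitting excluded frames from each window's mean. CV uses the
sample SD (n−1). Interference RTs average correct trials only, standard in
conflict-RT paradigms. The comprehension total is the arithmetic mean of
the three subscales rounded half-up to one decimal. TLX totals follow the
raw-TLX convention (unweighted mean of six 0–100 subscales); no pairwise
weighting was described.

## Statistics

The RM-ANOVA is the classical one-factor within-subject decomposition with
uncorrected df (k−1, (n−1)(k−1)) by default — the reported integer dfs imply
no sphericity correction — with Greenhouse–Geisser available as an option.
η²p is computed from the identity F·df₁/(F·df₁+df₂) and asserted on every
result object. Pairwise tests are two-sided paired t-tests with
p·(number of pairs) capped at 1; a zero-variance pair is reported
non-significant with an explicit flag. All tests are two-sided.

**Sample size.** `required_sample_size` inverts the within-factors
noncentral-F power function: λ = f²·N·m·ε/(1−ρ), df₁ = (m−1)ε,
df₂ = (N−1)(m−1)ε. The routine reproduces the standard worked example of
this convention (f = 0.25, α = 0.05, power 0.95, m = 4, ρ = 0.5 → N = 36)
exactly. **Known discrepancy:** at the protocol's stated inputs (f = 0.25,
power 0.85, m = 3, ρ = 0.5, ε = 1) this convention requires N = 31, whereas
the protocol reports 28 — which is what the same convention returns for
target power 0.80 (power(28) = 0.813, power(27) = 0.796). The reported 28
and the stated 0.85 cannot both be right; `nfkit` computes the power
function faithfully and reports its honest result rather than reproducing
the inconsistent pair.

## Synthetic-data generator

**EEG.** Band oscillators are sinusoids at band-center frequencies (5.5,
10, 21.5 Hz) with per-band amplitude envelopes, so band-power targets are
analytic (a²/2). The floor is 1/f^α Gaussian noise (α = 1 by default,
scale 3 µV) plus optional 50 Hz hum (2 µV) that the notch must remove.
Default amplitudes (θ 6, α 8, β 5 µV) give a plausible resting ratio ≈ 0.25.
The accelerometer baseline is 1.0 g on the vertical axis (gravity); motion
events add a step to that axis. Amplitude artifacts are 250 ms Hann pulses
scaled so the channel reaches exactly the requested peak µV.

**Behavioral study.** Defaults are the reported per-condition cell means and
SDs for every measure: attention mean 55.2±7.1 / 59.0±8.4 / 67.4±7.8
(device / sham / neurofeedback), attention CV, comprehension subscales,
interference RTs and accuracy, TLX subscales, strategy ratings. Where the
printed SDs carry an obvious typographic stray digit ("±76.7"), the
single-digit reading (6.7) is used. Within-subject correlation is an
additive Gaussian subject intercept with ρ = 0.5, the conventional RM
power-analysis assumption. Three structural couplings:

* comprehension subscales load on the standardized attention score with a
  per-condition loading λ solved in closed form so the comprehension *total*
  correlates with attention at the target r (0.12 / 0.19 / 0.63); this keeps
  "total = mean of subscales" exactly true in generated data;
* false-unrelated (FU) RTs are the baseline and FI = FU + Δ with Δ drawn at
  the reported interference means/SDs (52±11 / 47±9 / 28±8 ms); FU means are
  FI − Δ (730/721/686 ms) and FU SDs are √(FI² − Δ²)-consistent, which
  reproduces both the FI SDs and the Δ SDs and implies the near-unavoidable
  r ≈ 0.94 subject speed factor between trial types;
* TC reaction times and TC/FU/FP accuracies are not reported; realistic
  fill-ins (TC ≈ 640 ms, accuracies 87–95%) were fixed once.

Trial-level AWSIT tables draw 20 trials per cell (160 per session) with
90 ms trial noise truncated at ≥ 200 ms and Bernoulli correctness at the
cell accuracy. TLX totals are the raw-TLX mean of the generated subscales;
the printed totals are not the mean of the printed subscales and are
treated as reported-only values.

`generate_full_study` assigns each of the 6 condition orders to exactly
n/6 subjects (counterbalancing), keeps the protocol's session durations as
defaults (120 s pre-task baseline, 1800 s learning), and realizes EEG
lazily per session so full-length sessions never need to be held in memory
at once; each session's beta amplitude tracks the subject's sampled
attention index. Everything derives from a single seed via spawned seed
sequences and is bit-reproducible. Tests and the CLI examples use shorter
session durations — the statistical structure being tested does not depend
on session length.

**What the generator does not emulate** — and hence what passing tests do
not show about real recordings: no volume conduction or head-model forward
projection (channels are independent up to the shared hum), no ERPs,
non-stationarities, eye blinks or EMG (artifacts are clean steps and
pulses), no learning dynamics within a session, and behavioral measures are
Gaussian by construction. The generator validates the *pipeline's*
arithmetic and its statistical calibration, not dry-EEG signal quality.

## Numerical conventions

Half-up decimal rounding for reported scores (banker's rounding would bias
.5 cases); strict inequalities at every gating boundary; frames stamped at
buffer end, epochs half-open at the start so each sample belongs to exactly
one epoch; 30 s controller epochs own frames in (t₀, t₀+30]; percentile
anchors use linear interpolation on the sample. EDF export quantizes to
16 bits over each channel's observed physical range; the reader is
validated against an independent third-party EDF decoder in the tests.

## Known limitations

* The real-time path is emulated (causal filters, frame-by-frame updates)
  but not scheduled in real time; latency is a hardware property and out of
  scope.
* Only the four frontal channels are used computationally; other channels
  are carried through untouched.
* The protocol's mention of an alternative channel set (Fp1, Fp2, Cz) for
  the analysis-phase index contradicts the frontal-composite definition
  stated twice elsewhere; the four-frontal-site definition is implemented.
* A raw-ratio "0.65 threshold" mentioned in the source material's
  introduction is on a scale incompatible with the 0–100 normalization and
  is not implemented.
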