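"""Protocol constants and pipeline configuration.

Every numeric constant of the published protocol lives here; no other module
hard-codes them.  Overriding a value in :class:`PipelineConfig` is how a run
deviates from the protocol, and the run manifest records the override.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Tuple

# --- spectral definitions (Hz) ---
THETA_BAND: Tuple[float, float] = (4.0, 7.0)
ALPHA_BAND: Tuple[float, float] = (8.0, 12.0)
BETA_BAND: Tuple[float, float] = (13.0, 30.0)
ANALYSIS_PASSBAND: Tuple[float, float] = (4.0, 40.0)
NOTCH_HZ = 50.0

# --- acquisition ---
SAMPLE_RATE_HZ = 250.0
FRONTAL_CHANNELS: Tuple[str, ...] = ("Fp1", "Fp2", "F3", "F4")
DEFAULT_CHANNELS: Tuple[str, ...] = ("Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4")

# --- streaming attention index ---
FFT_WINDOW_S = 0.5          # buffer length per spectral frame
UPDATE_RATE_HZ = 4.0        # feedback frame rate

# --- artifact gating ---
MOTION_THRESHOLD_G = 0.5    # strict: deviation must exceed this
MOTION_MIN_DURATION_S = 0.5  # strict: run must exceed this
AMPLITUDE_THRESHOLD_UV = 100.0  # strict: |x| must exceed this on a frontal channel
GATE_EPOCH_S = 1.0
ACCEL_BASELINE_WINDOW_S = 10.0

# --- adaptive threshold controller ---
CONTROLLER_EPOCH_S = 30.0
CONTROLLER_RUN_LENGTH = 3   # consecutive epochs required to trigger an adjustment
CONTROLLER_STEP_PCT = 5.0   # threshold moves by this percentage
FEEDBACK_BAND_PCT = 10.0    # yellow zone: within +/-10% of threshold
THRESHOLD_CAP = 100.0

# --- outcome metrics ---
TRUNCATION_SD = 2.0
SMOOTHING_WINDOW_S = 5.0

# --- baseline calibration ---
BASELINE_LOW_PERCENTILE = 1.0
BASELINE_HIGH_PERCENTILE = 99.0
MIN_BASELINE_FRAMES = 20


@dataclass
class PipelineConfig:
    """One namespace of tunables for a pipeline run.

    Defaults are the protocol's printed values; the manifest logs any override.
    """

    sample_rate: float = SAMPLE_RATE_HZ
    theta_band: Tuple[float, float] = THETA_BAND
    alpha_band: Tuple[float, float] = ALPHA_BAND
    beta_band: Tuple[float, float] = BETA_BAND
    passband: Tuple[float, float] = ANALYSIS_PASSBAND
    notch_hz: float = NOTCH_HZ
    fft_window_s: float = FFT_WINDOW_S
    update_rate_hz: float = UPDATE_RATE_HZ
    motion_threshold_g: float = MOTION_THRESHOLD_G
    motion_min_duration_s: float = MOTION_MIN_DURATION_S
    amplitude_threshold_uv: float = AMPLITUDE_THRESHOLD_UV
    controller_epoch_s: float = CONTROLLER_EPOCH_S
    controller_run_length: int = CONTROLLER_RUN_LENGTH
    controller_step_pct: float = CONTROLLER_STEP_PCT
    feedback_band_pct: float = FEEDBACK_BAND_PCT
    band_mode: str = "relative"          # yellow band relative to threshold | absolute points
    truncation_mode: str = "clamp"       # clamp (winsorize) | drop
    sphericity_correction: bool = False  # Greenhouse-Geisser on RM-ANOVA p-values
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def overrides(self) -> dict:
        """Fields that differ from the protocol defaults."""
        ref = PipelineConfig()
        return {k: v for k, v in self.to_dict().items() if v != getattr(ref, k)}
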