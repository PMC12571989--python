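"""File formats and run manifests.

CSV dialects (headers carry units):

* EEG long format: ``time_s, channel, microvolts`` — exact round trip;
* accelerometer: ``time_s, ax_g, ay_g, az_g``;
* attention series: ``time_s, raw_ratio, index, excluded``;
* exclusion mask: ``epoch_start_s, flagged, reason``;
* behavioral long format: ``subject, condition, measure, value``.

EEG can also be written/read as 16-bit EDF (one 1-s data record per second,
physical range per channel taken from the data), which quantizes samples to
(phys_max − phys_min)/65535 µV.  The EDF codec here is deliberately minimal:
EDF only, no EDF+ annotations.
"""

from __future__ import annotations

import datetime as _dt
import json
import struct
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from nfkit import config
from nfkit.artifacts import ExclusionMask
from nfkit.core import AttentionSeries, EegRecording, ConfigurationError, ParameterError

DIG_MIN, DIG_MAX = -32768, 32767


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def write_eeg_csv(rec: EegRecording, path) -> None:
    t = rec.times
    frames = [
        pd.DataFrame({"time_s": t, "channel": ch, "microvolts": rec.samples[i]})
        for i, ch in enumerate(rec.channel_labels)
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_eeg_csv(path, accel_path=None) -> EegRecording:
    df = pd.read_csv(path)
    required = {"time_s", "channel", "microvolts"}
    if not required.issubset(df.columns):
        raise ParameterError(f"{path}: EEG CSV needs columns {sorted(required)}")
    labels = list(dict.fromkeys(df["channel"]))
    series = {}
    t_ref = None
    for ch in labels:
        sub = df[df["channel"] == ch]
        t = sub["time_s"].to_numpy()
        if t_ref is None:
            t_ref = t
            if len(t) > 2:
                dt = np.diff(t)
                if not np.allclose(dt, dt[0], rtol=0, atol=1e-6):
                    raise ParameterError(f"{path}: non-uniform sampling")
        elif len(t) != len(t_ref):
            raise ParameterError(f"{path}: channel {ch!r} has inconsistent length")
        series[ch] = sub["microvolts"].to_numpy()
    fs = 1.0 / (t_ref[1] - t_ref[0])
    accel = None
    if accel_path is not None:
        accel = read_accel_csv(accel_path)
        if accel.shape[1] != len(t_ref):
            raise ParameterError("accelerometer trace length does not match EEG")
    return EegRecording(
        sample_rate=float(round(fs, 6)),
        channel_labels=tuple(labels),
        samples=np.vstack([series[ch] for ch in labels]),
        accel=accel,
        start_time=float(t_ref[0]),
    )


def write_accel_csv(rec: EegRecording, path) -> None:
    if rec.accel is None:
        raise ConfigurationError("recording carries no accelerometer trace")
    pd.DataFrame(
        {"time_s": rec.times, "ax_g": rec.accel[0], "ay_g": rec.accel[1], "az_g": rec.accel[2]}
    ).to_csv(path, index=False)


def read_accel_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    required = {"time_s", "ax_g", "ay_g", "az_g"}
    if not required.issubset(df.columns):
        raise ParameterError(f"{path}: accelerometer CSV needs columns {sorted(required)}")
    return df[["ax_g", "ay_g", "az_g"]].to_numpy().T


def write_series_csv(series: AttentionSeries, path) -> None:
    pd.DataFrame(
        {
            "time_s": series.timestamps,
            "raw_ratio": series.raw_ratio,
            "index": series.index,
            "excluded": series.excluded.astype(int),
        }
    ).to_csv(path, index=False)


def read_series_csv(path) -> AttentionSeries:
    df = pd.read_csv(path)
    return AttentionSeries(
        timestamps=df["time_s"].to_numpy(),
        raw_ratio=df["raw_ratio"].to_numpy(),
        index=df["index"].to_numpy(),
        excluded=df["excluded"].to_numpy().astype(bool),
    )


def write_mask_csv(mask: ExclusionMask, path) -> None:
    pd.DataFrame(
        {
            "epoch_start_s": np.arange(mask.n_epochs) * mask.epoch_length,
            "flagged": mask.flagged.astype(int),
            "reason": [r or "" for r in mask.reasons],
        }
    ).to_csv(path, index=False)


def read_mask_csv(path) -> ExclusionMask:
    df = pd.read_csv(path, keep_default_na=False)
    epoch_length = config.GATE_EPOCH_S
    if len(df) > 1:
        epoch_length = float(df["epoch_start_s"].iloc[1] - df["epoch_start_s"].iloc[0])
    return ExclusionMask(
        flagged=df["flagged"].to_numpy().astype(bool),
        reasons=np.array([str(r) for r in df["reason"]], dtype=object),
        epoch_length=epoch_length,
    )


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def _num(value, width: int) -> bytes:
    s = f"{value:.10g}"[:width]
    return _pad(s, width)


def write_edf(rec: EegRecording, path) -> None:
    """Write EEG channels as 16-bit EDF, one 1-s data record per second."""
    if abs(rec.sample_rate - round(rec.sample_rate)) > 1e-9:
        raise ParameterError("EDF export requires an integer sample rate")
    fs = int(round(rec.sample_rate))
    if rec.n_samples % fs != 0:
        raise ParameterError("EDF export requires a whole number of seconds")
    n_records = rec.n_samples // fs
    ns = len(rec.channel_labels)
    pmins = rec.samples.min(axis=1)
    pmaxs = rec.samples.max(axis=1)
    flat = pmaxs - pmins <= 0
    pmins[flat] -= 1.0
    pmaxs[flat] += 1.0
    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate X X X X", 80),
            _pad(now.strftime("%d.%m.%y"), 8),
            _pad(now.strftime("%H.%M.%S"), 8),
            _num(256 + ns * 256, 8),
            _pad("", 44),
            _num(n_records, 8),
            _num(1, 8),
            _num(ns, 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_pad(ch, 16) for ch in rec.channel_labels),
            b"".join(_pad("", 80) for _ in range(ns)),
            b"".join(_pad("uV", 8) for _ in range(ns)),
            b"".join(_num(pmins[i], 8) for i in range(ns)),
            b"".join(_num(pmaxs[i], 8) for i in range(ns)),
            b"".join(_num(DIG_MIN, 8) for _ in range(ns)),
            b"".join(_num(DIG_MAX, 8) for _ in range(ns)),
            b"".join(_pad("", 80) for _ in range(ns)),
            b"".join(_num(fs, 8) for _ in range(ns)),
            b"".join(_pad("", 32) for _ in range(ns)),
        ]
    )
    # physical→digital quantization; EDF loses sub-quantum precision by design
    gains = (pmaxs - pmins) / (DIG_MAX - DIG_MIN)
    digital = np.empty((ns, rec.n_samples), dtype="<i2")
    for i in range(ns):
        digital[i] = np.round((rec.samples[i] - pmins[i]) / gains[i] + DIG_MIN).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for r in range(n_records):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())


def read_edf(path, required_channels=None) -> EegRecording:
    """Read a 16-bit EDF file written by :func:`write_edf` (plain EDF only)."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ParameterError(f"{path}: truncated EDF header")
        n_records = int(head[236:244].decode("ascii").strip())
        record_s = float(head[244:252].decode("ascii").strip())
        ns = int(head[252:256].decode("ascii").strip())
        sig = fh.read(ns * 256)
        # signal header fields, each stored for all ns signals consecutively:
        # label 16, transducer 80, dim 8, pmin 8, pmax 8, dmin 8, dmax 8,
        # prefilter 80, samples-per-record 8, reserved 32
        off = 0
        widths = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]
        fields = []
        for w in widths:
            base = off
            fields.append(
                [sig[base + i * w : base + (i + 1) * w].decode("ascii").strip() for i in range(ns)]
            )
            off += w * ns
        labels = fields[0]
        pmin = np.array([float(v) for v in fields[3]])
        pmax = np.array([float(v) for v in fields[4]])
        dmin = np.array([float(v) for v in fields[5]])
        dmax = np.array([float(v) for v in fields[6]])
        nsamp = np.array([int(v) for v in fields[8]])
        if len(set(nsamp)) != 1:
            raise ParameterError(f"{path}: mixed per-channel sampling rates unsupported")
        spr = int(nsamp[0])
        data = np.frombuffer(fh.read(n_records * ns * spr * 2), dtype="<i2")
    data = data.reshape(n_records, ns, spr).transpose(1, 0, 2).reshape(ns, -1).astype(float)
    gains = (pmax - pmin) / (dmax - dmin)
    samples = (data - dmin[:, None]) * gains[:, None] + pmin[:, None]
    if required_channels:
        missing = [ch for ch in required_channels if ch not in labels]
        if missing:
            raise ConfigurationError(
                f"{path}: missing channel label(s): {', '.join(missing)}"
            )
    return EegRecording(
        sample_rate=spr / record_s,
        channel_labels=tuple(labels),
        samples=samples,
    )


def edf_quantization_step(rec: EegRecording) -> np.ndarray:
    """Per-channel physical quantum of a 16-bit EDF export of ``rec`` (µV)."""
    pmins = rec.samples.min(axis=1)
    pmaxs = rec.samples.max(axis=1)
    flat = pmaxs - pmins <= 0
    pmins[flat] -= 1.0
    pmaxs[flat] += 1.0
    return (pmaxs - pmins) / (DIG_MAX - DIG_MIN)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def read_eeg(path, accel_path=None, required_channels=None) -> EegRecording:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        rec = read_edf(path, required_channels=required_channels)
        if accel_path is not None:
            accel = read_accel_csv(accel_path)
            if accel.shape[1] != rec.n_samples:
                raise ParameterError("accelerometer trace length does not match EEG")
            rec.accel = accel
        return rec
    if path.suffix.lower() == ".csv":
        rec = read_eeg_csv(path, accel_path=accel_path)
        if required_channels:
            missing = [ch for ch in required_channels if ch not in rec.channel_labels]
            if missing:
                raise ConfigurationError(
                    f"{path}: missing channel label(s): {', '.join(missing)}"
                )
        return rec
    raise ParameterError(f"unknown EEG file extension {path.suffix!r} (use .edf or .csv)")


def write_eeg(rec: EegRecording, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        write_edf(rec, path)
    elif path.suffix.lower() == ".csv":
        write_eeg_csv(rec, path)
    else:
        raise ParameterError(f"unknown EEG file extension {path.suffix!r} (use .edf or .csv)")


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Reproducibility record emitted by every CLI stage."""

    stage: str
    seed: int | None
    config: dict = field(default_factory=dict)
    overrides: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    version: str = "0.1.0"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
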