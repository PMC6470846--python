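"""Reading, writing, validation and quantization of accelerometer recordings.

The on-disk dialect is a plain CSV with columns ``time, ax_g, ay_g, az_g,
temp_c[, label]``: a sample index (or seconds) time column, tri-axial
acceleration in g, a co-sampled skin temperature channel in °C and an
optional per-minute ground-truth label ("fall" / "non-fall") repeated across
the rows of its minute.  Temperature may be sampled sparsely (empty cells);
it is forward-filled onto the 100 Hz grid because only the per-window
minimum is ever consumed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

SAMPLE_RATE_HZ = 100
SAMPLES_PER_SLICE = 6000  # one-minute slices at 100 Hz

LABEL_FALL = "fall"
LABEL_NON_FALL = "non-fall"

REQUIRED_COLUMNS = ("time", "ax_g", "ay_g", "az_g", "temp_c")


class FormatError(ValueError):
    """Malformed recording file (missing columns, bad rows, bad labels)."""


class SequencingError(ValueError):
    """Time column is not strictly increasing."""


class SensorPosition(str, Enum):
    back = "back"
    abdomen = "abdomen"
    chest = "chest"


class StudyPhase(str, Enum):
    phase1 = "phase1"
    phase2 = "phase2"
    synthetic = "synthetic"


@dataclass
class RecordingMeta:
    """Provenance metadata; carried along but never used in computation."""

    subject_id: str
    sensor_position: SensorPosition = SensorPosition.back
    phase: StudyPhase = StudyPhase.synthetic

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValueError("subject_id must be non-empty")


@dataclass
class AccelRecording:
    """A time-ordered 100 Hz stream of tri-axial acceleration plus temperature.

    Parameters
    ----------
    ax, ay, az : ndarray
        Acceleration series in g.
    temperature : ndarray
        Skin/ambient temperature in °C, forward-filled to the sample grid.
    sample_rate_hz : int
        Fixed at 100 for the sensor modelled here.
    start_time : float
        Offset of the first sample in seconds (or an epoch); informational.
    labels : ndarray of str, optional
        One label per complete one-minute slice, ``floor(n_samples/6000)``
        entries, each "fall" or "non-fall".
    """

    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    temperature: np.ndarray
    sample_rate_hz: int = SAMPLE_RATE_HZ
    start_time: float = 0.0
    labels: Optional[np.ndarray] = None
    meta: Optional[RecordingMeta] = None

    def __post_init__(self) -> None:
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n = len(self.ax)
        for name, series in (("ay", self.ay), ("az", self.az),
                             ("temp_c", self.temperature)):
            if len(series) != n:
                raise FormatError(
                    f"series length mismatch: ax has {n} samples, "
                    f"{name} has {len(series)}")
        if self.labels is not None:
            expected = n // SAMPLES_PER_SLICE
            if len(self.labels) != expected:
                raise FormatError(
                    f"label series length {len(self.labels)} != "
                    f"floor(n_samples/{SAMPLES_PER_SLICE}) = {expected}")
            bad = set(self.labels) - {LABEL_FALL, LABEL_NON_FALL}
            if bad:
                raise FormatError(f"unknown label values: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return len(self.ax)

    @property
    def n_slices(self) -> int:
        return self.n_samples // SAMPLES_PER_SLICE

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def slice_label(self, index: int) -> Optional[str]:
        if self.labels is None:
            return None
        return self.labels[index]


def read_recording(path) -> AccelRecording:
    """Read a recording from the CSV dialect described in the module docstring.

    Raises
    ------
    FormatError
        If a required column is absent or values cannot be parsed; the error
        message names the column or the offending line number.
    SequencingError
        If the time column is not strictly increasing.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")

    for col in ("time", "ax_g", "ay_g", "az_g"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[values.isna() & df[col].notna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise FormatError(
                f"non-numeric value in column {col!r} at line {bad[0] + 2}")
        if col != "time" and values.isna().any():
            raise FormatError(
                f"missing value in column {col!r} at line "
                f"{int(values.index[values.isna()][0]) + 2}")
        df[col] = values

    t = df["time"].to_numpy()
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        i = int(np.argmax(np.diff(t) <= 0))
        raise SequencingError(
            f"time column not strictly increasing at line {i + 3}")

    temp = pd.to_numeric(df["temp_c"], errors="coerce").ffill().bfill()
    if len(df) and temp.isna().all():
        raise FormatError("temperature column temp_c contains no values")

    labels = None
    if "label" in df.columns and len(df) >= SAMPLES_PER_SLICE:
        n_slices = len(df) // SAMPLES_PER_SLICE
        labels = df["label"].to_numpy()[
            np.arange(n_slices) * SAMPLES_PER_SLICE]
        if pd.isna(labels).any():
            labels = None
        else:
            labels = labels.astype(object)

    return AccelRecording(
        ax=df["ax_g"].to_numpy(),
        ay=df["ay_g"].to_numpy(),
        az=df["az_g"].to_numpy(),
        temperature=temp.to_numpy(),
        start_time=float(t[0]) if len(t) else 0.0,
        labels=labels,
    )


def write_recording(rec: AccelRecording, path) -> None:
    """Write a recording as CSV, fixed column order, 6-decimal acceleration."""
    n = rec.n_samples
    data = {
        "time": np.arange(n),
        "ax_g": np.round(rec.ax, 6),
        "ay_g": np.round(rec.ay, 6),
        "az_g": np.round(rec.az, 6),
        "temp_c": np.round(rec.temperature, 4),
    }
    df = pd.DataFrame(data, columns=list(REQUIRED_COLUMNS))
    if rec.labels is not None:
        per_row = np.full(n, "", dtype=object)
        for i, lab in enumerate(rec.labels):
            per_row[i * SAMPLES_PER_SLICE:(i + 1) * SAMPLES_PER_SLICE] = lab
        df["label"] = per_row
    df.to_csv(path, index=False)


def quantize(rec: AccelRecording, bits: int = 10,
             full_scale_g: float = 8.0) -> AccelRecording:
    """Quantize acceleration to ``2**bits`` mid-tread levels over ±full_scale.

    Emulates the sensor front end (10-bit, ±8 g).  Levels are uniformly
    spaced with 0 g exactly representable; out-of-range values clip to the
    extreme levels.  Idempotent: quantizing twice equals quantizing once.
    """
    if bits < 2:
        raise ValueError("bits must be >= 2")
    if full_scale_g <= 0:
        raise ValueError("full_scale_g must be positive")
    step = 2.0 * full_scale_g / 2 ** bits
    lo, hi = -(2 ** (bits - 1)), 2 ** (bits - 1) - 1

    def q(x: np.ndarray) -> np.ndarray:
        return np.clip(np.round(x / step), lo, hi) * step

    return AccelRecording(
        ax=q(rec.ax), ay=q(rec.ay), az=q(rec.az),
        temperature=rec.temperature.copy(),
        sample_rate_hz=rec.sample_rate_hz,
        start_time=rec.start_time,
        labels=None if rec.labels is None else rec.labels.copy(),
        meta=rec.meta,
    )
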