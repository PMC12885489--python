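"""Raw oscillometry recordings and their on-disk CSV representation.

A recording is one subject-day of mouth pressure and airflow sampled on a
uniform time grid while a single-frequency (default 5 Hz) sinusoidal pressure
forcing is superimposed on spontaneous tidal breathing.  The sign convention
throughout the package is inspiratory flow positive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: required CSV columns, in order
CSV_COLUMNS = ("time_s", "pressure_cmH2O", "flow_Lps")

#: tolerance (seconds) for deviations from a uniform time grid
GRID_TOLERANCE_S = 1e-6

_FILENAME_RE = re.compile(r"^(?P<subject>.+)_d(?P<day>\d+)$")


class RecordingError(ValueError):
    """Malformed recording file or inconsistent recording arrays."""


@dataclass
class Recording:
    """One day's pressure/flow pair with sampling metadata.

    Attributes
    ----------
    subject_id : str
        Identifier of the subject the recording belongs to.
    day_index : int
        1-based index of the monitoring day.
    time : ndarray
        Uniform time grid in seconds from recording start.
    pressure : ndarray
        Mouth pressure in cmH2O.
    flow : ndarray
        Airflow in L/s, inspiration positive.
    sampling_rate : float
        Samples per second; must resolve the forcing sinusoid
        (>= 8 times the forcing frequency).
    """

    subject_id: str
    day_index: int
    time: np.ndarray
    pressure: np.ndarray
    flow: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        if not (len(self.time) == len(self.pressure) == len(self.flow)):
            raise RecordingError(
                "time, pressure and flow must have equal length "
                f"(got {len(self.time)}, {len(self.pressure)}, {len(self.flow)})"
            )
        if self.day_index < 1:
            raise RecordingError(f"day_index must be >= 1, got {self.day_index}")
        if self.sampling_rate <= 0:
            raise RecordingError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def filename(self) -> str:
        return f"{self.subject_id}_d{self.day_index}.csv"


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording to CSV with the canonical three-column header."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": rec.time,
            "pressure_cmH2O": rec.pressure,
            "flow_Lps": rec.flow,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_recording(
    path: str | Path,
    subject_id: str | None = None,
    day_index: int | None = None,
) -> Recording:
    """Read and validate a recording CSV.

    Subject id and day index default to the ``<subject>_d<day>.csv`` filename
    convention; pass them explicitly for files named otherwise.

    Raises
    ------
    RecordingError
        On a missing column, NaN sample (the offending row is named),
        non-monotone time, or a non-uniform time grid (tolerance 1e-6 s).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in CSV_COLUMNS:
        if col not in df.columns:
            raise RecordingError(f"{path.name}: missing required column '{col}'")
    for col in CSV_COLUMNS:
        bad = np.flatnonzero(~np.isfinite(df[col].to_numpy()))
        if bad.size:
            raise RecordingError(
                f"{path.name}: non-finite value in column '{col}' at row {bad[0]}"
            )
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise RecordingError(f"{path.name}: fewer than 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise RecordingError(f"{path.name}: time values are not strictly increasing")
    dt0 = (t[-1] - t[0]) / (len(t) - 1)
    if np.max(np.abs(dt - dt0)) > GRID_TOLERANCE_S:
        raise RecordingError(f"{path.name}: non-uniform time grid (tolerance 1e-6 s)")

    if subject_id is None or day_index is None:
        m = _FILENAME_RE.match(path.stem)
        if m is not None:
            subject_id = subject_id or m.group("subject")
            day_index = day_index or int(m.group("day"))
        else:
            subject_id = subject_id or path.stem
            day_index = day_index or 1

    return Recording(
        subject_id=subject_id,
        day_index=day_index,
        time=t,
        pressure=df["pressure_cmH2O"].to_numpy(dtype=float),
        flow=df["flow_Lps"].to_numpy(dtype=float),
        sampling_rate=1.0 / dt0,
    )
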