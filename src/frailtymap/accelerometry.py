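"""Tri-axial accelerometer gait recordings and dispersion measures.

A waist-worn accelerometer sampled during a gait-and-balance exercise
(e.g. the Tinetti test walk) yields three acceleration series.  The
gait contribution to the frailty assessment is a set of 20 dispersion
measures: six statistics per axis — arithmetic mean, sample standard
deviation, mean absolute deviation about the mean, variance, amplitude
(max − min) and the Pearson coefficient of variation sd/|mean| — plus
the mean and sample standard deviation of the acceleration magnitude
sqrt(ax² + ay² + az²).

Standard deviations and variances use the n−1 (sample) convention.
A coefficient of variation is undefined for a zero-mean axis and is
reported as missing for that axis, which is flagged, not fatal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, RecordingFormatError
from .patient import PatientInstance, VariableValue
from .schema import DISPERSION_VARIABLES

AXES = ("x", "y", "z")
_PER_AXIS_STATS = ("arithmetic_mean", "standard_deviation",
                   "absolute_mean_difference", "variance", "amplitude",
                   "pearson_cv")


@dataclass(frozen=True)
class GaitRecording:
    """One tri-axial recording: times in seconds, accelerations per axis."""

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    unit: str = "m/s2"
    sampling_rate: float = 0.0  # Hz; 0 means "infer from time steps"

    def __post_init__(self) -> None:
        n = len(self.t)
        if n < 2:
            raise InsufficientDataError("a recording needs at least 2 samples")
        if any(len(a) != n for a in (self.ax, self.ay, self.az)):
            raise RecordingFormatError("axis arrays must match the time axis")
        if np.any(np.diff(self.t) <= 0):
            raise RecordingFormatError("time must be strictly increasing")
        if self.sampling_rate == 0.0:
            inferred = 1.0 / float(np.median(np.diff(self.t)))
            object.__setattr__(self, "sampling_rate", inferred)

    def __len__(self) -> int:
        return len(self.t)

    def axis(self, name: str) -> np.ndarray:
        return {"x": self.ax, "y": self.ay, "z": self.az}[name]


@dataclass(frozen=True)
class PreprocessConfig:
    """Smoothing window (odd sample count) and end-trim duration."""

    smoothing_window: int = 5
    trim_seconds: float = 1.0

    def __post_init__(self) -> None:
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be a positive odd integer")
        if self.trim_seconds < 0:
            raise ValueError("trim_seconds must be non-negative")


@dataclass(frozen=True)
class DispersionMeasures:
    """The 20 named gait statistics for one recording.

    ``values`` maps each dispersion variable name to its value; a CV
    that is undefined (zero axis mean) is absent from the map and its
    axis listed in ``undefined_cv_axes``.
    """

    values: dict[str, float]
    undefined_cv_axes: tuple[str, ...] = field(default_factory=tuple)

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def load_recording(path: str) -> GaitRecording:
    """Read a ``time,x,y,z`` CSV; a ``# unit=...`` comment declares units."""
    unit = "m/s2"
    with open(path, encoding="utf-8") as fh:
        head = fh.readline()
        if head.startswith("#"):
            for part in head[1:].replace(",", " ").split():
                if part.startswith("unit="):
                    unit = {"g": "g0"}.get(part[5:], part[5:])
        fh.seek(0)
        frame = pd.read_csv(fh, comment="#")
    required = {"time", "x", "y", "z"}
    if not required.issubset(frame.columns):
        raise RecordingFormatError(
            f"recording needs columns {sorted(required)}, got {list(frame.columns)}")
    if len(frame) < 2:
        raise InsufficientDataError("recording has fewer than 2 rows")
    t = frame["time"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise RecordingFormatError("time column is not strictly increasing")
    return GaitRecording(t=t,
                         ax=frame["x"].to_numpy(dtype=float),
                         ay=frame["y"].to_numpy(dtype=float),
                         az=frame["z"].to_numpy(dtype=float),
                         unit=unit)


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge truncation (window shrinks at ends)."""
    if window == 1:
        return values.copy()
    half = window // 2
    cumsum = np.concatenate(([0.0], np.cumsum(values)))
    n = len(values)
    out = np.empty(n)
    for idx in range(n):
        lo = max(0, idx - half)
        hi = min(n, idx + half + 1)
        out[idx] = (cumsum[hi] - cumsum[lo]) / (hi - lo)
    return out


def preprocess(rec: GaitRecording,
               config: PreprocessConfig = PreprocessConfig()) -> GaitRecording:
    """Smooth each axis with a centered moving average, then trim both ends.

    Trimming removes ``trim_seconds`` from the start and from the end
    of the recording (start-up and slow-down artefacts of the walk).
    """
    keep = ((rec.t >= rec.t[0] + config.trim_seconds)
            & (rec.t <= rec.t[-1] - config.trim_seconds))
    if int(keep.sum()) < 2:
        raise InsufficientDataError("trimming leaves fewer than 2 samples")
    smoothed = {axis: _moving_average(rec.axis(axis), config.smoothing_window)
                for axis in AXES}
    return GaitRecording(t=rec.t[keep],
                         ax=smoothed["x"][keep],
                         ay=smoothed["y"][keep],
                         az=smoothed["z"][keep],
                         unit=rec.unit,
                         sampling_rate=rec.sampling_rate)


def compute_dispersion_measures(rec: GaitRecording) -> DispersionMeasures:
    """Compute the 20 dispersion measures of a (preprocessed) recording."""
    values: dict[str, float] = {}
    undefined: list[str] = []
    for axis in AXES:
        a = rec.axis(axis)
        mean = float(np.mean(a))
        sd = float(np.std(a, ddof=1))
        values[f"{axis}_arithmetic_mean"] = mean
        values[f"{axis}_standard_deviation"] = sd
        values[f"{axis}_absolute_mean_difference"] = float(np.mean(np.abs(a - mean)))
        values[f"{axis}_variance"] = sd * sd
        values[f"{axis}_amplitude"] = float(np.max(a) - np.min(a))
        if mean == 0.0:
            if sd == 0.0:
                values[f"{axis}_pearson_cv"] = 0.0
            else:
                undefined.append(axis)
        else:
            values[f"{axis}_pearson_cv"] = sd / abs(mean)
    magnitude = np.sqrt(rec.ax ** 2 + rec.ay ** 2 + rec.az ** 2)
    values["acceleration_mean"] = float(np.mean(magnitude))
    values["acceleration_sd"] = float(np.std(magnitude, ddof=1))
    return DispersionMeasures(values=values, undefined_cv_axes=tuple(undefined))


def attach_to_instance(instance: PatientInstance,
                       dm: DispersionMeasures) -> PatientInstance:
    """Set the 20 dispersion variables of an instance from a recording.

    Existing dispersion values are overwritten; every other variable is
    untouched.  An undefined CV stays missing for its axis.
    """
    updates = {}
    for name in DISPERSION_VARIABLES:
        if name in dm.values:
            updates[name] = VariableValue.present(float(dm.values[name]))
        else:
            updates[name] = VariableValue.missing()
    merged = dict(instance.values)
    for name, vv in updates.items():
        if vv.is_present:
            merged[name] = vv
        else:
            merged.pop(name, None)
    return PatientInstance(patient_id=instance.patient_id,
                           instance_id=instance.instance_id,
                           iteration=instance.iteration,
                           sex=instance.sex, age=instance.age,
                           values=merged)


def _check_names() -> None:
    expected = set(DISPERSION_VARIABLES)
    produced = {f"{axis}_{stat}" for axis in AXES for stat in _PER_AXIS_STATS}
    produced |= {"acceleration_mean", "acceleration_sd"}
    assert produced == expected and len(expected) == 20


_check_names()
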