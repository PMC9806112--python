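"""Domain types and dataset I/O for two-arm wrist-IMU recordings.

The study dataset is a flat CSV table, one row per 50 Hz timestamp, holding
triaxial accelerometer (g), gyroscope (deg/s) and magnetometer (a.u.)
channels for each arm, plus four binary functional-use annotation tracks
(two annotators x two passes), a task track and a movement-type track.
This module defines the in-memory containers, the CSV reader/writer,
zero-order-hold resampling and the majority-vote ground-truth consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "ImuRecording",
    "AnnotationSet",
    "UseSignal",
    "ArmData",
    "SubjectDataset",
    "CSV_COLUMNS",
    "read_dataset",
    "write_dataset",
    "resample_zoh",
    "consensus_label",
]


class SchemaError(ValueError):
    """A dataset file does not match the documented CSV schema."""


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


#: Documented CSV schema: one row per 50 Hz timestamp.
CSV_COLUMNS = [
    "subject", "group", "arm", "time",
    "ax", "ay", "az", "gx", "gy", "gz", "mx", "my", "mz",
    "use_a1p1", "use_a1p2", "use_a2p1", "use_a2p2",
    "task", "movement_type",
]

USE_TRACKS = ["use_a1p1", "use_a1p2", "use_a2p1", "use_a2p2"]

ARM_LABELS = ("left", "right", "affected", "unaffected")


@dataclass
class ImuRecording:
    """Per-arm IMU time series.

    Parameters
    ----------
    timestamps : (N,) float array, seconds, strictly increasing.
    accel : (N, 3) array in g.
    gyro : (N, 3) array in deg/s.
    mag : (N, 3) array in arbitrary units, or None for 6-DOF data.
    nominal_rate : nominal sampling rate in Hz.
    arm_label : one of ``left, right, affected, unaffected``.
    """

    timestamps: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    mag: np.ndarray | None = None
    nominal_rate: float = 50.0
    arm_label: str = "right"

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.mag is not None:
            self.mag = np.asarray(self.mag, dtype=float)
        n = len(self.timestamps)
        if n == 0:
            raise ValidationError("recording is empty")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValidationError("timestamps must be strictly increasing")
        for name, arr in (("accel", self.accel), ("gyro", self.gyro),
                          ("mag", self.mag)):
            if arr is None:
                continue
            if arr.shape != (n, 3):
                raise ValidationError(
                    f"{name} must have shape ({n}, 3), got {arr.shape}")
        if self.nominal_rate <= 0:
            raise ValidationError("nominal_rate must be > 0")
        if self.arm_label not in ARM_LABELS:
            raise ValidationError(f"unknown arm_label {self.arm_label!r}")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def duration(self) -> float:
        """Covered duration in seconds (span + one nominal sample period)."""
        return float(self.timestamps[-1] - self.timestamps[0]
                     + 1.0 / self.nominal_rate)


@dataclass
class AnnotationSet:
    """Annotation tracks sharing one timestamp grid.

    ``use_tracks`` is an (N, 4) binary array: annotator 1 pass 1/2,
    annotator 2 pass 1/2. ``task_track`` and ``movement_type_track`` are
    length-N object arrays of strings (movement type in
    ``{Arm, Hand, NonFunctional}``).
    """

    timestamps: np.ndarray
    use_tracks: np.ndarray
    task_track: np.ndarray
    movement_type_track: np.ndarray
    rate: float = 30.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.use_tracks = np.asarray(self.use_tracks)
        n = len(self.timestamps)
        if self.use_tracks.shape != (n, 4):
            raise ValidationError(
                f"use_tracks must have shape ({n}, 4), got {self.use_tracks.shape}")
        if not np.isin(self.use_tracks, (0, 1)).all():
            raise ValidationError("use_tracks values must be binary")
        for name, arr in (("task_track", self.task_track),
                          ("movement_type_track", self.movement_type_track)):
            if len(arr) != n:
                raise ValidationError(f"{name} length {len(arr)} != {n}")

    def __len__(self) -> int:
        return len(self.timestamps)

    def consensus(self) -> np.ndarray:
        """Majority-vote ground truth across the four tracks (tie -> 0)."""
        return consensus_label(self.use_tracks)


@dataclass
class UseSignal:
    """Binary upper-limb-use series at a measure-specific rate."""

    timestamps: np.ndarray
    values: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=int)
        if len(self.timestamps) != len(self.values):
            raise ValidationError("timestamps and values lengths differ")
        if not np.isin(self.values, (0, 1)).all():
            raise ValidationError("use values must be binary")
        if self.rate <= 0:
            raise ValidationError("rate must be > 0")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ArmData:
    """One arm's recording together with its annotations."""

    recording: ImuRecording
    annotations: AnnotationSet


@dataclass
class SubjectDataset:
    """Both arms of one subject.

    For controls the arms are labelled ``left``/``right`` (right assumed
    dominant); for patients ``affected``/``unaffected``.
    """

    subject_id: str
    group: str
    arms: dict[str, ArmData] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("control", "patient"):
            raise ValidationError(f"unknown group {self.group!r}")
        if len(self.arms) != 2:
            raise ValidationError("both arms must be present")
        expected = {"left", "right"} if self.group == "control" \
            else {"affected", "unaffected"}
        if set(self.arms) != expected:
            raise ValidationError(
                f"arm labels {set(self.arms)} inconsistent with group "
                f"{self.group!r} (expected {expected})")

    @property
    def dominant(self) -> ArmData:
        """Dominant (control) or unaffected (patient) arm."""
        return self.arms["right" if self.group == "control" else "unaffected"]

    @property
    def nondominant(self) -> ArmData:
        """Non-dominant (control) or affected (patient) arm."""
        return self.arms["left" if self.group == "control" else "affected"]


# ---------------------------------------------------------------------------
# Resampling and consensus

def resample_zoh(timestamps, values, target_rate: float):
    """Resample a time series onto a uniform grid by zero-order hold.

    The output grid starts at the first input timestamp and steps by
    ``1/target_rate`` up to the last input timestamp. Each output sample is
    the most recent input value at or before its grid time, so the output
    never contains values absent from the input.

    Returns ``(grid_timestamps, grid_values)``.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    values = np.asarray(values)
    if len(timestamps) == 0:
        raise ValidationError("cannot resample an empty series")
    if len(timestamps) != len(values):
        raise ValidationError("timestamps and values lengths differ")
    if np.any(np.diff(timestamps) <= 0):
        raise ValidationError("timestamps must be strictly increasing")
    step = 1.0 / float(target_rate)
    n_out = int(np.floor((timestamps[-1] - timestamps[0]) / step + 1e-9)) + 1
    grid = timestamps[0] + step * np.arange(n_out)
    idx = np.searchsorted(timestamps, grid + 1e-12, side="right") - 1
    idx = np.clip(idx, 0, len(timestamps) - 1)
    return grid, values[idx]


def consensus_label(labels) -> np.ndarray:
    """Majority vote over four binary annotation labels; 2-2 ties -> 0.

    ``labels`` is either a length-4 vector (one instant) or an (N, 4)
    array. Returns an int scalar/array of the consensus.
    """
    arr = np.asarray(labels)
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError("consensus labels must be binary")
    scalar = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] != 4:
        raise ValidationError("consensus expects exactly 4 labels per instant")
    out = (arr.sum(axis=1) > 2).astype(int)
    return int(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# CSV I/O

def write_dataset(subjects: list[SubjectDataset], path) -> None:
    """Write subjects to the flat CSV schema.

    Annotation tracks are upsampled to the sensor grid by zero-order hold
    before writing, so one row fully describes one 50 Hz instant.
    """
    frames = []
    for subj in subjects:
        for arm_label, arm in subj.arms.items():
            rec, ann = arm.recording, arm.annotations
            n = len(rec)
            cols: dict[str, object] = {
                "subject": np.repeat(subj.subject_id, n),
                "group": np.repeat(subj.group, n),
                "arm": np.repeat(arm_label, n),
                "time": rec.timestamps,
            }
            for i, c in enumerate(("ax", "ay", "az")):
                cols[c] = rec.accel[:, i]
            for i, c in enumerate(("gx", "gy", "gz")):
                cols[c] = rec.gyro[:, i]
            mag = rec.mag if rec.mag is not None else np.full((n, 3), np.nan)
            for i, c in enumerate(("mx", "my", "mz")):
                cols[c] = mag[:, i]
            for j, c in enumerate(USE_TRACKS):
                _, v = resample_zoh(ann.timestamps, ann.use_tracks[:, j],
                                    rec.nominal_rate)
                cols[c] = _fit_length(v, n)
            _, task = resample_zoh(ann.timestamps, ann.task_track,
                                   rec.nominal_rate)
            cols["task"] = _fit_length(task, n)
            _, mt = resample_zoh(ann.timestamps, ann.movement_type_track,
                                 rec.nominal_rate)
            cols["movement_type"] = _fit_length(mt, n)
            frames.append(pd.DataFrame(cols))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _fit_length(values: np.ndarray, n: int) -> np.ndarray:
    """Pad (by repeating the last value) or truncate to length n."""
    if len(values) >= n:
        return values[:n]
    pad = np.repeat(values[-1], n - len(values))
    return np.concatenate([values, pad])


def read_dataset(path) -> list[SubjectDataset]:
    """Read the flat CSV schema back into one SubjectDataset per subject."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    subjects = []
    for sid, sdf in df.groupby("subject", sort=False):
        groups = sdf["group"].unique()
        if len(groups) != 1:
            raise SchemaError(f"subject {sid!r} has inconsistent group labels")
        arms = {}
        for arm_label, adf in sdf.groupby("arm", sort=False):
            t = adf["time"].to_numpy(dtype=float)
            if np.any(np.diff(t) <= 0):
                raise ValidationError(
                    f"non-monotone timestamps for subject {sid!r} arm {arm_label!r}")
            rate = _infer_rate(t)
            mag = adf[["mx", "my", "mz"]].to_numpy(dtype=float)
            rec = ImuRecording(
                timestamps=t,
                accel=adf[["ax", "ay", "az"]].to_numpy(dtype=float),
                gyro=adf[["gx", "gy", "gz"]].to_numpy(dtype=float),
                mag=None if np.isnan(mag).all() else mag,
                nominal_rate=rate,
                arm_label=str(arm_label),
            )
            ann = AnnotationSet(
                timestamps=t,
                use_tracks=adf[USE_TRACKS].to_numpy(dtype=int),
                task_track=adf["task"].to_numpy(dtype=object),
                movement_type_track=adf["movement_type"].to_numpy(dtype=object),
                rate=rate,
            )
            arms[str(arm_label)] = ArmData(rec, ann)
        subjects.append(SubjectDataset(str(sid), str(groups[0]), arms))
    return subjects


def _infer_rate(timestamps: np.ndarray) -> float:
    if len(timestamps) < 2:
        return 50.0
    return float(round(1.0 / np.median(np.diff(timestamps))))
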