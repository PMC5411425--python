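"""Trial I/O, movement segmentation, and fixed-length velocity profiles.

A grasp trial is a short multi-joint recording of hand joint angles (degrees)
sampled at a fixed rate (125 Hz for the reference glove).  The processing
chain implemented here is:

1. differentiate angles to angular velocities (deg/s),
2. segment the movement window — from the first to the last time any joint's
   absolute velocity reaches a fraction (default 5%) of the peak velocity,
3. zero-pad the segmented window at the tail to a fixed length
   (default 151 samples, i.e. 1.208 s at 125 Hz, the longest grasp observed).

Trial files are plain CSV (one row per sample) or an HDF5 container for bulk
storage; see :func:`read_trials` / :func:`write_trials`.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

from .errors import (
    InvalidInputError,
    NoMovementError,
    OverlongTrialError,
    ShapeError,
    TrialParseError,
)
from .joints import JOINT_NAMES, N_JOINTS

DEFAULT_RATE: float = 125.0
#: Fixed profile length: round(1.208 s * 125 Hz) = 151 samples.
DEFAULT_LENGTH: int = 151
DEFAULT_THRESHOLD_FRACTION: float = 0.05

CSV_META_COLUMNS = ("subject", "object", "grasp_type", "repetition", "t")


@dataclass
class RawRecording:
    """One labelled recording of joint angles over time.

    Parameters
    ----------
    angles:
        ``(T, 10)`` array of joint angles in degrees, canonical joint order.
    rate:
        Sampling rate in samples/second.
    """

    angles: np.ndarray
    rate: float = DEFAULT_RATE
    subject_id: str = ""
    object_id: str = ""
    grasp_type: str = ""
    repetition: int = 0

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2 or self.angles.shape[1] != N_JOINTS:
            raise ShapeError(
                f"angles must be (T, {N_JOINTS}); got {self.angles.shape}"
            )
        if self.angles.shape[0] < 2:
            raise InvalidInputError("recording needs at least 2 time samples")
        if not np.all(np.isfinite(self.angles)):
            raise InvalidInputError("angles must be finite")
        if not self.rate > 0:
            raise InvalidInputError("sampling rate must be positive")

    @property
    def labels(self) -> tuple[str, str, str, int]:
        return (self.subject_id, self.object_id, self.grasp_type, self.repetition)


@dataclass
class GraspTrial:
    """A segmented movement: velocities from movement onset to completion."""

    velocity: np.ndarray  # (T, 10) deg/s
    onset_index: int
    offset_index: int
    rate: float = DEFAULT_RATE
    subject_id: str = ""
    object_id: str = ""
    grasp_type: str = ""
    repetition: int = 0

    def __post_init__(self):
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.velocity.ndim != 2 or self.velocity.shape[1] != N_JOINTS:
            raise ShapeError(
                f"velocity must be (T, {N_JOINTS}); got {self.velocity.shape}"
            )
        if self.offset_index < self.onset_index:
            raise InvalidInputError("offset must be >= onset")

    def __len__(self) -> int:
        return self.velocity.shape[0]


@dataclass
class FixedProfile:
    """A trial's velocities zero-padded at the tail to a fixed length."""

    velocity: np.ndarray  # (L, 10) deg/s
    rate: float = DEFAULT_RATE
    subject_id: str = ""
    object_id: str = ""
    grasp_type: str = ""
    repetition: int = 0

    def __post_init__(self):
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.velocity.ndim != 2 or self.velocity.shape[1] != N_JOINTS:
            raise ShapeError(f"velocity must be (L, {N_JOINTS})")

    @property
    def length(self) -> int:
        return self.velocity.shape[0]

    def flattened(self) -> np.ndarray:
        """Joint-major flattening: joint 1 samples 1..L, then joint 2, ..."""
        return self.velocity.T.reshape(-1)


def compute_velocity(recording: RawRecording) -> np.ndarray:
    """Angular velocities (deg/s) by central differences, one-sided at the ends.

    Returns an array with the same shape as ``recording.angles``.
    """
    if recording.angles.shape[0] < 2:
        raise InvalidInputError("need at least 2 samples to differentiate")
    return np.gradient(recording.angles, axis=0) * recording.rate


def segment_velocity(
    velocity: np.ndarray,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    onset_mode: str = "global",
) -> tuple[int, int]:
    """Find the movement window on a ``(T, 10)`` velocity array.

    ``onset_mode='global'`` (default): the peak is the maximum of |velocity|
    over all joints jointly and the window runs from the first to the last
    sample where *any* joint reaches ``threshold_fraction`` of that peak.
    ``onset_mode='per_joint'``: each joint is thresholded against its own
    peak before the any-joint union is taken.
    """
    speed = np.abs(np.asarray(velocity, dtype=float))
    if onset_mode == "global":
        peak = speed.max()
        if peak == 0.0:
            raise NoMovementError("all-zero velocity: no movement to segment")
        active = (speed >= threshold_fraction * peak).any(axis=1)
    elif onset_mode == "per_joint":
        peaks = speed.max(axis=0)
        if not np.any(peaks > 0):
            raise NoMovementError("all-zero velocity: no movement to segment")
        thresh = threshold_fraction * peaks
        active = (speed >= thresh[None, :]).any(axis=1)
    else:
        raise InvalidInputError(f"unknown onset_mode {onset_mode!r}")
    idx = np.flatnonzero(active)
    return int(idx[0]), int(idx[-1])


def segment_trial(
    recording: RawRecording,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    onset_mode: str = "global",
    smooth_window: int | None = None,
) -> GraspTrial:
    """Extract the movement window from a recording.

    ``smooth_window`` optionally applies a centred moving average (in samples)
    to the velocities before thresholding and extraction; off by default.
    """
    velocity = compute_velocity(recording)
    if smooth_window is not None and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        velocity = np.apply_along_axis(
            lambda x: np.convolve(x, kernel, mode="same"), 0, velocity
        )
    onset, offset = segment_velocity(velocity, threshold_fraction, onset_mode)
    return GraspTrial(
        velocity=velocity[onset : offset + 1],
        onset_index=onset,
        offset_index=offset,
        rate=recording.rate,
        subject_id=recording.subject_id,
        object_id=recording.object_id,
        grasp_type=recording.grasp_type,
        repetition=recording.repetition,
    )


def pad_to_fixed(trial: GraspTrial, length: int = DEFAULT_LENGTH) -> FixedProfile:
    """Zero-pad a trial at the tail to exactly ``length`` rows."""
    T = len(trial)
    if T > length:
        raise OverlongTrialError(
            f"trial has {T} samples, exceeding the fixed length {length}; "
            "raise the configured maximum"
        )
    velocity = np.zeros((length, N_JOINTS))
    velocity[:T] = trial.velocity
    return FixedProfile(
        velocity=velocity,
        rate=trial.rate,
        subject_id=trial.subject_id,
        object_id=trial.object_id,
        grasp_type=trial.grasp_type,
        repetition=trial.repetition,
    )


# ---------------------------------------------------------------------------
# Trial file I/O
# ---------------------------------------------------------------------------

def write_trials(recordings: list[RawRecording], path) -> None:
    """Write recordings to a CSV session file.

    Columns: subject, object, grasp_type, repetition, t, then the ten joint
    columns in canonical order.  ``t`` is the sample time in seconds, which
    encodes the sampling rate.
    """
    frames = []
    for rec in recordings:
        n = rec.angles.shape[0]
        df = pd.DataFrame(rec.angles, columns=list(JOINT_NAMES))
        df.insert(0, "t", np.arange(n) / rec.rate)
        df.insert(0, "repetition", rec.repetition)
        df.insert(0, "grasp_type", rec.grasp_type)
        df.insert(0, "object", rec.object_id)
        df.insert(0, "subject", rec.subject_id)
        frames.append(df)
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=list(CSV_META_COLUMNS) + list(JOINT_NAMES))
    out.to_csv(path, index=False)


def read_trials(path, rate: float | None = None) -> list[RawRecording]:
    """Read recordings from a CSV session file written by :func:`write_trials`.

    The sampling rate is recovered from the spacing of the ``t`` column
    (rounded to 1e-6) unless ``rate`` overrides it.  An empty file yields an
    empty list.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in list(CSV_META_COLUMNS) + list(JOINT_NAMES) if c not in df.columns]
    if missing:
        raise TrialParseError(f"missing columns: {missing}")
    if df.empty:
        return []
    for col in ("subject", "object", "grasp_type"):
        df[col] = df[col].fillna("")
    numeric_cols = ["t"] + list(JOINT_NAMES)
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if df[col].isna().any() or bad.any():
            row = int(np.flatnonzero(df[col].isna() | bad)[0])
            raise TrialParseError(f"non-numeric cell in column {col!r} at row {row}")
        df[col] = coerced

    recordings = []
    keys = (
        df["subject"].astype(str)
        + "\x00" + df["object"].astype(str)
        + "\x00" + df["grasp_type"].astype(str)
        + "\x00" + df["repetition"].astype(str)
    )
    for _, group in df.groupby(keys.values, sort=False):
        t = group["t"].to_numpy()
        if rate is not None:
            r = float(rate)
        elif len(t) > 1 and t[-1] > t[0]:
            r = round((len(t) - 1) / (t[-1] - t[0]), 6)
        else:
            r = DEFAULT_RATE
        recordings.append(
            RawRecording(
                angles=group[list(JOINT_NAMES)].to_numpy(),
                rate=r,
                subject_id=str(group["subject"].iloc[0]),
                object_id=str(group["object"].iloc[0]),
                grasp_type=str(group["grasp_type"].iloc[0]),
                repetition=int(group["repetition"].iloc[0]),
            )
        )
    return recordings


def save_trials_h5(recordings: list[RawRecording], path) -> None:
    """HDF5 bulk storage: /subjects/<id>/trials/<n> with label attributes."""
    with h5py.File(path, "w") as f:
        counters: dict[str, int] = {}
        for rec in recordings:
            sid = rec.subject_id or "_"
            n = counters.get(sid, 0)
            counters[sid] = n + 1
            ds = f.create_dataset(f"/subjects/{sid}/trials/{n}", data=rec.angles)
            ds.attrs["rate"] = rec.rate
            ds.attrs["subject"] = rec.subject_id
            ds.attrs["object"] = rec.object_id
            ds.attrs["grasp_type"] = rec.grasp_type
            ds.attrs["repetition"] = rec.repetition


def load_trials_h5(path) -> list[RawRecording]:
    recordings = []
    with h5py.File(path, "r") as f:
        if "subjects" not in f:
            return []
        for sid in f["subjects"]:
            trials = f[f"subjects/{sid}/trials"]
            for n in sorted(trials, key=int):
                ds = trials[n]
                recordings.append(
                    RawRecording(
                        angles=ds[()],
                        rate=float(ds.attrs["rate"]),
                        subject_id=str(ds.attrs["subject"]),
                        object_id=str(ds.attrs["object"]),
                        grasp_type=str(ds.attrs["grasp_type"]),
                        repetition=int(ds.attrs["repetition"]),
                    )
                )
    return recordings
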