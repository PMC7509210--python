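"""Shared domain types and delimited-text I/O.

A *trial* is one synchronized recording of 10 surface-EMG channels plus
steering torque (N·m) and steering angle (degrees) at a single sampling
rate.  Trials travel as a CSV data file (columns ``time, torque, angle,
emg_01 … emg_10``) with a JSON metadata sidecar (``<basename>.meta.json``).

Sign convention: positive torque = clockwise steering effort.  The
convention is recorded in every metadata sidecar so importers of real
recordings can flip the sign once at ingest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, DomainError, FormatError, TimingError, UsageError


class ArmMode(str, Enum):
    BOTH = "both"
    SINGLE = "single"


class Task(str, Enum):
    ACTIVE = "active"
    PASSIVE = "passive"


class Direction(str, Enum):
    CW = "cw"
    CCW = "ccw"


#: Valid steering-wheel grip codes per arm mode ("0300" = 3 o'clock, etc.)
HAND_POSITIONS = {
    ArmMode.BOTH: ("0300", "1010", "1200"),
    ArmMode.SINGLE: ("0300", "0130", "1200"),
}

N_CHANNELS = 10
EMG_COLUMNS = [f"emg_{i:02d}" for i in range(1, N_CHANNELS + 1)]
TRIAL_COLUMNS = ["time", "torque", "angle", *EMG_COLUMNS]

#: Relative tolerance on the uniformity of the time step.
TIME_STEP_RTOL = 1e-9

SCHEMA_VERSION = "steerlimb.v1"


def channel_labels(arm_mode: ArmMode) -> list[str]:
    """Muscle channel codes for a montage: MB1..MB10 (both arms) or MS1..MS10 (single)."""
    prefix = "MB" if ArmMode(arm_mode) is ArmMode.BOTH else "MS"
    return [f"{prefix}{i}" for i in range(1, N_CHANNELS + 1)]


@dataclass
class Trial:
    """One recording: 10 EMG channels + torque + angle + metadata."""

    subject_id: str
    arm_mode: ArmMode
    hand_position: str
    task: Task
    fs: float
    time: np.ndarray
    torque: np.ndarray
    angle: np.ndarray
    emg: np.ndarray  # shape (10, n_samples), mV
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.arm_mode = ArmMode(self.arm_mode)
        self.task = Task(self.task)
        self.time = np.asarray(self.time, dtype=float)
        self.torque = np.asarray(self.torque, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        if not self.channel_labels:
            self.channel_labels = channel_labels(self.arm_mode)

    @property
    def n_samples(self) -> int:
        return self.time.shape[0]

    def validate(self) -> "Trial":
        """Check all structural invariants; raise a steerlimb error on violation."""
        n = self.n_samples
        if self.fs <= 0:
            raise DomainError(f"fs must be positive, got {self.fs}")
        for name in ("torque", "angle"):
            if getattr(self, name).shape != (n,):
                raise FormatError(f"series '{name}' length differs from time axis")
        if self.emg.shape != (N_CHANNELS, n):
            raise FormatError(
                f"emg must have shape ({N_CHANNELS}, {n}), got {self.emg.shape}"
            )
        if len(self.channel_labels) != N_CHANNELS:
            raise FormatError("channel_labels must list exactly 10 muscle codes")
        if self.hand_position not in HAND_POSITIONS[self.arm_mode]:
            raise FormatError(
                f"hand_position {self.hand_position!r} invalid for arm_mode "
                f"{self.arm_mode.value!r}; allowed: {HAND_POSITIONS[self.arm_mode]}"
            )
        for name in ("time", "torque", "angle", "emg"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                idx = int(np.flatnonzero(~np.isfinite(arr).reshape(-1, n).all(axis=0))[0])
                raise DataError(f"non-finite value in '{name}' at row {idx}")
        _check_uniform_time(self.time, self.fs)
        return self


def _check_uniform_time(time: np.ndarray, fs: float) -> None:
    dt = np.diff(time)
    if dt.size == 0:
        raise TimingError("trial must contain at least 2 samples")
    if np.any(dt <= 0):
        idx = int(np.flatnonzero(dt <= 0)[0])
        raise TimingError(f"time not strictly increasing at row {idx + 1}")
    expected = 1.0 / fs
    dev = np.abs(dt - expected)
    # absolute floor covers representation error of t = k/fs at large k
    tol = TIME_STEP_RTOL * expected + 1e-12 * max(abs(time[0]), abs(time[-1]), 1.0)
    if np.any(dev > tol):
        idx = int(np.argmax(dev))
        raise TimingError(
            f"non-uniform time step at row {idx + 1}: "
            f"dt={dt[idx]:.9g} s, expected {expected:.9g} s"
        )


@dataclass
class MuscleDirectionResult:
    """Per-muscle, per-direction analysis outcome.

    ``r`` is the peak normalized cross-correlation in [0, 1], ``a`` the mean
    normalized envelope over the direction's episodes, ``c`` the contribution
    ratio (r·a normalized over the 10 muscles), and ``tau_ms`` the signed
    delay (negative = muscle activity precedes torque).
    """

    muscle: str
    direction: str
    r: float
    a: float
    c: float
    tau_ms: float

    def validate(self) -> "MuscleDirectionResult":
        if not 0.0 <= self.r <= 1.0:
            raise DomainError(f"r must lie in [0,1], got {self.r}")
        if self.a < 0:
            raise DomainError(f"a must be >= 0, got {self.a}")
        if not 0.0 <= self.c <= 1.0:
            raise DomainError(f"c must lie in [0,1], got {self.c}")
        return self


@dataclass
class CohortSummary:
    """One aggregated statistic for one experimental condition."""

    arm_mode: str
    task: str
    hand_position: str
    direction: str
    statistic: str
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    n_subjects: int

    def validate(self) -> "CohortSummary":
        if self.sd < 0:
            raise DomainError("sd must be >= 0")
        if not (self.q1 <= self.median <= self.q3):
            raise DomainError("quartiles must satisfy q1 <= median <= q3")
        if self.n_subjects < 1:
            raise DomainError("n_subjects must be >= 1")
        return self


# --------------------------------------------------------------------------
# Trial I/O


def default_meta_path(path_data: str | Path) -> Path:
    """``foo/bar.csv`` → ``foo/bar.meta.json``."""
    p = Path(path_data)
    return p.with_name(p.stem + ".meta.json")


def read_trial(path_data: str | Path, path_meta: str | Path | None = None) -> Trial:
    """Read a trial CSV plus its JSON metadata sidecar and validate it.

    The sampling rate is inferred from the median time step.
    """
    path_data = Path(path_data)
    path_meta = Path(path_meta) if path_meta is not None else default_meta_path(path_data)
    df = pd.read_csv(path_data, float_precision="round_trip")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trial file {path_data} is missing column '{missing[0]}'")
    for col in TRIAL_COLUMNS:
        vals = df[col].to_numpy(dtype=float)
        bad = ~np.isfinite(vals)
        if bad.any():
            raise DataError(
                f"non-finite value in column '{col}' at row {int(np.flatnonzero(bad)[0])}"
            )
    time = df["time"].to_numpy(dtype=float)
    dt = np.diff(time)
    if dt.size == 0 or np.any(dt <= 0):
        raise TimingError("time column must be strictly increasing with >= 2 samples")
    fs = 1.0 / float(np.median(dt))

    with open(path_meta, encoding="utf-8") as fh:
        meta = json.load(fh)
    for key in ("subject_id", "arm_mode", "hand_position", "task"):
        if key not in meta:
            raise FormatError(f"metadata {path_meta} is missing key '{key}'")

    trial = Trial(
        subject_id=str(meta["subject_id"]),
        arm_mode=ArmMode(meta["arm_mode"]),
        hand_position=str(meta["hand_position"]),
        task=Task(meta["task"]),
        fs=fs,
        time=time,
        torque=df["torque"].to_numpy(dtype=float),
        angle=df["angle"].to_numpy(dtype=float),
        emg=df[EMG_COLUMNS].to_numpy(dtype=float).T,
        channel_labels=list(meta.get("channel_labels", [])) or channel_labels(ArmMode(meta["arm_mode"])),
    )
    return trial.validate()


def write_trial(trial: Trial, path_data: str | Path, path_meta: str | Path | None = None) -> None:
    """Write a trial as CSV + JSON sidecar; round-trips losslessly through read_trial."""
    trial.validate()
    path_data = Path(path_data)
    path_meta = Path(path_meta) if path_meta is not None else default_meta_path(path_data)
    cols = {"time": trial.time, "torque": trial.torque, "angle": trial.angle}
    for i, col in enumerate(EMG_COLUMNS):
        cols[col] = trial.emg[i]
    pd.DataFrame(cols).to_csv(path_data, index=False, lineterminator="\n")
    meta = {
        "subject_id": trial.subject_id,
        "arm_mode": trial.arm_mode.value,
        "hand_position": trial.hand_position,
        "task": trial.task.value,
        "fs": trial.fs,
        "channel_labels": list(trial.channel_labels),
        "torque_sign": "cw_positive",
    }
    with open(path_meta, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


# --------------------------------------------------------------------------
# Result-table I/O

_RESULT_SCHEMAS = {
    "muscle_direction": MuscleDirectionResult,
    "cohort_summary": CohortSummary,
}


def _kind_of(record) -> str:
    for kind, cls in _RESULT_SCHEMAS.items():
        if isinstance(record, cls):
            return kind
    raise UsageError(f"unsupported result record type {type(record).__name__}")


def write_results(results: list, path: str | Path) -> None:
    """Write a homogeneous list of result records as a schema-tagged CSV."""
    if not results:
        raise UsageError("write_results called with an empty list")
    kinds = {_kind_of(r) for r in results}
    if len(kinds) > 1:
        raise UsageError(f"mixed result kinds in one call: {sorted(kinds)}")
    kind = kinds.pop()
    cls = _RESULT_SCHEMAS[kind]
    col_names = [f.name for f in fields(cls)]
    df = pd.DataFrame([{c: getattr(r, c) for c in col_names} for r in results])
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# schema={SCHEMA_VERSION} kind={kind}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_results(path: str | Path) -> list:
    """Read a result CSV written by :func:`write_results`."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
    if not header.startswith("# schema="):
        raise FormatError(f"{path} lacks a steerlimb schema header line")
    try:
        kind = header.split("kind=", 1)[1].strip()
        cls = _RESULT_SCHEMAS[kind]
    except (IndexError, KeyError) as exc:
        raise FormatError(f"unknown result schema in {path}: {header!r}") from exc
    df = pd.read_csv(path, skiprows=1, float_precision="round_trip")
    records = []
    for row in df.itertuples(index=False):
        records.append(cls(**row._asdict()))
    return records
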