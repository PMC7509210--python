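"""EMG envelope extraction, normalization, and steering-direction segmentation.

All filtering is zero-phase (forward-backward), so envelopes carry no
filter-induced lag that would contaminate the downstream time-delay
analysis.  Direction labeling uses a torque dead-band plus a minimum
episode duration, because the raw torque sign chatters near zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import Direction
from .errors import (
    DataError,
    DegenerateInputError,
    EmptySegmentsWarning,
    LengthError,
    ParameterError,
    UsageError,
)


@dataclass(frozen=True)
class PreprocessParams:
    bp_low: float = 20.0  # Hz
    bp_high: float = 450.0  # Hz
    env_cutoff: float = 6.0  # Hz
    norm_method: str = "trial_max"  # or "reference_value"

    def validate(self, fs: float) -> "PreprocessParams":
        if not 0 < self.bp_low < self.bp_high:
            raise ParameterError("need 0 < bp_low < bp_high")
        if fs <= 2.0 * self.bp_high:
            raise ParameterError(
                f"fs={fs} Hz cannot represent the band-pass upper corner {self.bp_high} Hz"
            )
        if not 0 < self.env_cutoff < self.bp_low:
            raise ParameterError("need 0 < env_cutoff < bp_low")
        if self.norm_method not in ("trial_max", "reference_value"):
            raise ParameterError(f"unknown norm_method {self.norm_method!r}")
        return self


@dataclass(frozen=True)
class SegmentationParams:
    """Dead-band threshold ``theta`` (N·m); if None it defaults to
    ``theta_frac`` of the trial's max |torque|."""

    theta: float | None = None
    theta_frac: float = 0.05
    min_dur_s: float = 0.5

    def validate(self) -> "SegmentationParams":
        if self.theta is not None and self.theta < 0:
            raise ParameterError("theta must be >= 0")
        if not 0 <= self.theta_frac < 1:
            raise ParameterError("theta_frac must lie in [0, 1)")
        if self.min_dur_s <= 0:
            raise ParameterError("min_dur_s must be > 0")
        return self


@dataclass
class DirectionSegments:
    """Sorted, non-overlapping steering episodes: (start, end) half-open, direction."""

    segments: list[tuple[int, int, str]]
    fs: float

    def for_direction(self, direction: str | Direction) -> list[tuple[int, int]]:
        d = Direction(direction).value
        return [(s, e) for (s, e, seg_d) in self.segments if seg_d == d]

    def n_samples(self, direction: str | Direction) -> int:
        return sum(e - s for s, e in self.for_direction(direction))

    def gather(self, x: np.ndarray, direction: str | Direction) -> list[np.ndarray]:
        """Per-segment slices of ``x`` for one direction."""
        return [x[s:e] for s, e in self.for_direction(direction)]

    @property
    def directions_present(self) -> list[str]:
        return [d.value for d in (Direction.CW, Direction.CCW) if self.n_samples(d) > 0]


def envelope(raw: np.ndarray, fs: float, params: PreprocessParams | None = None) -> np.ndarray:
    """Activation envelope of one raw EMG channel.

    Zero-phase band-pass (bp_low, bp_high) -> full-wave rectification ->
    zero-phase low-pass at env_cutoff, clipped at 0.  Same length as input.
    """
    if params is None:
        params = PreprocessParams()
    params.validate(fs)
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise DataError("raw EMG contains non-finite values")
    min_len = int(math.ceil(10.0 * fs / params.bp_low))
    if raw.size < min_len:
        raise LengthError(f"need at least {min_len} samples at fs={fs}, got {raw.size}")
    sos_bp = signal.butter(
        4, (params.bp_low, params.bp_high), btype="bandpass", fs=fs, output="sos"
    )
    sos_lp = signal.butter(4, params.env_cutoff, btype="lowpass", fs=fs, output="sos")
    band = signal.sosfiltfilt(sos_bp, raw)
    env = signal.sosfiltfilt(sos_lp, np.abs(band))
    return np.maximum(env, 0.0)


def normalize(env: np.ndarray, method: str = "trial_max", ref: float | None = None) -> np.ndarray:
    """Scale an envelope to a comparable range.

    ``trial_max``: divide by the envelope's own maximum (max becomes 1).
    ``reference_value``: divide by a caller-supplied positive reference.
    """
    env = np.asarray(env, dtype=float)
    if method == "trial_max":
        m = float(np.max(env)) if env.size else 0.0
        if m <= 0:
            raise DegenerateInputError("cannot trial_max-normalize an all-zero envelope")
        return env / m
    if method == "reference_value":
        if ref is None or ref <= 0:
            raise UsageError("reference_value normalization requires ref > 0")
        return env / ref
    raise UsageError(f"unknown normalization method {method!r}")


def segment_directions(
    torque: np.ndarray, fs: float, params: SegmentationParams | None = None
) -> DirectionSegments:
    """Label clockwise/counterclockwise steering episodes of a torque trace.

    Samples with torque > +theta are clockwise, < -theta counterclockwise,
    |torque| <= theta unlabeled; maximal runs shorter than ``min_dur_s``
    are discarded.
    """
    if params is None:
        params = SegmentationParams()
    params.validate()
    torque = np.asarray(torque, dtype=float)
    if not np.all(np.isfinite(torque)):
        raise DataError("torque contains non-finite values")
    max_abs = float(np.max(np.abs(torque))) if torque.size else 0.0
    theta = params.theta if params.theta is not None else params.theta_frac * max_abs

    labels = np.zeros(torque.size, dtype=np.int8)
    labels[torque > theta] = 1
    labels[torque < -theta] = -1

    min_samples = max(1, int(math.ceil(params.min_dur_s * fs)))
    segments: list[tuple[int, int, str]] = []
    if torque.size:
        change = np.flatnonzero(np.diff(labels)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [labels.size]))
        for s, e in zip(starts, ends):
            lab = labels[s]
            if lab != 0 and e - s >= min_samples:
                segments.append((int(s), int(e), "cw" if lab == 1 else "ccw"))
    if not segments:
        warnings.warn(
            "no steering episode exceeded the dead-band/duration thresholds",
            EmptySegmentsWarning,
            stacklevel=2,
        )
    return DirectionSegments(segments=segments, fs=fs)


def decimate_series(x: np.ndarray, fs: float, target_fs: float) -> tuple[np.ndarray, float]:
    """Stride-decimate an already low-passed series to approximately target_fs.

    Plain striding is used because envelopes (<= env_cutoff Hz) and steering
    torque are far below the target Nyquist; returns (series, achieved fs).
    """
    if target_fs <= 0:
        raise ParameterError("target_fs must be > 0")
    factor = max(1, int(round(fs / target_fs)))
    return np.asarray(x)[..., ::factor], fs / factor
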