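"""Direction-resolved EMG-torque correlation, amplitude, and contribution analysis.

For one muscle and one steering direction, the correlation ``r`` is the
maximum of the normalized cross-correlation (over a bounded lag window)
between the muscle's normalized envelope and the torque magnitude,
restricted to that direction's episodes.  Correlation and amplitude are
then integrated into a per-direction contribution ratio
``c_i = r_i * a_i / sum_j r_j * a_j`` that ranks muscle importance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Direction
from .errors import (
    CoverageError,
    DegenerateInputError,
    DomainError,
    PairingError,
    SampleSizeError,
)
from .lags import _xcorr_core
from .preprocess import DirectionSegments

STRONG = "strong"
NOT_STRONG = "not_strong"


@dataclass(frozen=True)
class CorrelationParams:
    max_lag_ms: float = 1000.0  # half-window for the lag search
    strong_threshold: float = 0.75

    def validate(self) -> "CorrelationParams":
        if self.max_lag_ms <= 0:
            raise DomainError("max_lag_ms must be > 0")
        if not 0 < self.strong_threshold < 1:
            raise DomainError("strong_threshold must lie in (0, 1)")
        return self


def _concat_demeaned(pieces: list[np.ndarray]) -> np.ndarray:
    # per-segment mean removal prevents between-episode offsets inflating r
    return np.concatenate([p - p.mean() for p in pieces])


def direction_correlation(
    env: np.ndarray,
    torque: np.ndarray,
    segs: DirectionSegments,
    direction: str | Direction,
    params: CorrelationParams | None = None,
) -> float:
    """Peak normalized cross-correlation between envelope and |torque| within
    one direction's episodes; anticorrelation is reported as 0."""
    if params is None:
        params = CorrelationParams()
    params.validate()
    direction = Direction(direction)
    env = np.asarray(env, dtype=float)
    torque = np.asarray(torque, dtype=float)
    env_pieces = segs.gather(env, direction)
    if not env_pieces:
        raise CoverageError(f"no segments labeled {direction.value!r}")
    x = _concat_demeaned(env_pieces)
    y = _concat_demeaned(segs.gather(np.abs(torque), direction))
    max_lag = max(1, int(round(params.max_lag_ms * segs.fs / 1000.0)))
    if x.size < 2 * max_lag:
        raise CoverageError(
            f"direction {direction.value!r} has {x.size} labeled samples; "
            f"need >= 2*max_lag = {2 * max_lag}"
        )
    if np.var(x) == 0 or np.var(y) == 0:
        raise DegenerateInputError(
            f"zero-variance series within {direction.value!r} segments"
        )
    rho = _xcorr_core(x, y, max_lag)
    return float(np.clip(np.max(rho), 0.0, 1.0))


def classify_strength(r: float, params: CorrelationParams | None = None) -> str:
    """'strong' iff r exceeds the threshold (strictly; default 0.75)."""
    if params is None:
        params = CorrelationParams()
    params.validate()
    if not 0.0 <= r <= 1.0:
        raise DomainError(f"correlation must lie in [0,1], got {r}")
    return STRONG if r > params.strong_threshold else NOT_STRONG


def amplitude_statistic(
    env: np.ndarray, segs: DirectionSegments, direction: str | Direction
) -> float:
    """Mean normalized envelope over all samples in one direction's episodes."""
    direction = Direction(direction)
    pieces = segs.gather(np.asarray(env, dtype=float), direction)
    if not pieces:
        raise CoverageError(f"no segments labeled {direction.value!r}")
    total = sum(p.sum() for p in pieces)
    count = sum(p.size for p in pieces)
    return float(total / count)


def contribution_ratios(rs: np.ndarray, amps: np.ndarray) -> np.ndarray:
    """Contribution ratio per muscle for one direction: c_i = r_i a_i / sum r_j a_j."""
    rs = np.asarray(rs, dtype=float)
    amps = np.asarray(amps, dtype=float)
    if rs.shape != amps.shape or rs.ndim != 1:
        raise PairingError("rs and amps must be 1-D arrays aligned by muscle")
    if np.any(rs < 0) or np.any(amps < 0):
        raise DomainError("correlations and amplitudes must be >= 0")
    products = rs * amps
    total = products.sum()
    if total <= 0:
        raise DegenerateInputError("all correlation*amplitude products are zero")
    if np.all(products == products[0]):
        # symmetry is exact by construction; avoid round-off in the ratio
        return np.full(products.size, 1.0 / products.size)
    return products / total


def direction_dependence_test(
    r_cw: np.ndarray,
    r_ccw: np.ndarray,
    n_resamples: int = 20_000,
    seed: int | None = 0,
) -> float:
    """Two-sided paired sign-flip permutation test on the mean cw-ccw difference.

    Exact (exhaustive over all 2^n sign patterns) for n <= 20; Monte-Carlo
    with the given seed above that.  Returns p in (0, 1].
    """
    r_cw = np.asarray(r_cw, dtype=float)
    r_ccw = np.asarray(r_ccw, dtype=float)
    if r_cw.shape != r_ccw.shape or r_cw.ndim != 1:
        raise PairingError("r_cw and r_ccw must be 1-D arrays paired by subject")
    n = r_cw.size
    if n < 2:
        raise SampleSizeError(f"need n >= 2 paired subjects, got {n}")
    d = r_cw - r_ccw
    obs = abs(d.mean())
    tol = 1e-12 * (1.0 + obs)

    if n <= 20:
        total = 1 << n
        count = 0
        bit_cols = np.arange(n)
        chunk = 1 << 16
        for start in range(0, total, chunk):
            idx = np.arange(start, min(start + chunk, total), dtype=np.int64)
            signs = 1.0 - 2.0 * ((idx[:, None] >> bit_cols) & 1)
            means = np.abs(signs @ d) / n
            count += int(np.sum(means >= obs - tol))
        return count / total

    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_resamples, n))
    means = np.abs(signs @ d) / n
    count = int(np.sum(means >= obs - tol))
    return (1 + count) / (1 + n_resamples)


def holm_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment of a family of p-values."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p)
    adjusted = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        val = min(1.0, (m - rank) * p[idx])
        running_max = max(running_max, val)
        adjusted[idx] = running_max
    return adjusted
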