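"""Normalized lagged cross-correlation and EMG-to-torque delay estimation.

The delay of a muscle is the lag at which the absolute normalized
cross-correlation between the torque magnitude and the muscle's envelope
peaks.  Sign convention: ``tau_ms < 0`` means the envelope changes precede
the matching torque changes (the muscle *leads*); positive means the
envelope lags behind the torque, as with co-contracting antagonists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import BoundaryWarning, DegenerateInputError, LengthError
from .preprocess import DirectionSegments


@dataclass
class DelayResult:
    muscle: str
    tau_ms: float
    rho_at_tau: float
    max_lag_ms: float
    boundary: bool = False  # optimum landed on the search-window edge


def _xcorr_core(x: np.ndarray, y: np.ndarray, max_lag: int) -> np.ndarray:
    """rho[tau + max_lag] = Pearson correlation of x(t) with y(t + tau),
    each overlap window mean-removed; 0.0 where a window is degenerate."""
    n = x.size
    rho = np.zeros(2 * max_lag + 1)
    for k, tau in enumerate(range(-max_lag, max_lag + 1)):
        if tau >= 0:
            a = x[: n - tau]
            b = y[tau:]
        else:
            a = x[-tau:]
            b = y[: n + tau]
        if a.size < 3:
            continue
        a = a - a.mean()
        b = b - b.mean()
        denom = np.sqrt(np.dot(a, a) * np.dot(b, b))
        if denom > 0:
            rho[k] = np.dot(a, b) / denom
    return rho


def xcorr_normalized(x: np.ndarray, y: np.ndarray, max_lag: int) -> np.ndarray:
    """Normalized cross-correlation rho(tau) for tau = -max_lag .. +max_lag.

    rho(tau) is the Pearson correlation between x(t) and y(t + tau) over
    the overlapping range, with each window's mean removed, so
    |rho(tau)| <= 1 for all tau.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise LengthError("x and y must be 1-D arrays of equal length")
    if max_lag < 1:
        raise LengthError("max_lag must be >= 1")
    if x.size < 4 * max_lag:
        raise LengthError(f"series length {x.size} must be >= 4*max_lag = {4 * max_lag}")
    if np.var(x) == 0 or np.var(y) == 0:
        raise DegenerateInputError("zero-variance input to xcorr_normalized")
    return _xcorr_core(x, y, max_lag)


def _argmax_abs_smallest_lag(rho: np.ndarray, max_lag: int) -> int:
    """Index of max |rho|; ties broken toward the smallest |tau| (then negative tau)."""
    lags = np.arange(-max_lag, max_lag + 1)
    order = np.lexsort((lags, np.abs(lags)))  # 0, -1, +1, -2, +2, ...
    best_idx = order[0]
    best_val = abs(rho[best_idx])
    for idx in order[1:]:
        v = abs(rho[idx])
        if v > best_val:
            best_val = v
            best_idx = idx
    return int(best_idx)


def estimate_delay(
    env: np.ndarray,
    torque: np.ndarray,
    fs: float,
    segs: DirectionSegments | None = None,
    max_lag_ms: float = 1000.0,
    muscle: str = "",
) -> DelayResult:
    """Delay between a muscle envelope and the steering torque magnitude.

    ``tau*`` maximizes |rho(tau)| where rho(tau) correlates |torque|(t)
    with env(t + tau); a negative ``tau_ms`` therefore means the envelope
    leads the torque.  When ``segs`` is given, the analysis is restricted
    to the contiguous span from the first to the last labeled sample (lag
    structure requires contiguity, so segments are not concatenated).
    A warning flag is attached when the optimum sits on the window edge.
    """
    env = np.asarray(env, dtype=float)
    torque = np.asarray(torque, dtype=float)
    if segs is not None and segs.segments:
        start = segs.segments[0][0]
        end = segs.segments[-1][1]
        env = env[start:end]
        torque = torque[start:end]
    max_lag = max(1, int(round(max_lag_ms * fs / 1000.0)))
    rho = xcorr_normalized(np.abs(torque), env, max_lag)
    idx = _argmax_abs_smallest_lag(rho, max_lag)
    tau = idx - max_lag
    boundary = abs(tau) == max_lag
    if boundary:
        warnings.warn(
            f"delay optimum at search-window edge ({tau * 1000.0 / fs:+.0f} ms); "
            "the window is likely too small",
            BoundaryWarning,
            stacklevel=2,
        )
    return DelayResult(
        muscle=muscle,
        tau_ms=tau * 1000.0 / fs,
        rho_at_tau=float(rho[idx]),
        max_lag_ms=max_lag * 1000.0 / fs,
        boundary=boundary,
    )
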