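"""Steering-smoothness metrics on the torque signal.

Two complementary readouts: approximate entropy (regularity; lower =
more regular) and the mean sliding-window standard deviation (local
variability; lower = smoother).  Both are 0 on constant input.

Approximate entropy follows the standard construction with self-matches
included and a tolerance relative to the series SD, so the value is
invariant under affine transforms of the input.  Because successive raw
samples at kHz rates are trivially similar (collapsing the statistic
toward 0), the trial-level report decimates the torque to ``apen_fs``
before embedding; the rate is a configuration knob.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import Trial
from .errors import LengthError, ParameterError
from .preprocess import decimate_series


@dataclass(frozen=True)
class ApEnParams:
    m: int = 2  # embedding dimension
    r_frac: float = 0.2  # tolerance as a fraction of the series SD

    def validate(self) -> "ApEnParams":
        if self.m < 1:
            raise ParameterError("embedding dimension m must be >= 1")
        if self.r_frac <= 0:
            raise ParameterError("r_frac must be > 0")
        return self


@dataclass
class ApEnTrace:
    phi_m: float
    phi_m1: float
    counts: np.ndarray  # per-template match counts at length m (self-match included)
    degenerate: bool = False


@dataclass(frozen=True)
class SsdParams:
    window_s: float = 0.5
    step: int = 1

    def validate(self, fs: float) -> "SsdParams":
        if self.window_s * fs < 2:
            raise ParameterError("window must span at least 2 samples")
        if self.step < 1:
            raise ParameterError("step must be >= 1")
        return self


@dataclass
class SmoothnessResult:
    apen: float
    ssd: float
    degenerate: bool = False


def _template_counts(x: np.ndarray, m: int, r_tol: float) -> np.ndarray:
    """counts[i] = #{ j : max_k |x[i+k] - x[j+k]| <= r_tol, k < m }, self included.

    Computed dimension-wise (boolean AND across the m coordinates) in row
    chunks to bound memory at O(chunk * n_templates).
    """
    n_templates = x.size - m + 1
    counts = np.empty(n_templates, dtype=np.int64)
    cols = [x[k : k + n_templates] for k in range(m)]
    chunk = max(1, 2_000_000 // max(n_templates, 1))
    for start in range(0, n_templates, chunk):
        stop = min(start + chunk, n_templates)
        ok = np.ones((stop - start, n_templates), dtype=bool)
        for col in cols:
            ok &= np.abs(col[start:stop, None] - col[None, :]) <= r_tol
        counts[start:stop] = ok.sum(axis=1)
    return counts


def _phi(x: np.ndarray, m: int, r_tol: float) -> tuple[float, np.ndarray]:
    counts = _template_counts(x, m, r_tol)
    n_templates = x.size - m + 1
    return float(np.mean(np.log(counts / n_templates))), counts


def approximate_entropy(
    x: np.ndarray, params: ApEnParams | None = None
) -> tuple[float, ApEnTrace]:
    """Approximate entropy ApEn(m, r) = Phi^m - Phi^{m+1} of a series.

    Tolerance is ``r_frac * SD(x)``.  A constant series (SD = 0) returns
    0 with the degenerate flag set.
    """
    if params is None:
        params = ApEnParams()
    params.validate()
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise LengthError("series contains non-finite values")
    n = x.size
    if n <= params.m + 1:
        raise LengthError(f"series length {n} must exceed m+1 = {params.m + 1}")
    sd = float(x.std())
    if sd == 0.0 or np.ptp(x) == 0.0:  # constant series; mean round-off can leave sd != 0
        return 0.0, ApEnTrace(phi_m=0.0, phi_m1=0.0, counts=np.full(n - params.m + 1, n - params.m + 1), degenerate=True)
    r_tol = params.r_frac * sd
    phi_m, counts = _phi(x, params.m, r_tol)
    phi_m1, _ = _phi(x, params.m + 1, r_tol)
    return phi_m - phi_m1, ApEnTrace(phi_m=phi_m, phi_m1=phi_m1, counts=counts)


def sliding_sd(x: np.ndarray, fs: float, params: SsdParams | None = None) -> float:
    """Mean over window positions of the within-window sample SD (ddof=1)."""
    if params is None:
        params = SsdParams()
    params.validate(fs)
    x = np.asarray(x, dtype=float)
    w = int(round(params.window_s * fs))
    if x.size < w:
        raise LengthError(f"series length {x.size} shorter than window {w}")
    if np.ptp(x) == 0.0:  # constant input must score exactly 0
        return 0.0
    windows = sliding_window_view(x, w)[:: params.step]
    return float(windows.std(axis=1, ddof=1).mean())


def smoothness_report(
    trial: Trial,
    apen_params: ApEnParams | None = None,
    ssd_params: SsdParams | None = None,
    apen_fs: float = 100.0,
) -> SmoothnessResult:
    """Both smoothness metrics on a trial's torque channel (lower = smoother)."""
    trial.validate()
    decimated, _ = decimate_series(trial.torque, trial.fs, apen_fs)
    apen, trace = approximate_entropy(decimated, apen_params)
    ssd = sliding_sd(trial.torque, trial.fs, ssd_params)
    return SmoothnessResult(apen=apen, ssd=ssd, degenerate=trace.degenerate)
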