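"""Convergence-time estimation on node-activity time series.

A stochastic Boolean network with noise on every node typically relaxes to a
stationary activity profile within a handful of steps.  The criterion used
here compares, for every node, the mean activity over two same-sized sliding
windows ending at steps t and t-1; the series is declared converged at the
first t where all per-node differences fall strictly below a user threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ConvergenceResult", "calc_convergence_time"]


@dataclass(frozen=True)
class ConvergenceResult:
    converged: bool
    step: int | None
    threshold: float
    window: int

    def __bool__(self) -> bool:
        return self.converged


def calc_convergence_time(series, threshold: float, window: int) -> ConvergenceResult:
    """Estimate the time-step at which node activities stabilise.

    Parameters
    ----------
    series:
        Activity time series: array-like or DataFrame of shape
        ``(steps+1, n)`` with rows indexed by time-step (row 0 = initial).
    threshold:
        Positive bound; convergence at t requires
        ``|mean(A[t-window+1 .. t, i]) - mean(A[t-window .. t-1, i])| < threshold``
        for every node i (strict inequality).
    window:
        Window size in rows (>= 1).

    Returns the first qualifying t (which is at least ``window``); the
    criterion is not required to persist afterwards.
    """
    if isinstance(series, pd.DataFrame):
        values = series.to_numpy(dtype=float)
    else:
        values = np.asarray(series, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    rows = values.shape[0]
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if window < 1:
        raise ValueError("window must be >= 1")
    if window >= rows:
        raise ValueError(f"window ({window}) must be smaller than the number "
                         f"of rows ({rows})")
    # mean over rows [t-window+1, t] minus mean over rows [t-window, t-1]
    # equals (A[t] - A[t-window]) / window
    diff = np.abs(values[window:] - values[:-window]) / window
    hit = np.all(diff < threshold, axis=1)
    idx = np.flatnonzero(hit)
    if idx.size == 0:
        return ConvergenceResult(False, None, threshold, window)
    return ConvergenceResult(True, int(idx[0] + window), threshold, window)
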