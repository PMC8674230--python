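"""Droplet-formation kinetics from a continuously-recorded trace.

The kinetic baseline is an asymmetric penalized least-squares (Whittaker)
smoother: minimize Σ w_i (y_i − z_i)² + λ Σ (Δ² z_i)², with weights p for
points above the current baseline and 1 − p below, iteratively re-weighted.
The parameter mapping adopted from the originating analysis settings is:
symmetric factor → asymmetry p = 0.001, smoothing factor 4 → λ = 10⁴,
threshold 0.005 → iteration-convergence tolerance (max relative baseline
change), 20-iteration cap.

On top of the baseline: a local maximum more than 1% above the baseline is
a droplet; peak heights are averaged in a 10-peak sliding window; the lag
time is the first detected peak and the early growth rate is the OLS slope
of the averaged heights over the first two minutes.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .baseline import _run_integral, _runs_above
from .types import InsufficientDataError, PeakTable, Trace, ValidationError


def als_baseline(
    trace: Trace | np.ndarray,
    asymmetry_p: float = 0.001,
    smoothness_log10: float = 4.0,
    iterations: int = 20,
    tol: float = 0.005,
) -> np.ndarray:
    """Asymmetric least-squares baseline of a uniformly sampled trace.

    Solves (W + λ·D₂ᵀD₂)·z = W·y per pass with a second-difference penalty,
    λ = 10^smoothness_log10, and re-weights w_i = p where y_i > z_i else
    1 − p, until the maximum relative change of z drops below ``tol`` or the
    iteration cap is reached.
    """
    if isinstance(trace, Trace):
        if not trace.is_uniform:
            raise ValidationError("ALS baseline requires uniform sampling; resample first")
        y = trace.signal
    else:
        y = np.asarray(trace, dtype=float)
    n = y.size
    if n < 10:
        raise InsufficientDataError(f"ALS baseline needs at least 10 samples, got {n}")
    if not (0.0 < asymmetry_p < 1.0):
        raise ValidationError("asymmetry_p must lie in (0, 1)")
    lam = 10.0 ** smoothness_log10
    d2 = sparse.diags_array([1.0, -2.0, 1.0], offsets=[0, 1, 2],
                            shape=(n - 2, n)).tocsc()
    penalty = lam * (d2.T @ d2)
    w = np.ones(n)
    z = y.copy()
    for _ in range(iterations):
        a = sparse.diags_array(w).tocsc() + penalty
        z_new = spsolve(a, w * y)
        change = np.max(np.abs(z_new - z) / np.maximum(np.abs(z), 1e-300))
        z = z_new
        w = np.where(y > z, asymmetry_p, 1.0 - asymmetry_p)
        if change < tol:
            break
    return z


def detect_kinetic_peaks(trace: Trace, baseline: np.ndarray) -> PeakTable:
    """Droplets under the relative criterion: (y − z)/z > 1%.

    One peak per contiguous supra-criterion region; height is y − z at the
    region maximum.  The baseline must be strictly positive for the relative
    criterion to be meaningful.
    """
    z = np.asarray(baseline, dtype=float)
    if z.shape != trace.signal.shape:
        raise ValidationError("baseline must be computed on the trace's grid")
    if (z <= 0).any():
        raise ValidationError("relative peak criterion undefined: baseline <= 0 somewhere")
    rel = (trace.signal - z) / z
    excess = trace.signal - z
    runs = _runs_above(rel > 0.01)
    times, heights, integrals = [], [], []
    for s, e in runs:
        # tie-break on the raw signal: first sample of a plateaued maximum
        k = int(np.argmax(trace.signal[s:e + 1]))
        times.append(float(trace.time[s + k]))
        heights.append(float(excess[s + k]))
        integrals.append(_run_integral(trace.time, excess, s, e))
    return PeakTable(np.array(times), np.array(heights), np.array(integrals),
                     np.zeros(len(times), dtype=bool), threshold_used=0.01)


def sliding_peak_average(peaks: PeakTable, window: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Rolling mean of consecutive peak heights.

    Returns (times, means) with one point per consecutive window of
    ``window`` peaks (stride 1), timestamped at the window's median peak
    time.  Fewer peaks than the window yields an empty series.
    """
    if window < 1:
        raise ValidationError("window must be >= 1")
    order = np.argsort(peaks.peak_times, kind="stable")
    t = peaks.peak_times[order]
    h = peaks.heights[order]
    if peaks.n < window:
        import warnings
        warnings.warn(f"only {peaks.n} peaks for a {window}-peak window; empty series")
        return np.array([]), np.array([])
    kernel = np.ones(window) / window
    means = np.convolve(h, kernel, mode="valid")
    times = np.array([np.median(t[i:i + window]) for i in range(means.size)])
    return times, means


@dataclass
class KineticsResult:
    """Lag time and early droplet-growth rate of one kinetics trace."""

    lag_time_s: float            # time of the first detected peak (nan if none)
    rate_fu_per_min: float       # OLS slope of averaged heights over the fit window
    n_peaks: int
    no_peaks: bool = False


def onset_and_rate(
    peaks: PeakTable,
    averaged: tuple[np.ndarray, np.ndarray],
    fit_start: float = 0.0,
    fit_end: float = 120.0,
) -> KineticsResult:
    """Lag time (first detected peak) and early growth rate.

    The rate is the ordinary least-squares slope of the window-averaged peak
    heights over [fit_start, fit_end] seconds, reported in FU/min.  With no
    peaks the lag is NaN and the rate 0, flagged.
    """
    if peaks.n == 0:
        return KineticsResult(float("nan"), 0.0, 0, no_peaks=True)
    lag = float(np.min(peaks.peak_times))
    times, means = averaged
    m = (times >= fit_start) & (times <= fit_end)
    if m.sum() >= 2:
        slope_per_s = float(np.polyfit(times[m], means[m], 1)[0])
        rate = slope_per_s * 60.0
    else:
        rate = 0.0
    return KineticsResult(lag, rate, int(peaks.n))
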