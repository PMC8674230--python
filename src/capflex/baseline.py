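"""Standard-curve calibration, dilute-phase baseline extraction, spike detection.

This is the core of the capillary-flow LLPS readout: the flat baseline of a
trace reports the dilute-phase (saturation) concentration through a linear
standard curve, while the spikes riding on it are individual droplets.

Baseline extraction follows a fixed recipe: (1) fit a 4-parameter logistic
to the full trace and start the baseline region where the fit first exceeds
99% of its upper asymptote; (2) discard samples above 1.10× the
calibration-predicted signal for the expected total concentration;
(3) median-filter the survivors (31-sample window); (4) take the lower 5%
quantile (linear-interpolation/type-7 definition) as the baseline
fluorescence and invert the calibration for the dilute-phase concentration.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import optimize, signal as sps, stats

from .types import (
    BaselineResult,
    CalibrationError,
    CalibrationCurve,
    FrontDetectionError,
    InsufficientDataError,
    PeakTable,
    Trace,
    ValidationError,
)


def fit_standard_curve(concentrations: np.ndarray, baselines: np.ndarray) -> CalibrationCurve:
    """Ordinary least squares line through (concentration, baseline FU) standards.

    All standards must come from non-phase-separated samples (caller's
    responsibility); a non-positive fitted slope is rejected as the signature
    of phase-separated standards or mislabeled data.
    """
    conc = np.asarray(concentrations, dtype=float)
    base = np.asarray(baselines, dtype=float)
    if conc.shape != base.shape:
        raise ValidationError("concentrations and baselines must have equal length")
    if np.unique(conc).size < 2:
        raise CalibrationError("need at least 2 distinct concentrations")
    res = stats.linregress(conc, base)
    if res.slope <= 0:
        raise CalibrationError(
            f"fitted slope {res.slope:.3g} FU/µM is not positive "
            "(phase-separated standards or mislabeled data?)")
    return CalibrationCurve(conc, base, float(res.slope), float(res.intercept),
                            float(res.rvalue ** 2))


def _logistic4(t: np.ndarray, lower: float, upper: float, midpoint: float,
               rate: float) -> np.ndarray:
    z = np.clip(-rate * (t - midpoint), -700.0, 700.0)
    return lower + (upper - lower) / (1.0 + np.exp(z))


def fit_front_sigmoid(trace: Trace) -> dict[str, float]:
    """Fit the 4-parameter logistic (lower, upper, midpoint, rate) to a trace.

    Initialization from data quantiles: lower/upper from the 2%/98%
    quantiles, midpoint at the first half-range crossing, rate from the
    25–75% rise time.
    """
    t, y = trace.time, trace.signal
    lo0, hi0 = np.quantile(y, [0.02, 0.98])
    if hi0 <= lo0:
        raise FrontDetectionError("trace has no dynamic range for a sigmoid fit")
    half = lo0 + 0.5 * (hi0 - lo0)
    above = np.nonzero(y >= half)[0]
    mid0 = t[above[0]] if above.size else t[t.size // 2]
    q25 = lo0 + 0.25 * (hi0 - lo0)
    q75 = lo0 + 0.75 * (hi0 - lo0)
    i25 = np.nonzero(y >= q25)[0]
    i75 = np.nonzero(y >= q75)[0]
    rise = max(t[i75[0]] - t[i25[0]], trace.dt) if i25.size and i75.size else trace.dt * 10
    rate0 = 2.2 / rise  # logit(0.75) − logit(0.25) = ln 9 ≈ 2.2 over the rise
    try:
        popt, _ = optimize.curve_fit(
            _logistic4, t, y, p0=[lo0, hi0, mid0, rate0],
            maxfev=20000, xtol=1e-10, ftol=1e-10)
    except RuntimeError as exc:  # pragma: no cover - scipy convergence failure
        raise FrontDetectionError(f"sigmoid fit did not converge: {exc}") from exc
    lower, upper, midpoint, rate = (float(v) for v in popt)
    if upper <= lower or rate <= 0:
        raise FrontDetectionError(
            f"sigmoid fit degenerate (lower={lower:.3g}, upper={upper:.3g}, "
            f"rate={rate:.3g})")
    return {"lower": lower, "upper": upper, "midpoint": midpoint, "rate": rate}


def extract_baseline(
    trace: Trace,
    calibration: Optional[CalibrationCurve] = None,
    expected_total_conc: Optional[float] = None,
    quantile: float = 0.05,
    median_window: int = 31,
    front_fraction: float = 0.99,
    discard_factor: float = 1.10,
) -> BaselineResult:
    """Locate the post-front baseline region and measure its fluorescence.

    When a calibration and the expected total concentration are supplied,
    samples above ``discard_factor`` × the predicted total-concentration
    signal are discarded before filtering (droplet spikes), and the baseline
    is inverted to a dilute-phase concentration.
    """
    if not trace.is_uniform:
        raise ValidationError("trace sampling is too non-uniform; resample first")
    params = fit_front_sigmoid(trace)
    level = front_fraction * params["upper"]
    fitted = _logistic4(trace.time, **params)
    idx = np.nonzero(fitted >= level)[0]
    if not idx.size:
        raise FrontDetectionError(
            "fitted sigmoid never reaches the requested fraction of its plateau")
    start = int(idx[0])
    region_t = (float(trace.time[start]), float(trace.time[-1]))
    y = trace.signal[start:]

    if calibration is not None and expected_total_conc is not None:
        cutoff = discard_factor * float(calibration.predict(expected_total_conc))
        y = y[y <= cutoff]
    if y.size < median_window:
        raise InsufficientDataError(
            f"only {y.size} samples survive in the baseline region; "
            f"need at least {median_window}")
    if median_window % 2 == 0:
        raise ValidationError("median_window must be odd")
    filtered = sps.medfilt(y, kernel_size=median_window)
    baseline_fu = float(np.quantile(filtered, quantile))  # type-7 interpolation
    dilute = float(calibration.inverse(baseline_fu)) if calibration is not None else None
    return BaselineResult(
        baseline_fu=baseline_fu,
        baseline_region=region_t,
        front_time=float(min(params["midpoint"], region_t[0])),
        sigmoid_params=params,
        dilute_phase_conc=dilute,
    )


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, stop) index pairs, stop inclusive."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(s), int(e) - 1) for s, e in zip(edges[::2], edges[1::2])]


def _run_integral(time: np.ndarray, excess: np.ndarray, s: int, e: int) -> float:
    """Trapezoidal area of ``excess`` over a run extended one sample each side.

    Extending to the flanking below-threshold samples makes the integral of
    a rectangular spike exact on the grid (the partial edge bins carry the
    missing corner area)."""
    lo = max(s - 1, 0)
    hi = min(e + 1, time.size - 1)
    return float(np.trapezoid(excess[lo:hi + 1], time[lo:hi + 1]))


def detect_peaks(
    trace: Trace,
    baseline: BaselineResult,
    threshold: float = 0.2,
    saturation_ceiling: float = 50.0,
) -> PeakTable:
    """Droplet spikes above the dilute-phase baseline.

    A peak is one contiguous region of the baseline-region signal exceeding
    ``baseline_fu + threshold`` (absolute FU offset).  Its height is the
    region maximum minus the baseline; its integral is the area above the
    baseline between the surrounding threshold crossings; it is flagged
    saturated when the raw maximum reaches the detector ceiling.  For
    plateaued (saturated) maxima the first sample of the plateau is the peak
    time.  An empty table is a valid result.
    """
    t0, t1 = baseline.baseline_region
    m = (trace.time >= t0) & (trace.time <= t1)
    t, y = trace.time[m], trace.signal[m]
    level = baseline.baseline_fu + threshold
    excess = y - baseline.baseline_fu
    runs = _runs_above(y > level)
    times, heights, integrals, saturated = [], [], [], []
    for s, e in runs:
        seg = y[s:e + 1]
        peak_local = int(np.argmax(seg))        # argmax → first sample of a plateau
        times.append(float(t[s + peak_local]))
        heights.append(float(seg[peak_local] - baseline.baseline_fu))
        integrals.append(_run_integral(t, excess, s, e))
        saturated.append(bool(seg[peak_local] >= saturation_ceiling))
    return PeakTable(np.array(times), np.array(heights), np.array(integrals),
                     np.array(saturated, dtype=bool), threshold_used=threshold)


def partitioned_amount(total_conc: float, dilute_conc: float) -> float:
    """Dilute-phase-equivalent amount partitioned into droplets, µM.

    Simply total − dilute; slightly negative values from measurement noise
    are reported as-is (use :func:`is_within_noise` to flag them).
    """
    if total_conc < 0 or dilute_conc < 0:
        raise ValidationError("concentrations must be non-negative")
    return total_conc - dilute_conc


def is_within_noise(amount_um: float, noise_bound_um: float) -> bool:
    """True when a partitioned amount is indistinguishable from zero."""
    return abs(amount_um) <= noise_bound_um


def reversibility_check(
    before: PeakTable,
    after: PeakTable,
    min_fraction_lost: float = 0.95,
) -> tuple[bool, dict[str, float]]:
    """Did the droplets dissolve between two same-channel analyses?

    Reversible (liquid-like) when the after-count has dropped to at most
    (1 − min_fraction_lost) of the before-count; matured/solidified samples
    keep their spikes.
    """
    if before.n == 0:
        raise ValidationError("reversibility undefined: no peaks before dilution")
    reversible = after.n <= (1.0 - min_fraction_lost) * before.n
    summary = {
        "peaks_before": float(before.n),
        "peaks_after": float(after.n),
        "fraction_lost": 1.0 - after.n / before.n,
        "min_fraction_lost": min_fraction_lost,
    }
    return bool(reversible), summary
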