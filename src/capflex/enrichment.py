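"""Relative enrichment of two labeled species inside droplets, plus the
photobleaching-corrected FRAP normalization and throughput arithmetic.

Two same-composition samples differ only in which species carries the
label.  For each, the droplet-phase signal fraction is

    Ratio = Σ(peak areas above baseline) / (total curve area),

with a peak being any contiguous region more than 0.5% above the baseline.
The enrichment factor is Ratio(A)/Ratio(B); by construction it does not
require knowing the dense-phase volume fraction, which cancels.
"""
from __future__ import annotations

import numpy as np

from .baseline import _run_integral, _runs_above
from .types import Trace, ValidationError


def signal_ratio(trace: Trace, baseline: np.ndarray,
                 rel_threshold: float = 0.005) -> float:
    """Droplet-phase fraction of the total signal in one trace.

    ``baseline`` is the baseline curve on the trace's grid (a flat array or
    an ALS baseline).  Peaks are contiguous regions with
    (y − z)/z > rel_threshold; their trapezoidal area above the baseline is
    divided by the trapezoidal area under the whole trace.
    """
    z = np.asarray(baseline, dtype=float)
    if z.shape != trace.signal.shape:
        raise ValidationError("baseline must be on the trace's grid")
    if (z <= 0).any():
        raise ValidationError("relative criterion undefined: baseline <= 0 somewhere")
    curve_area = float(np.trapezoid(trace.signal, trace.time))
    if curve_area <= 0:
        raise ValidationError("degenerate trace: non-positive total curve area")
    excess = trace.signal - z
    peak_area = sum(
        _run_integral(trace.time, excess, s, e)
        for s, e in _runs_above(excess / z > rel_threshold)
    )
    return peak_area / curve_area


def relative_enrichment(
    trace_a: Trace,
    trace_b: Trace,
    baseline_a: np.ndarray,
    baseline_b: np.ndarray,
    rel_threshold: float = 0.005,
) -> float:
    """Ratio(A)/Ratio(B) for paired same-composition traces."""
    ratio_a = signal_ratio(trace_a, baseline_a, rel_threshold)
    ratio_b = signal_ratio(trace_b, baseline_b, rel_threshold)
    if ratio_b == 0:
        raise ValidationError(
            "species B shows no droplet signal (Ratio_B = 0); the enrichment "
            "factor is undefined — check the 0.5% criterion and the baseline")
    return ratio_a / ratio_b


def frap_normalize(i_t: float, i_b: float, i_c: float, i_c0: float) -> float:
    """Photobleaching-corrected FRAP intensity: (I(t) − I(b)) / r, r = I_c/I_c0.

    ``i_c0``/``i_c`` are a control region's intensity before/after the
    bleach; their ratio r is the passive photobleaching rate.
    """
    if i_c0 <= 0 or i_c <= 0:
        raise ValidationError("control intensities must be positive")
    return (i_t - i_b) / (i_c / i_c0)


def throughput(n_samples: int, elapsed_h: float) -> float:
    """Measurement throughput in samples/hour: N/t."""
    if elapsed_h <= 0:
        raise ValidationError("elapsed time must be positive")
    return n_samples / elapsed_h


def mass_fraction(conc_a_um: float, mw_a_da: float,
                  conc_b_um: float, mw_b_da: float) -> float:
    """Mass fraction of species A in an A+B mixture.

    Molecular weights are explicit inputs (Da); no defaults are assumed.
    """
    if min(mw_a_da, mw_b_da) <= 0 or min(conc_a_um, conc_b_um) < 0:
        raise ValidationError("need positive molecular weights and non-negative concentrations")
    mass_a = conc_a_um * mw_a_da
    mass_b = conc_b_um * mw_b_da
    if mass_a + mass_b == 0:
        raise ValidationError("both species absent")
    return mass_a / (mass_a + mass_b)
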