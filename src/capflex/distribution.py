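"""Spike-intensity distribution statistics and the flow model linking them
to relative droplet sizes.

Because peak intensity scales with droplet volume, relative droplet
diameters follow from the cube root of peak heights — relative only; no
absolute µm calibration is attempted.  The residual width of the intensity
distribution for monodisperse particles comes from the parabolic flow
profile: a particle's integrated signal is proportional to its residence
time in the detection window, i.e. to the reciprocal of its local velocity.
With the relative intensity s(r) = u(0)/u(r) = 1/(1 − (r/R)²), the radial
flux density transforms in closed form:

    paper flux law  (1 − r/R)²·r   →  f_S(s) = 6·(1 − √(1 − 1/s))² / s²
    Poiseuille flux (1 − (r/R)²)·r →  f_S(s) = 2 / s³

both supported on s ≥ 1 — a hard lower bound at the centerline intensity.
A monodisperse-sphere calibration convolves this flow kernel with a
lognormal intrinsic-brightness spread and fits a single intensity scale by
maximum likelihood.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .simulate import RADIAL_MODES, radial_cdf, sample_radial_position
from .types import ConfigError, FitError, PeakTable, ValidationError


@dataclass
class IntensityStats:
    """Robust summary of a peak-height distribution."""

    median: float        # FU
    iqr: float           # FU
    width_sd: float      # FU
    n: int
    saturated_fraction: float


def intensity_stats(peaks: PeakTable) -> IntensityStats:
    """Median, IQR, SD and saturation bookkeeping of peak heights.

    An empty table yields an all-NaN sentinel; a mostly-saturated table
    triggers a skew warning because the ceiling truncates the distribution.
    """
    if peaks.n == 0:
        return IntensityStats(float("nan"), float("nan"), float("nan"), 0, float("nan"))
    h = peaks.heights
    q25, q50, q75 = np.quantile(h, [0.25, 0.5, 0.75])
    sat = float(np.mean(peaks.saturated))
    if sat > 0.1:
        warnings.warn(
            f"{sat:.0%} of peaks saturated the detector; the intensity "
            "distribution is skewed by the ceiling")
    return IntensityStats(float(q50), float(q75 - q25),
                          float(np.std(h, ddof=1)) if peaks.n > 1 else 0.0,
                          int(peaks.n), sat)


def relative_diameters(peaks: PeakTable) -> tuple[np.ndarray, int]:
    """Relative droplet diameters ∝ height^(1/3), normalized to median 1.

    Saturated peaks are excluded (their height is a floor, not a
    measurement); the exclusion count is returned alongside.
    """
    keep = ~peaks.saturated
    n_excluded = int(peaks.n - keep.sum())
    h = peaks.heights[keep]
    if h.size == 0:
        return np.array([]), n_excluded
    d = np.cbrt(h)
    return d / np.median(d), n_excluded


# --- monodisperse flow model ---------------------------------------------

def _check_dist_mode(mode: str) -> None:
    if mode not in RADIAL_MODES:
        raise ConfigError(f"unknown pdf mode {mode!r}; expected one of {RADIAL_MODES}")


def intensity_pdf(s: np.ndarray, mode: str = "paper") -> np.ndarray:
    """Monodisperse relative-intensity density on s >= 1 (closed form)."""
    _check_dist_mode(mode)
    s = np.asarray(s, dtype=float)
    out = np.zeros_like(s)
    ok = s >= 1.0
    if mode == "paper":
        x = np.sqrt(1.0 - 1.0 / s[ok])
        out[ok] = 6.0 * (1.0 - x) ** 2 / s[ok] ** 2
    else:
        out[ok] = 2.0 / s[ok] ** 3
    return out


def intensity_cdf(s: np.ndarray, mode: str = "paper") -> np.ndarray:
    """CDF of the relative intensity: the radial CDF at x(s) = √(1 − 1/s)."""
    _check_dist_mode(mode)
    s = np.asarray(s, dtype=float)
    out = np.zeros_like(s)
    ok = s >= 1.0
    out[ok] = radial_cdf(np.sqrt(1.0 - 1.0 / s[ok]), mode)
    return out


def predicted_intensity_distribution(
    mode: str = "paper",
    n_grid: int = 512,
    s_max: float = 50.0,
    velocity_profile: str = "poiseuille",
) -> tuple[np.ndarray, np.ndarray]:
    """Relative-intensity density on a grid, normalized over [1, s_max].

    ``velocity_profile="plug"`` (uniform velocity) collapses the density to
    a single bin at s = 1: every particle resides equally long in the
    detection window.
    """
    if n_grid < 100:
        warnings.warn(f"n_grid = {n_grid} is coarse; the density may be under-resolved")
    s = np.linspace(1.0, s_max, n_grid)
    if velocity_profile == "plug":
        dens = np.zeros(n_grid)
        dens[0] = 2.0 / (s[1] - s[0])  # delta-like: all mass in the first bin
        return s, dens
    if velocity_profile != "poiseuille":
        raise ConfigError("velocity_profile must be 'poiseuille' or 'plug'")
    dens = intensity_pdf(s, mode)
    dens = dens / np.trapezoid(dens, s)   # renormalize over the truncated support
    return s, dens


def sample_relative_intensity(n: int, mode: str, rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo draws of the relative intensity: r → 1/u(r) on a unit capillary."""
    x = sample_radial_position(1.0, mode, rng, size=n)
    return 1.0 / (1.0 - x ** 2)


@dataclass
class SphereFit:
    """Monodisperse-sphere calibration fit."""

    scale: float            # FU per unit relative intensity
    brightness_cv: float
    mode: str
    ks_stat: float
    ks_pvalue: float


def _model_pdf_factory(scale: float, brightness_cv: float, mode: str):
    """pdf(i) of I = scale·S·B with B lognormal (mean 1, CV brightness_cv)."""
    if brightness_cv == 0.0:
        def pdf(i: np.ndarray) -> np.ndarray:
            return intensity_pdf(np.asarray(i, dtype=float) / scale, mode) / scale
        return pdf
    sig2 = np.log1p(brightness_cv ** 2)
    sig = np.sqrt(sig2)
    mu = -0.5 * sig2
    s_nodes = np.concatenate([np.linspace(1.0, 3.0, 241),
                              np.geomspace(3.0, 200.0, 160)[1:]])
    f_s = intensity_pdf(s_nodes, mode)

    def pdf(i: np.ndarray) -> np.ndarray:
        i = np.atleast_1d(np.asarray(i, dtype=float))
        b = i[:, None] / (scale * s_nodes[None, :])
        f_b = np.where(
            b > 0,
            np.exp(-0.5 * ((np.log(np.maximum(b, 1e-300)) - mu) / sig) ** 2)
            / (np.maximum(b, 1e-300) * sig * np.sqrt(2.0 * np.pi)),
            0.0,
        )
        integrand = f_s[None, :] * f_b / (scale * s_nodes[None, :])
        return np.trapezoid(integrand, s_nodes, axis=1)

    return pdf


def fit_sphere_calibration(
    observed_heights: np.ndarray,
    brightness_cv: float = 0.1,
    mode: str = "paper",
) -> SphereFit:
    """Fit the flow model × lognormal brightness spread to sphere peak heights.

    A single intensity scale is fitted by maximum likelihood; the
    Kolmogorov–Smirnov statistic against the fitted model is reported as the
    goodness-of-fit.  With ``brightness_cv = 0`` the model's support starts
    at the scale itself (the centerline intensity), and the ML scale is the
    sample minimum.
    """
    _check_dist_mode(mode)
    obs = np.asarray(observed_heights, dtype=float)
    if obs.size < 50:
        raise ValidationError(f"need at least 50 observed heights, got {obs.size}")
    if np.ptp(obs) == 0:
        raise FitError("degenerate observations: all heights equal")
    if (obs <= 0).any():
        raise ValidationError("heights must be positive")

    if brightness_cv == 0.0:
        scale = float(obs.min())
    else:
        # typical S is ~1.2-1.5; bracket the scale around the low quantiles
        lo = float(np.quantile(obs, 0.01)) / 5.0
        hi = float(np.median(obs)) * 2.0

        def nll(log_scale: float) -> float:
            pdf = _model_pdf_factory(np.exp(log_scale), brightness_cv, mode)
            vals = pdf(obs)
            return -float(np.sum(np.log(np.maximum(vals, 1e-300))))

        res = optimize.minimize_scalar(nll, bounds=(np.log(lo), np.log(hi)),
                                       method="bounded",
                                       options={"xatol": 1e-6})
        scale = float(np.exp(res.x))

    # goodness of fit: KS against the fitted model's CDF
    if brightness_cv == 0.0:
        def cdf(i: np.ndarray) -> np.ndarray:
            return intensity_cdf(np.asarray(i, dtype=float) / scale, mode)
    else:
        grid = np.linspace(min(obs.min() * 0.5, scale * 0.5),
                           obs.max() * 1.5, 2048)
        pdf_vals = _model_pdf_factory(scale, brightness_cv, mode)(grid)
        cum = np.concatenate([[0.0], np.cumsum(
            0.5 * (pdf_vals[1:] + pdf_vals[:-1]) * np.diff(grid))])
        cum = np.clip(cum / max(cum[-1], 1e-300), 0.0, 1.0)

        def cdf(i: np.ndarray) -> np.ndarray:
            return np.interp(np.asarray(i, dtype=float), grid, cum)

    ks = stats.kstest(obs, cdf)
    return SphereFit(scale, brightness_cv, mode, float(ks.statistic), float(ks.pvalue))


def draw_model_heights(
    n: int,
    scale: float,
    brightness_cv: float,
    mode: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample peak heights from the calibration model itself (for checks)."""
    s = sample_relative_intensity(n, mode, rng)
    if brightness_cv == 0.0:
        return scale * s
    sig2 = np.log1p(brightness_cv ** 2)
    b = rng.lognormal(-0.5 * sig2, np.sqrt(sig2), n)
    return scale * s * b
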