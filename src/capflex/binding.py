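"""Taylor-dispersion readout and cooperative binding-isotherm fitting.

A small plug of labeled indicator pushed through the capillary by laminar
flow disperses into a Gaussian whose temporal variance encodes the
indicator's diffusivity: D = r_c²·t_R / (24·σ_t²).  Stokes–Einstein then
converts diffusivity to an apparent hydrodynamic radius.  Titrating an
analyte against a fixed indicator shifts the apparent radius between the
unbound and fully-bound values; the shift follows a fully-cooperative 1:n
isotherm (Hill exponent n, no partially-occupied species):

    f_b = ([A]/K_d)ⁿ / (1 + ([A]/K_d)ⁿ)
    1/R_h = (1 − f_b)/R_h,unbound + f_b/R_h,bound

which is algebraically identical to the conventional indicator-size
equations for n = 1 and n = 2.  The overall association constant of the
n-site reaction is (K_a)ⁿ = [IAₙ]/([I][A]ⁿ); the reported K_d is 1/K_a,
the per-site concentration scale at which binding occurs.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize

from .simulate import stokes_einstein_diffusivity
from .types import (
    K_B,
    BindingModel,
    CapillarySystem,
    FitError,
    Trace,
    ValidationError,
)


def _gaussian(t: np.ndarray, amp: float, center: float, sigma: float,
              offset: float) -> np.ndarray:
    return offset + amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)


def taylorgram_rh(trace: Trace, system: CapillarySystem,
                  temperature: float = 293.15) -> float:
    """Apparent hydrodynamic radius (nm) from a single-peak Taylorgram.

    Fits a Gaussian (amplitude, centre t_R, width σ_t, offset), converts the
    width to a diffusivity via D = r_c²·t_R/(24·σ_t²) and inverts
    Stokes–Einstein at the given temperature.
    """
    t, y = trace.time, trace.signal
    offset0 = float(np.quantile(y, 0.05))
    amp0 = float(y.max() - offset0)
    if amp0 <= 0:
        raise FitError("trace has no peak above its floor")
    center0 = float(t[np.argmax(y)])
    weights = np.clip(y - offset0, 0.0, None)
    wsum = weights.sum()
    sigma0 = float(np.sqrt(np.sum(weights * (t - center0) ** 2) / wsum)) if wsum > 0 else trace.dt
    try:
        popt, _ = optimize.curve_fit(
            _gaussian, t, y, p0=[amp0, center0, max(sigma0, trace.dt), offset0],
            maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"Gaussian fit did not converge: {exc}") from exc
    _, t_r, sigma, _ = popt
    sigma2 = float(sigma) ** 2
    if sigma2 <= 0 or t_r <= 0:
        raise FitError("degenerate Taylorgram peak (non-positive centre or variance)")
    d_diff = system.radius ** 2 * float(t_r) / (24.0 * sigma2)
    r_h_m = K_B * temperature / (6.0 * math.pi * system.viscosity * d_diff)
    return r_h_m * 1e9


def bound_fraction(analyte_conc: np.ndarray, k_d: float, n: int) -> np.ndarray:
    """Fully-cooperative bound fraction ([A]/K_d)ⁿ / (1 + ([A]/K_d)ⁿ)."""
    x = (np.asarray(analyte_conc, dtype=float) / k_d) ** n
    return x / (1.0 + x)


def binding_isotherm(model: BindingModel, analyte_conc: float | np.ndarray) -> float | np.ndarray:
    """Apparent hydrodynamic radius (nm) at an analyte concentration (µM)."""
    a = np.asarray(analyte_conc, dtype=float)
    if (a < 0).any():
        raise ValidationError("analyte concentration must be non-negative")
    f_b = bound_fraction(a, model.k_d, model.stoichiometry_n)
    inv_rh = (1.0 - f_b) / model.r_h_unbound + f_b / model.r_h_bound
    out = 1.0 / inv_rh
    return float(out) if out.ndim == 0 else out


@dataclass
class BindingFit:
    """Result of a nonlinear least-squares isotherm fit.

    ``stderr`` holds Jacobian-based standard errors keyed like the model
    parameters.  The overall association constant of the fitted reaction is
    (1/k_d)ⁿ; ``k_d`` itself is the per-site scale 1/K_a.
    """

    model: BindingModel
    stderr: dict[str, float]
    rss: float
    n_points: int

    @property
    def overall_association_constant(self) -> float:
        """(K_a)ⁿ = [IAₙ]/([I][A]ⁿ), in µM⁻ⁿ."""
        return (1.0 / self.model.k_d) ** self.model.stoichiometry_n


def fit_binding(
    analyte_conc: np.ndarray,
    rh_nm: np.ndarray,
    stoichiometry_n: int,
    fix_unbound: Optional[float] = None,
    sd_nm: Optional[np.ndarray] = None,
) -> BindingFit:
    """Fit (K_d, R_h,unbound, R_h,bound) to a titration by least squares.

    The fit runs in log10(K_d) with positivity bounds on the radii;
    initialization takes R_unbound from the lowest-concentration point,
    R_bound from the highest, and K_d from the mid-transition concentration.
    Unweighted by default; pass per-point SDs for weighted residuals.  A K_d
    landing more than 10× outside the titrated range triggers an
    extrapolation warning.
    """
    a = np.asarray(analyte_conc, dtype=float)
    r = np.asarray(rh_nm, dtype=float)
    if a.shape != r.shape:
        raise ValidationError("analyte and radius arrays must have equal length")
    if stoichiometry_n not in (1, 2, 3):
        raise ValidationError("stoichiometry_n must be 1, 2 or 3")
    n_free = 2 if fix_unbound is not None else 3
    if a.size < n_free + 1:
        raise ValidationError(
            f"underdetermined: {a.size} points for {n_free} parameters")
    w = 1.0 / np.asarray(sd_nm, dtype=float) if sd_nm is not None else None

    order = np.argsort(a)
    r_u0 = fix_unbound if fix_unbound is not None else float(r[order[0]])
    r_b0 = float(r[order[-1]])
    if abs(r_b0 - r_u0) < 1e-9:
        r_b0 = r_u0 * 1.5  # flat-looking data; let the fit decide
    mid = 0.5 * (r_u0 + r_b0)
    pos = a[order] > 0
    crossing = np.nonzero(np.sign(r[order] - mid)[pos] != np.sign(r_u0 - mid))[0]
    kd0 = float(a[order][pos][crossing[0]]) if crossing.size else float(np.median(a[a > 0]))
    kd0 = max(kd0, 1e-6)

    def unpack(theta: np.ndarray) -> BindingModel:
        if fix_unbound is not None:
            log_kd, r_b = theta
            r_u = fix_unbound
        else:
            log_kd, r_u, r_b = theta
        return BindingModel(stoichiometry_n, 10.0 ** log_kd, r_u, r_b)

    def residuals(theta: np.ndarray) -> np.ndarray:
        res = binding_isotherm(unpack(theta), a) - r
        return res * w if w is not None else res

    if fix_unbound is not None:
        theta0 = np.array([math.log10(kd0), r_b0])
        bounds = ([-9.0, 1e-3], [9.0, 1e3])
        names = ["k_d_log10", "r_h_bound"]
    else:
        theta0 = np.array([math.log10(kd0), r_u0, r_b0])
        bounds = ([-9.0, 1e-3, 1e-3], [9.0, 1e3, 1e3])
        names = ["k_d_log10", "r_h_unbound", "r_h_bound"]
    sol = optimize.least_squares(residuals, theta0, bounds=bounds, xtol=1e-12,
                                 ftol=1e-12, gtol=1e-12)
    if not sol.success:
        raise FitError(f"binding fit did not converge: {sol.message}")
    model = unpack(sol.x)
    rss = float(np.sum(sol.fun ** 2))

    dof = max(a.size - len(sol.x), 1)
    jtj = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(jtj) * rss / dof
        se_theta = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se_theta = np.full(len(sol.x), np.nan)
    stderr = dict(zip(names, (float(s) for s in se_theta)))
    # delta method: SE(K_d) = ln(10) · K_d · SE(log10 K_d)
    stderr["k_d"] = math.log(10.0) * model.k_d * stderr["k_d_log10"]

    titrated = a[a > 0]
    if titrated.size and not (titrated.min() / 10.0 <= model.k_d <= titrated.max() * 10.0):
        warnings.warn(
            f"fitted K_d = {model.k_d:.3g} µM lies >10x outside the titrated "
            f"range [{titrated.min():.3g}, {titrated.max():.3g}] µM")
    return BindingFit(model, stderr, rss, int(a.size))


def select_stoichiometry(
    analyte_conc: np.ndarray,
    rh_nm: np.ndarray,
    candidates: tuple[int, ...] = (1, 2, 3),
    fix_unbound: Optional[float] = None,
) -> tuple[int, dict[int, BindingFit]]:
    """Fit each candidate stoichiometry and pick the lowest residual sum of squares."""
    fits: dict[int, BindingFit] = {}
    for n in candidates:
        try:
            fits[n] = fit_binding(analyte_conc, rh_nm, n, fix_unbound=fix_unbound)
        except FitError:
            continue
    if not fits:
        raise FitError("no candidate stoichiometry converged")
    best = min(fits, key=lambda n: fits[n].rss)
    return best, fits
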