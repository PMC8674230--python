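# Methods

This note records the models, parameter choices and numerical conventions
behind `capflex`, and what the synthetic-data generator does and does not
emulate.

## The measurement model

A capillary-flow LLPS measurement pushes a (possibly phase-separated)
sample through a thin capillary past a point fluorescence detector.  The
trace decomposes as

    signal(t) = front(t) · baseline_FU + Σ_droplets spike_i(t) + noise,

clipped at the detector ceiling.  The baseline is proportional to the
labeled-species concentration in the dilute phase (standard-curve
calibration); each droplet contributes a spike whose **amplitude** scales
with droplet volume (fluorophore content) and whose **width** is its
residence time in the detection window, detection_window / u(r), with
u(r) = U_max·(1 − (2r/D)²) the Poiseuille profile at the droplet's radial
position.  Residence time therefore affects spike width and area, not
height.  Overlapping spikes add linearly (fluorescence additivity) before
clipping.

### Front geometry

The centerline fluid arrives at the detector at the dead time
t₀ = L/U_max; slower streamlines arrive later, producing a sigmoidal rise.
Two front modes:

- **hydrodynamic** — the exact fill geometry: the fraction of the
  cross-section carrying sample at the detector is f(t) = 1 − t₀/t
  (reaches 50% of the plateau at exactly 2·t₀).  This tail approaches the
  plateau slowly (99% only at 100·t₀).
- **logistic** (default) — a 4-parameter logistic rising from ≈1% at t₀ to
  ≈99% at 1.5·t₀ (midpoint 1.25·t₀).  This matches the observed behavior of
  the real instrument, whose front settles within ~50% of the dead time
  (8 s dead time, stable baseline by ~12 s) because the fill happens at
  constant pressure for a finite time rather than asymptotically.

### Radial droplet positions

Two flux-weighting conventions are implemented because the published flux
law differs from the standard Poiseuille one:

- `"paper"` (default): flux ∝ (1 − r/R)²·r — normalized density
  12(1 − x)²x on x = r/R, CDF 6x² − 8x³ + 3x⁴;
- `"poiseuille"`: flux ∝ (1 − (r/R)²)·r — density 4(1 − x²)x, CDF
  2x² − x⁴ (inverted in closed form).

No ruling is made on which is physically intended; both are exposed
end-to-end (simulator, distribution model, acceptance checks).

## Simulator conditions (defaults)

These constants define the study conditions and are fixed, not tuned:

| parameter | default | why |
|---|---|---|
| capillary | 75 µm ID × 1 m, turn radius 5 mm, water (μ = 10⁻³ Pa·s, ρ = 10³ kg/m³, 20 °C) | the instrument geometry |
| fill pressure | 3500 mbar → dead time 8.13 s | the instrument's fast-fill protocol |
| measurement pressure | 50 mbar | fill-fast/measure-slow protocol; droplet transits then span ≥ 2–3 sampling intervals so spikes carry full amplitude |
| detection window | 50 µm | not specified by the instrument documentation; configurable |
| sampling rate | 100 Hz | resolves ~30 ms droplet transits |
| calibration | 0.05 FU/µM through zero | places a 70 µM dilute phase at 3.5 FU |
| noise | 0.05 FU additive Gaussian | detector-like; the level used in all recovery studies |
| saturation ceiling | 50 FU | the detector's ceiling |
| droplet volumes | lognormal (σ = 0.5 log-units) | positive, right-skewed like observed droplet populations |
| trace length | 120 s | ≥ 31 baseline samples by a wide margin |

Spikes are deposited area-preserving on the sampling grid (each bin gets
amplitude × fractional overlap), so total fluorescence is conserved exactly
and sub-sample spikes keep their area at reduced height (logged as a
warning).  The kinetics-trace generator uses noise 0.005 FU on a 2.5 FU
baseline: the droplet criterion for kinetics is *relative* (1% above
baseline), and the generator must keep noise well below that criterion —
at 10σ here — for the criterion to identify droplets rather than noise, as
it evidently does on real traces.

What the simulator does **not** emulate: droplet deformation or breakup in
shear, inner-filter effects, photobleaching along the capillary, detector
nonlinearity below the ceiling, slow baseline drift, and non-Gaussian
detector noise.  Passing recovery tests therefore demonstrate correctness
of the analysis chain under the stated model, not robustness to every
instrumental artifact.

## Baseline extraction

Fixed recipe: (1) 4-parameter logistic fit to the full trace (initialized
from the 2%/98% quantiles, the half-range crossing, and the 25–75% rise
time); the baseline region starts where the fitted curve first exceeds 99%
of its upper asymptote.  (2) Samples above 1.10× the calibration-predicted
total-concentration signal are discarded (hard cut, applied before
filtering).  (3) 31-sample median filter — a sample count, not a time
window, so the effective time span scales with the sampling rate; the
window is exposed in the API and CLI.  (4) Lower 5% quantile of the
filtered series (linear-interpolation/type-7 quantiles throughout, for
bit-reproducibility), taken over the filtered series rather than the
unfiltered survivors.  The 5% quantile of filtered noise sits slightly
below the mean, giving a small negative bias (≈ −0.3 µM at noise 0.05 FU
and slope 0.05 FU/µM) — well inside the ±3 µM recovery band and accepted
as the price of spike robustness.

Peak detection uses an **absolute** 0.2 FU threshold above the baseline.
A peak is one contiguous supra-threshold region: this makes droplet counts
exact for non-overlapping spikes, where a literal local-maximum rule would
split noisy spike tops.  Peak time is the first sample of the region's
maximum plateau (relevant for saturated, flat-topped spikes); the integral
is the area above the baseline between the threshold crossings, computed
by trapezoid over the region extended one sample each side (exact for
rectangular spikes on the grid).  Saturation is flagged when the raw
maximum reaches the ceiling.

The three peak criteria are deliberately different, as each analysis
defines its own: 0.2 FU absolute (baseline analysis), 1% relative
(kinetics), 0.5% relative (enrichment).

## ALS baseline (kinetics)

Whittaker-style asymmetric least squares: minimize
Σ w_i(y_i − z_i)² + λ Σ(Δ²z_i)², second-difference penalty, λ = 10⁴,
asymmetry p = 0.001 (weights p above the baseline, 1 − p below),
re-weighted for at most 20 passes or until the maximum relative change of
z falls below 0.005.  The originating analysis software names these
"symmetric factor / smoothing factor / threshold / iterations"; the
mapping adopted here is symmetric factor → p, smoothing factor → log₁₀λ,
threshold → convergence tolerance (the alternative clipping reading is not
implementable from the available description), iterations → cap.  Solved
with sparse Cholesky-free `spsolve`; a dense direct solve of the same
system is the test oracle (< 10⁻⁸ relative agreement per iteration).

## Binding

The 1:n isotherm assumes full cooperativity (no partially-bound species —
deliberately, since titration data only pin the end-state sizes), with the
overall association constant (K_a)ⁿ = [IAₙ]/([I][A]ⁿ) and the reported
K_d = 1/K_a.  Indicator depletion is ignored (indicator is held at nM
against µM analyte).  The fit runs in log₁₀K_d with positivity bounds on
radii; initialization from the titration endpoints and the mid-transition
concentration; unweighted least squares by default with optional per-point
SD weights.  Standard errors come from the Jacobian at the solution
(cov = (JᵀJ)⁻¹·RSS/dof), with the K_d error delta-transformed from
log-space.  Stoichiometry selection compares residual sums of squares
across n ∈ {1, 2, 3}.

Taylorgrams: Gaussian fit (amplitude, centre, width, offset);
D = r_c²·t_R/(24σ_t²); R_h from Stokes–Einstein at the configured
temperature (default 293.15 K — the instrument runs 20–37 °C, so the
temperature must be explicit).  Note the dispersion relation contains no
viscosity: for a fixed trace, changing μ changes R_h as 1/μ through
Stokes–Einstein only.

## Flow physics

Physical mode uses the standard laminar-pipe results:
U_max = ΔP·D²/(16μL), U_mean = U_max/2, dead time L/U_max, fill time
L/U_mean.  These reproduce the instrument's measured ~8 s dead time at
3500 mbar.  The published order-of-magnitude mode evaluates ΔP·D²/(8μL)
and rounds to the nearest power of ten, reproducing the printed ≈10⁻¹ m/s
chain.  Two dead-time-like quantities are reported distinctly:
**dead time** (centerline arrival, 8.1 s at 3500 mbar) and **fill time**
(one capillary volume, 2× dead time, 16.3 s) — the "~15 s" sometimes
quoted for instrument latency corresponds to the fill, not the front
arrival.  The published wall-shear figure (2 Pa) is not derivable from its
own velocity scale (8·U_mean/D·μ gives ≈6.6 Pa at the instrument's
conditions); the physical value is reported and the published number is
carried as an explicitly flagged discrepancy.

## Enrichment

Ratio = Σ(peak areas above baseline)/(total curve area), both by
trapezoid on the native grid; peaks are contiguous regions >0.5% above the
baseline.  The ratio of ratios between two labelings of the same
composition cancels the dense-phase volume fraction.  Known bias: additive
noise contributes small spurious peak area to both ratios, pulling a true
enrichment of 1.5 toward ≈1.36 at noise 0.05 FU on a 3 FU baseline — well
inside the ±0.26 empirical spread and vanishing as noise → 0 (noise-free
recovery is exact to <1%).  The mass-fraction helper takes molecular
weights as explicit inputs and asserts no defaults.

## Distribution model

Relative intensity of a monodisperse particle: s(r) = u(0)/u(r) =
1/(1 − (r/R)²) ≥ 1 — a hard lower bound at the centerline.  The radial
flux densities transform in closed form: f_S(s) = 6(1 − √(1 − 1/s))²/s²
(paper mode) and 2/s³ (Poiseuille mode), with CDFs obtained by mapping
back to the radial CDF.  The density grid is truncated at s_max
(default 50; tail mass ~s_max⁻³ and ~s_max⁻² respectively) and
renormalized.  The sphere-calibration model is I = scale·S·B with B
lognormal (mean 1, CV given); the scale is fitted by maximum likelihood
(numeric convolution over an s-grid; for CV = 0 the likelihood is
monotone in the scale up to the support boundary, so the ML scale is the
sample minimum).  Goodness of fit is a Kolmogorov–Smirnov statistic
against the fitted CDF.  Sub-centerline observations are impossible under
the pure flow model and are attributed to the brightness-spread term.

## Problem sizes

Recovery studies use 120 s traces at 100 Hz (12 000 samples) with 150–200
droplets, 100-replicate Monte-Carlo titration studies on a 12-point
0–358 µM grid, 10⁶-draw Monte-Carlo checks of the flow model over 64
radial bins, and an n = 200 ALS oracle — sizes at which every estimate in
this package is stable to well within its stated tolerance.

## Known limitations

- Absolute droplet sizes are out of scope by design; only relative
  distributions are claimed, and saturated peaks are excluded from size
  statistics (reported separately).
- The baseline recipe presumes a single front followed by a quasi-steady
  baseline; multi-front injections or strong drift need pre-segmentation.
- The relative (1%, 0.5%) criteria presume noise well below the criterion;
  traces violating that will count noise as droplets.
- The binding model ignores indicator depletion and partial occupancy.
- Dean-flow and inertial-focusing numbers are screening estimates, not
  flow solutions.
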