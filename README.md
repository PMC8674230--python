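# capflex

Quantitative analysis of protein liquid–liquid phase separation (LLPS) from
capillary-flow fluorescence traces.

When a phase-separated protein sample is pushed through a thin thermostatted
capillary past a fluorescence detector, the recording has two informative
components: a flat **baseline** whose level is proportional to the labeled
species' concentration in the dilute phase, and **signal spikes** as
individual condensate droplets transit the detection window.  From a single
trace one can therefore read the dilute-phase (saturation) concentration —
the thermodynamically meaningful quantity at phase coexistence — count
droplets, follow their formation kinetics, and estimate relative droplet
size distributions.  The same instrument, run in plug-injection mode,
measures binding affinities by Taylor dispersion.

`capflex` implements the full analysis chain for this kind of measurement,
together with a physics-based simulator that generates traces with known
ground truth, so every stage is testable without instrument data.

## What it computes

- **Standard-curve calibration and dilute-phase concentration.**  Baseline
  FU vs. concentration is an OLS line; a trace's baseline is extracted by
  fitting a 4-parameter logistic to the solution front, keeping the region
  past 99% of the plateau, discarding samples above 1.10× the expected
  signal, median-filtering (31 samples) and taking the lower 5% quantile.
- **Droplet spikes.**  Local maxima more than 0.2 FU above the baseline,
  with heights, areas and detector-saturation flags (ceiling 50 FU).
- **Formation kinetics.**  Asymmetric least-squares (Whittaker) baseline
  (p = 0.001, λ = 10⁴, 20 iterations), droplets as local maxima >1% above
  the baseline, 10-peak sliding averages, lag time and early growth rate
  from a 0–2 min linear fit.
- **Binding isotherms.**  Gaussian Taylorgram fits give
  D = r_c²·t_R/(24·σ_t²) and R_h = k_BT/(6πμD); titrations are fitted with
  a fully cooperative 1:n model,
  f_b = ([A]/K_d)ⁿ/(1 + ([A]/K_d)ⁿ), 1/R_h = (1−f_b)/R_u + f_b/R_b.
- **Relative enrichment.**  Ratio = Σ(peak areas)/(curve area) per labeled
  species; the ratio of ratios is volume-fraction free.
- **Size distributions.**  Relative diameters ∝ height^(1/3); the
  monodisperse flow model maps the radial flux density through the
  reciprocal Poiseuille velocity to predict the intensity spread of
  identical particles (closed form for both flux conventions).
- **Flow physics.**  Hagen–Poiseuille maximum/mean velocity, dead time
  (L/U_max), fill time, Reynolds and Dean numbers, inertial focusing
  length, wall shear stress — each also available in a published
  order-of-magnitude mode.

## Worked example

```python
import numpy as np
from capflex import simulate as sim, baseline as bl, distribution as dist
from capflex.types import SyntheticGroundTruth

gt = SyntheticGroundTruth(total_conc=100.0, dilute_conc=70.0, droplet_count=200)
cfg = sim.SimulationConfig(ground_truth=gt, noise_sd=0.05)
trace, events = sim.simulate_trace(cfg, seed=1)

calib = sim.default_calibration()                      # 0.05 FU/µM
res = bl.extract_baseline(trace, calib, expected_total_conc=100.0)
peaks = bl.detect_peaks(trace, res)
print(f"baseline {res.baseline_fu:.3f} FU -> dilute phase {res.dilute_phase_conc:.1f} uM")
print(f"partitioned: {bl.partitioned_amount(100.0, res.dilute_phase_conc):.1f} uM")
print(f"{peaks.n} droplet spikes detected ({int(peaks.saturated.sum())} saturated)")
st = dist.intensity_stats(peaks)
print(f"median spike height {st.median:.2f} FU, IQR {st.iqr:.2f} FU")
```

prints

```
baseline 3.483 FU -> dilute phase 69.7 uM
partitioned: 30.3 uM
189 droplet spikes detected (0 saturated)
median spike height 3.35 FU, IQR 2.51 FU
```

The simulated sample held 100 µM protein of which 30 µM (dilute-phase
equivalent) partitioned into droplets; the analysis reads the 70 µM
dilute-phase truth back to 0.3 µM.  189 of the 200 simulated droplets clear
the 0.2 FU detection threshold (the rest are too dim or overlap).

A command-line interface mirrors the library:

```
capflex flowcalc --pressure-mbar 3500 --diameter-um 75 --length-m 1
capflex simulate --seed 1 --out trace.csv
capflex analyze --trace trace.csv --calibration calib.csv --total-conc 100
```

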