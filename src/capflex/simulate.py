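"""Physics-based synthetic trace generator with known ground truth.

Emulates what the capillary detector records during a phase-separation
measurement: a sigmoidal solution front (the parabolic Poiseuille profile
brings the centerline fluid to the detector first, at the dead time t0), a
flat dilute-phase baseline proportional to the labeled-species
concentration, droplet spikes whose amplitude scales with droplet volume and
whose width is the residence time of the droplet in the detection window at
its radial position, detector saturation at a fixed ceiling, and additive
Gaussian noise.  A Taylorgram generator produces the Gaussian dispersion
plugs used for hydrodynamic-radius readouts.

The default conditions mirror the measurement protocol the analysis modules
target: the capillary (75 µm × 1 m, water-like fluid) is filled fast at
3500 mbar — giving the ~8 s dead time — and the measurement then continues
at a lower pressure (50 mbar default) so droplet transits through the 50 µm
detection window span several sampling intervals at 100 Hz.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import flow
from .types import (
    K_B,
    MBAR_TO_PA,
    CalibrationCurve,
    CapillarySystem,
    ConfigError,
    SyntheticGroundTruth,
    Trace,
    ValidationError,
)

logger = logging.getLogger(__name__)

RADIAL_MODES = ("paper", "poiseuille")
FRONT_MODES = ("logistic", "hydrodynamic")


def default_calibration(slope: float = 0.05, intercept: float = 0.0) -> CalibrationCurve:
    """A clean synthetic standard curve (default 0.05 FU/µM through zero)."""
    conc = np.array([10.0, 20.0, 50.0])
    return CalibrationCurve(conc, slope * conc + intercept, slope, intercept, 1.0)


# --- Poiseuille kinematics ------------------------------------------------

def local_velocity(system: CapillarySystem, r: float | np.ndarray) -> float | np.ndarray:
    """Local axial velocity u(r) = U_max · (1 − (2r/D)²), m/s.

    Valid for 0 <= r < D/2; positions at or beyond the wall are rejected.
    """
    r = np.asarray(r, dtype=float)
    if (r < 0).any() or (r >= system.radius).any():
        raise ValidationError("radial position must satisfy 0 <= r < D/2")
    u_max = flow.max_velocity(system)
    out = u_max * (1.0 - (r / system.radius) ** 2)
    return float(out) if out.ndim == 0 else out


def radial_density(x: np.ndarray, mode: str = "paper") -> np.ndarray:
    """Normalized particle-flux density over the reduced radius x = r/R ∈ [0, 1).

    ``"paper"`` uses the published flux law ∝ (1 − x)²·x; ``"poiseuille"``
    uses the standard flux weighting ∝ (1 − x²)·x.  Both vanish at the wall;
    the paper form also vanishes at the centerline.
    """
    x = np.asarray(x, dtype=float)
    if mode == "paper":
        return 12.0 * (1.0 - x) ** 2 * x          # ∫₀¹ (1−x)²x dx = 1/12
    if mode == "poiseuille":
        return 4.0 * (1.0 - x ** 2) * x           # ∫₀¹ (1−x²)x dx = 1/4
    raise ConfigError(f"unknown radial pdf mode {mode!r}; expected one of {RADIAL_MODES}")


def radial_cdf(x: np.ndarray, mode: str = "paper") -> np.ndarray:
    """Closed-form CDF of :func:`radial_density` on the reduced radius."""
    x = np.asarray(x, dtype=float)
    if mode == "paper":
        return 6.0 * x ** 2 - 8.0 * x ** 3 + 3.0 * x ** 4
    if mode == "poiseuille":
        return 2.0 * x ** 2 - x ** 4
    raise ConfigError(f"unknown radial pdf mode {mode!r}; expected one of {RADIAL_MODES}")


def sample_radial_position(
    radius: float,
    mode: str,
    rng: np.random.Generator,
    size: Optional[int] = None,
) -> float | np.ndarray:
    """Draw radial positions (m) from the flux-weighted density.

    The Poiseuille-mode CDF inverts in closed form; the paper-mode quartic
    CDF is inverted by interpolation on a dense grid.
    """
    u = rng.random(size if size is not None else 1)
    if mode == "poiseuille":
        x = np.sqrt(1.0 - np.sqrt(1.0 - u))
    elif mode == "paper":
        grid = np.linspace(0.0, 1.0, 4097)
        x = np.interp(u, radial_cdf(grid, mode), grid)
    else:
        raise ConfigError(f"unknown radial pdf mode {mode!r}; expected one of {RADIAL_MODES}")
    r = radius * x
    return float(r[0]) if size is None else r


# --- droplet events and configuration ------------------------------------

@dataclass
class DropletEvent:
    """One droplet transit: when it enters the detection window, where in the
    cross-section it rides, its volume and intrinsic brightness."""

    entry_time: float            # s
    radial_position: float       # m, 0 <= r < D/2
    volume: float                # arbitrary volume units
    brightness_per_volume: float  # FU per volume unit

    @property
    def amplitude(self) -> float:
        """Unclipped spike amplitude, FU: brightness × volume."""
        return self.brightness_per_volume * self.volume

    def residence_time(self, system: CapillarySystem) -> float:
        """Transit time through the detection window, s."""
        return system.detection_window / local_velocity(system, self.radial_position)


@dataclass
class SimulationConfig:
    """All knobs of one synthetic measurement.

    ``noise_sd`` may be 0 for noise-free reference traces; the saturation
    ceiling must always exceed it.  ``fill_pressure_mbar`` sets the dead time
    (fast capillary fill), while ``system.pressure_pa`` governs droplet
    residence times during the measurement itself.
    """

    system: CapillarySystem = field(default_factory=CapillarySystem)
    ground_truth: SyntheticGroundTruth = field(
        default_factory=lambda: SyntheticGroundTruth(
            total_conc=100.0, dilute_conc=70.0, droplet_count=200)
    )
    calibration: CalibrationCurve = field(default_factory=default_calibration)
    noise_sd: float = 0.05               # FU
    saturation_ceiling: float = 50.0     # FU
    sampling_rate: float = 100.0         # Hz
    duration: float = 120.0              # s
    radial_pdf_mode: str = "paper"
    front_mode: str = "logistic"
    fill_pressure_mbar: float = 3500.0
    brightness_per_volume: float = 3.0   # FU per volume unit
    include_front: bool = True
    non_overlapping: bool = False        # place spikes on a jittered grid

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if self.saturation_ceiling <= self.noise_sd:
            raise ConfigError("saturation ceiling must exceed the noise level")
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be positive")
        if self.radial_pdf_mode not in RADIAL_MODES:
            raise ConfigError(f"radial_pdf_mode must be one of {RADIAL_MODES}")
        if self.front_mode not in FRONT_MODES:
            raise ConfigError(f"front_mode must be one of {FRONT_MODES}")

    @property
    def fill_system(self) -> CapillarySystem:
        sys = self.system
        return CapillarySystem(
            length_l=sys.length_l, inner_diameter=sys.inner_diameter,
            turn_radius=sys.turn_radius, pressure_pa=self.fill_pressure_mbar * MBAR_TO_PA,
            viscosity=sys.viscosity, density=sys.density,
            detection_window=sys.detection_window,
        )

    @property
    def dead_time(self) -> float:
        """Centerline front arrival at the fill pressure, s."""
        return flow.dead_time(self.fill_system)

    @property
    def baseline_fu(self) -> float:
        """Plateau fluorescence implied by the dilute-phase concentration."""
        return float(self.calibration.predict(self.ground_truth.dilute_conc))

    @property
    def front_settle_time(self) -> float:
        """Time at which the front reaches 99% of the plateau."""
        t0 = self.dead_time
        return 1.5 * t0 if self.front_mode == "logistic" else 100.0 * t0


def simulate_front(config: SimulationConfig, time: Optional[np.ndarray] = None) -> np.ndarray:
    """Droplet-free front curve: signal fraction × plateau FU.

    Hydrodynamic mode follows the fill geometry exactly — the fraction of
    the detector cross-section already carrying sample is f(t) = 1 − t0/t
    for t > t0 (50% of plateau at exactly 2·t0).  Logistic mode is a
    4-parameter logistic rising from ~1% at t0 to ~99% at 1.5·t0 (midpoint
    1.25·t0), matching the observed 8 s → 12 s settle of the instrument.
    """
    if time is None:
        time = np.arange(0.0, config.duration, 1.0 / config.sampling_rate)
    t0 = config.dead_time
    if config.front_mode == "hydrodynamic":
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(time > t0, 1.0 - t0 / np.maximum(time, t0), 0.0)
    else:
        rate = 4.0 * math.log(99.0) / t0
        frac = 1.0 / (1.0 + np.exp(-rate * (time - 1.25 * t0)))
    return config.baseline_fu * frac


def _deposit_rectangle(signal: np.ndarray, dt: float, t_start: float,
                       duration: float, amplitude: float) -> None:
    """Add a rectangular spike, conserving its area exactly on the grid.

    Each sample bin i integrates [i·dt, (i+1)·dt); the bin receives the
    amplitude scaled by its fractional overlap with the rectangle, so spikes
    narrower than one sampling interval keep their area (at reduced height).
    """
    i0 = int(np.floor(t_start / dt))
    i1 = int(np.floor((t_start + duration) / dt))
    for i in range(max(i0, 0), min(i1, signal.size - 1) + 1):
        lo = max(t_start, i * dt)
        hi = min(t_start + duration, (i + 1) * dt)
        if hi > lo:
            signal[i] += amplitude * (hi - lo) / dt


def simulate_trace(config: SimulationConfig, seed: int) -> tuple[Trace, list[DropletEvent]]:
    """Generate one full synthetic trace plus its ground-truth droplet events.

    Overlapping spikes sum linearly (fluorescence additivity) before the
    detector ceiling clips the total; Gaussian noise is added last.  Spikes
    narrower than the sampling interval are deposited area-preserving on the
    nearest samples and logged as a warning.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / config.sampling_rate
    time = np.arange(0.0, config.duration, dt)
    if config.include_front:
        signal = simulate_front(config, time)
        window_start = min(config.front_settle_time, config.duration * 0.5)
    else:
        signal = np.full(time.size, config.baseline_fu)
        window_start = 0.0

    gt = config.ground_truth
    n = gt.droplet_count
    events: list[DropletEvent] = []
    if n > 0:
        t_lo, t_hi = window_start + 1.0, config.duration - 1.0
        if t_hi <= t_lo:
            raise ConfigError("trace too short to place droplets after the front")
        if config.non_overlapping:
            spacing = (t_hi - t_lo) / n
            entries = t_lo + spacing * (np.arange(n) + 0.5 +
                                        rng.uniform(-0.2, 0.2, n))
        else:
            entries = rng.uniform(t_lo, t_hi, n)
        radii = sample_radial_position(config.system.radius, config.radial_pdf_mode,
                                       rng, size=n)
        volumes = rng.lognormal(gt.volume_mu, gt.volume_sigma, n)
        narrow = 0
        for t_e, r, v in zip(entries, radii, volumes):
            ev = DropletEvent(float(t_e), float(r), float(v),
                              config.brightness_per_volume)
            dur = ev.residence_time(config.system)
            if dur < dt:
                narrow += 1
            _deposit_rectangle(signal, dt, ev.entry_time, dur, ev.amplitude)
            events.append(ev)
        if narrow:
            logger.warning(
                "%d of %d spikes narrower than the sampling interval; "
                "deposited area-preserving on nearest samples", narrow, n)

    np.minimum(signal, config.saturation_ceiling, out=signal)
    if config.noise_sd > 0:
        signal = signal + rng.normal(0.0, config.noise_sd, signal.size)
    trace = Trace(time, signal, channel="alexa488",
                  pressure_mbar=config.system.pressure_pa / MBAR_TO_PA,
                  sample_id=f"synthetic-seed{seed}",
                  metadata={"seed": seed, "dead_time_s": config.dead_time,
                            "dilute_conc_um": gt.dilute_conc})
    return trace, events


def spike_area(event: DropletEvent, config: SimulationConfig) -> float:
    """Exact area (FU·s) a droplet deposits on the trace, before clipping."""
    return event.amplitude * event.residence_time(config.system)


# --- kinetics traces ------------------------------------------------------

def simulate_kinetics_trace(
    seed: int,
    onset_s: float = 30.0,
    growth_rate_fu_per_min: float = 1.0,
    initial_height_fu: float = 0.3,
    plateau_fu: Optional[float] = None,
    event_interval_s: float = 1.0,
    duration_s: float = 240.0,
    baseline_fu: float = 2.5,
    spike_width_s: float = 0.05,
    noise_sd: float = 0.005,
    sampling_rate: float = 100.0,
) -> tuple[Trace, dict]:
    """Continuously-recorded droplet-formation kinetics trace.

    No droplets before ``onset_s``; from the onset, droplets arrive every
    ``event_interval_s`` (the first exactly at the onset) with heights
    growing linearly at ``growth_rate_fu_per_min`` from ``initial_height_fu``
    until the optional plateau.  Returns the trace and a ground-truth dict
    with event times and heights.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / sampling_rate
    time = np.arange(0.0, duration_s, dt)
    signal = np.full(time.size, baseline_fu)
    event_times = np.arange(onset_s, duration_s - 1.0, event_interval_s)
    heights = initial_height_fu + growth_rate_fu_per_min * (event_times - onset_s) / 60.0
    if plateau_fu is not None:
        heights = np.minimum(heights, plateau_fu)
    for t_e, h in zip(event_times, heights):
        _deposit_rectangle(signal, dt, t_e, spike_width_s, h)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, signal.size)
    trace = Trace(time, signal, channel="alexa488", sample_id=f"kinetics-seed{seed}",
                  metadata={"seed": seed, "onset_s": onset_s})
    truth = {"onset_s": onset_s, "event_times": event_times, "heights": heights,
             "growth_rate_fu_per_min": growth_rate_fu_per_min}
    return trace, truth


# --- Taylorgrams ----------------------------------------------------------

def stokes_einstein_diffusivity(r_h_m: float, viscosity: float = 1.0e-3,
                                temperature: float = 293.15) -> float:
    """D = k_B·T / (6π·μ·R_h), m²/s."""
    if r_h_m <= 0:
        raise ValidationError("hydrodynamic radius must be positive")
    return K_B * temperature / (6.0 * math.pi * viscosity * r_h_m)


def simulate_taylorgram(
    r_h_nm: float,
    system: CapillarySystem,
    residence_time_tr: float,
    amplitude: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    sampling_rate: float = 10.0,
    temperature: float = 293.15,
) -> Trace:
    """Gaussian dispersion plug centred at the residence time t_R.

    The temporal variance encodes the analyte diffusivity through the
    dispersion relation σ_t² = r_c²·t_R / (24·D) with r_c the capillary
    radius and D from Stokes–Einstein at the configured temperature.
    """
    if r_h_nm <= 0 or residence_time_tr <= 0:
        raise ValidationError("R_h and t_R must be positive")
    d_diff = stokes_einstein_diffusivity(r_h_nm * 1e-9, system.viscosity, temperature)
    sigma2 = system.radius ** 2 * residence_time_tr / (24.0 * d_diff)
    sigma = math.sqrt(sigma2)
    if sigma < 3.0 / sampling_rate:
        raise ConfigError(
            f"peak width sigma_t={sigma:.3g}s narrower than 3 sampling intervals; "
            "increase sampling_rate")
    rng = np.random.default_rng(seed)
    time = np.arange(0.0, residence_time_tr + 6.0 * sigma, 1.0 / sampling_rate)
    signal = amplitude * np.exp(-0.5 * ((time - residence_time_tr) / sigma) ** 2)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, signal.size)
    return Trace(time, signal, channel="alexa488", sample_id=f"taylorgram-rh{r_h_nm}nm",
                 metadata={"r_h_nm": r_h_nm, "t_r_s": residence_time_tr,
                           "sigma_t_s": sigma, "temperature_k": temperature})


# --- paired enrichment traces --------------------------------------------

def simulate_enrichment_pair(
    seed: int,
    enrichment: float = 1.5,
    ratio_b: float = 0.10,
    n_droplets: int = 150,
    duration_s: float = 100.0,
    baseline_fu: float = 3.0,
    noise_sd: float = 0.0,
    system: Optional[CapillarySystem] = None,
    sampling_rate: float = 100.0,
    radial_pdf_mode: str = "paper",
    volume_sigma: float = 0.4,
) -> tuple[Trace, Trace, dict]:
    """Two same-composition traces differing only in which species is labeled.

    The droplet-phase signal fraction (Σ spike area / total area) is set to
    ``ratio_b`` for species B and ``enrichment × ratio_b`` for species A, by
    scaling the intrinsic droplet brightness after the droplet events are
    drawn.  Both traces are post-front segments on a flat baseline.
    """
    system = system or CapillarySystem()
    truth = {"enrichment": enrichment, "ratio_a": enrichment * ratio_b,
             "ratio_b": ratio_b}
    traces = []
    for label, frac, sub in (("A", enrichment * ratio_b, 0), ("B", ratio_b, 1)):
        if not (0.0 < frac < 0.9):
            raise ConfigError("target droplet signal fraction must lie in (0, 0.9)")
        rng = np.random.default_rng([seed, sub])
        dt = 1.0 / sampling_rate
        time = np.arange(0.0, duration_s, dt)
        entries = rng.uniform(1.0, duration_s - 1.0, n_droplets)
        radii = sample_radial_position(system.radius, radial_pdf_mode, rng,
                                       size=n_droplets)
        volumes = rng.lognormal(0.0, volume_sigma, n_droplets)
        durations = system.detection_window / local_velocity(system, radii)
        unit_area = float(np.sum(volumes * durations))
        baseline_area = baseline_fu * duration_s
        bpv = frac * baseline_area / ((1.0 - frac) * unit_area)
        signal = np.full(time.size, baseline_fu)
        for t_e, dur, v in zip(entries, durations, volumes):
            _deposit_rectangle(signal, dt, float(t_e), float(dur), bpv * float(v))
        if noise_sd > 0:
            signal = signal + rng.normal(0.0, noise_sd, signal.size)
        traces.append(Trace(time, signal, channel="alexa488",
                            sample_id=f"enrichment-{label}-seed{seed}",
                            metadata={"target_ratio": frac}))
    return traces[0], traces[1], truth
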