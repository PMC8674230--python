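"""Domain types shared across the capillary-flow LLPS analysis toolkit.

Units convention: time in seconds, fluorescence in arbitrary detector units
(FU), concentrations in µM, geometry in SI (metres, Pa, Pa·s, kg/m³).
Pressures are accepted in mbar at user-facing surfaces and converted to Pa
internally (1 mbar = 100 Pa).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import numpy as np

#: Boltzmann constant, J/K (CODATA exact value).
K_B = 1.380649e-23

#: mbar → Pa
MBAR_TO_PA = 100.0


class CapflexError(Exception):
    """Base class for toolkit errors."""


class FormatError(CapflexError):
    """A file does not follow the expected tabular dialect."""


class ValidationError(CapflexError):
    """An object violates a domain invariant."""


class CalibrationError(CapflexError):
    """Standard-curve calibration is impossible or unphysical."""


class FrontDetectionError(CapflexError):
    """The solution-front sigmoid could not be located."""


class InsufficientDataError(CapflexError):
    """Too few samples survive for the requested computation."""


class FitError(CapflexError):
    """A nonlinear fit failed to converge or is degenerate."""


class ConfigError(CapflexError):
    """An unknown mode or inconsistent configuration was requested."""


def _as_1d(x: Sequence[float] | np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class Trace:
    """One detector channel's time/fluorescence series.

    ``time`` must be strictly increasing (non-monotone inputs are rejected,
    never sorted) and of the same length as ``signal`` with at least two
    samples.  Sampling is expected to be approximately uniform; the
    ``is_uniform`` flag is checked by operations that require it
    (median filtering, ALS baselines).
    """

    time: np.ndarray
    signal: np.ndarray
    channel: str = "alexa488"
    pressure_mbar: float = 50.0
    sample_id: str = ""
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = _as_1d(self.time, "time")
        self.signal = _as_1d(self.signal, "signal")
        if self.time.size != self.signal.size:
            raise ValidationError(
                f"time ({self.time.size}) and signal ({self.signal.size}) lengths differ"
            )
        if self.time.size < 2:
            raise ValidationError("a trace needs at least 2 samples")
        if self.time[0] < 0:
            raise ValidationError("time must be non-negative")
        dt = np.diff(self.time)
        bad = np.nonzero(dt <= 0)[0]
        if bad.size:
            raise ValidationError(
                f"time must be strictly increasing; first violation at index {int(bad[0]) + 1}"
            )

    def __len__(self) -> int:
        return int(self.time.size)

    @property
    def dt(self) -> float:
        """Median sampling interval, s."""
        return float(np.median(np.diff(self.time)))

    @property
    def is_uniform(self) -> bool:
        """True when max/min sampling interval ratio < 1.5."""
        dt = np.diff(self.time)
        return bool(dt.max() / dt.min() < 1.5)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def window(self, t_start: float, t_end: float) -> "Trace":
        """Sub-trace with t_start <= time <= t_end."""
        m = (self.time >= t_start) & (self.time <= t_end)
        if m.sum() < 2:
            raise ValidationError(f"window [{t_start}, {t_end}] holds fewer than 2 samples")
        return Trace(
            self.time[m], self.signal[m], channel=self.channel,
            pressure_mbar=self.pressure_mbar, sample_id=self.sample_id,
            metadata=dict(self.metadata),
        )


@dataclass
class CapillarySystem:
    """Capillary geometry and fluid parameters (SI units).

    Defaults describe the instrument used throughout: a 75 µm inner-diameter,
    1 m fused-silica capillary coiled at ~5 mm turn radius, water-like fluid.
    """

    length_l: float = 1.0                 # m
    inner_diameter: float = 75e-6         # m
    turn_radius: float = 0.5e-2           # m
    pressure_pa: float = 5000.0           # Pa (50 mbar measurement pressure)
    viscosity: float = 1.0e-3             # Pa·s (water, 20 °C)
    density: float = 1.0e3                # kg/m³
    detection_window: float = 50e-6       # m

    def __post_init__(self) -> None:
        for name in ("length_l", "inner_diameter", "turn_radius", "pressure_pa",
                     "viscosity", "density", "detection_window"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if self.inner_diameter >= self.length_l / 100.0:
            raise ValidationError("inner_diameter must be much smaller than length_l")

    @property
    def radius(self) -> float:
        """Capillary inner radius, m."""
        return self.inner_diameter / 2.0

    @classmethod
    def at_pressure_mbar(cls, pressure_mbar: float, **kw: Any) -> "CapillarySystem":
        return cls(pressure_pa=pressure_mbar * MBAR_TO_PA, **kw)


@dataclass
class CalibrationCurve:
    """Linear map between labeled-species concentration (µM) and baseline FU."""

    concentrations: np.ndarray
    baselines: np.ndarray
    slope: float          # FU/µM
    intercept: float      # FU
    r_squared: float

    def __post_init__(self) -> None:
        self.concentrations = _as_1d(self.concentrations, "concentrations")
        self.baselines = _as_1d(self.baselines, "baselines")
        if self.slope <= 0:
            raise CalibrationError(
                f"calibration slope must be positive, got {self.slope!r} "
                "(phase-separated standards or mislabeled data?)"
            )
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValidationError(f"r_squared must lie in [0, 1], got {self.r_squared}")

    def predict(self, conc_um: float | np.ndarray) -> float | np.ndarray:
        """Baseline FU expected for a given concentration."""
        return self.slope * np.asarray(conc_um, dtype=float) + self.intercept

    def inverse(self, baseline_fu: float | np.ndarray) -> float | np.ndarray:
        """Concentration (µM) implied by a baseline fluorescence."""
        return (np.asarray(baseline_fu, dtype=float) - self.intercept) / self.slope


@dataclass
class PeakTable:
    """Detected droplet spikes: times, heights above baseline, integrals, flags."""

    peak_times: np.ndarray          # s
    heights: np.ndarray             # FU above baseline
    integrals: np.ndarray           # FU·s above baseline
    saturated: np.ndarray           # bool, raw max reached the detector ceiling
    threshold_used: float           # FU offset or relative fraction, per detector

    def __post_init__(self) -> None:
        self.peak_times = _as_1d(self.peak_times, "peak_times")
        self.heights = _as_1d(self.heights, "heights")
        self.integrals = _as_1d(self.integrals, "integrals")
        self.saturated = np.asarray(self.saturated, dtype=bool).reshape(-1)
        n = self.peak_times.size
        if not (self.heights.size == self.integrals.size == self.saturated.size == n):
            raise ValidationError("peak table columns must have equal length")
        if n and (self.heights <= 0).any():
            raise ValidationError("peak heights must be positive")

    def __len__(self) -> int:
        return int(self.peak_times.size)

    @property
    def n(self) -> int:
        return len(self)


@dataclass
class BaselineResult:
    """Dilute-phase baseline extracted from a trace.

    ``front_time`` is the sigmoid midpoint (50% rise); the baseline region
    starts where the fitted sigmoid first exceeds 99% of its upper asymptote.
    """

    baseline_fu: float
    baseline_region: tuple[float, float]      # (t_start, t_end), s
    front_time: float                         # s, sigmoid midpoint
    sigmoid_params: dict[str, float]          # lower, upper, midpoint, rate
    dilute_phase_conc: Optional[float] = None  # µM, if a calibration was supplied

    def __post_init__(self) -> None:
        if self.front_time > self.baseline_region[0] + 1e-12:
            raise ValidationError("front_time must not exceed baseline-region start")
        lo = self.sigmoid_params.get("lower", -np.inf)
        hi = self.sigmoid_params.get("upper", np.inf)
        if not (min(lo, hi) - 1e-9 <= self.baseline_fu <= max(lo, hi) + 1e-9):
            raise ValidationError("baseline_fu must lie between the sigmoid asymptotes")


@dataclass
class BindingModel:
    """Cooperative 1:n binding model parameters for the size isotherm.

    ``r_h_bound`` may be smaller than ``r_h_unbound``: a bound complex can be
    more compact than the free indicator (ssDNA collapsing on a cationic
    peptide is the canonical example).
    """

    stoichiometry_n: int
    k_d: float            # µM
    r_h_unbound: float    # nm
    r_h_bound: float      # nm

    def __post_init__(self) -> None:
        if self.stoichiometry_n not in (1, 2, 3):
            raise ValidationError("stoichiometry_n must be 1, 2 or 3")
        if self.k_d <= 0:
            raise ValidationError("K_d must be positive")
        if self.r_h_unbound <= 0 or self.r_h_bound <= 0:
            raise ValidationError("hydrodynamic radii must be positive")


@dataclass
class SyntheticGroundTruth:
    """Known truth attached to a simulated trace (simulator bookkeeping)."""

    total_conc: float                  # µM
    dilute_conc: float                 # µM
    droplet_count: int
    label_fraction: float = 1.0
    volume_distribution: str = "lognormal"
    volume_mu: float = 0.0             # lognormal log-scale location
    volume_sigma: float = 0.5          # lognormal log-scale spread
    enrichment_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.dilute_conc <= self.total_conc):
            raise ValidationError("need 0 < dilute_conc <= total_conc")
        if not (0.0 < self.label_fraction <= 1.0):
            raise ValidationError("label_fraction must lie in (0, 1]")
        if self.droplet_count < 0:
            raise ValidationError("droplet_count must be non-negative")
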