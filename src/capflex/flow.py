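"""Closed-form capillary flow physics.

Two modes are offered throughout.  ``"physical"`` evaluates the standard
laminar-pipe-flow results: Hagen–Poiseuille centerline velocity
U_max = ΔP·D²/(16 μ L), mean velocity U_max/2, dead time L/U_max (arrival of
the fastest, centerline streamline at the detector), fill time L/U_mean.
``"paper_order_of_magnitude"`` reproduces the published back-of-envelope
substitution chain for the same quantities, which uses ΔP·D²/(8 μ L) and
rounds to the nearest power of ten.  The physical mode is the default
because it reproduces the instrument's measured ~8 s dead time at 3500 mbar
through a 75 µm × 1 m water-filled capillary.

The wall-shear estimate published for this instrument (2 Pa) is not
derivable from its own velocity scale; :func:`wall_shear_stress` returns the
physical value and :data:`PAPER_PRINTED_WALL_SHEAR_PA` carries the published
number as a documented discrepancy — it is never silently matched.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .types import CapillarySystem, ConfigError

PHYSICAL = "physical"
PAPER = "paper_order_of_magnitude"
_MODES = (PHYSICAL, PAPER)

#: Published order-of-magnitude wall shear for this instrument, Pa.  Not
#: reproducible from the published velocity scale (8·U_m/D·μ with
#: U_m ≈ 10⁻¹ m/s, D = 10⁻⁴ m gives 8 Pa); kept for reference only.
PAPER_PRINTED_WALL_SHEAR_PA = 2.0


def _check_mode(mode: str) -> None:
    if mode not in _MODES:
        raise ConfigError(f"unknown mode {mode!r}; expected one of {_MODES}")


def _round_power_of_ten(x: float) -> float:
    return 10.0 ** round(math.log10(x)) if x > 0 else 0.0


def max_velocity(system: CapillarySystem, mode: str = PHYSICAL) -> float:
    """Centerline (maximum) velocity, m/s.

    Physical mode: U_max = ΔP·D²/(16 μ L).  Paper mode evaluates the
    published substitution ΔP·D²/(8 μ L) and rounds to the nearest power of
    ten, reproducing the printed ≈10⁻¹ m/s chain.
    """
    _check_mode(mode)
    dp, d = system.pressure_pa, system.inner_diameter
    if mode == PHYSICAL:
        return dp * d ** 2 / (16.0 * system.viscosity * system.length_l)
    return _round_power_of_ten(dp * d ** 2 / (8.0 * system.viscosity * system.length_l))


def mean_velocity(system: CapillarySystem, mode: str = PHYSICAL) -> float:
    """Cross-section average velocity: U_max/2 for a parabolic profile."""
    return max_velocity(system, mode) / 2.0


def dead_time(system: CapillarySystem) -> float:
    """Time for the centerline streamline to reach the detector, s: L/U_max."""
    return system.length_l / max_velocity(system, PHYSICAL)


def fill_time(system: CapillarySystem) -> float:
    """Time to push one capillary volume past the detector, s: L/U_mean = 2·dead_time."""
    return 2.0 * dead_time(system)


def reynolds(system: CapillarySystem, velocity: float) -> float:
    """Re = ρ·v·D/μ."""
    return system.density * velocity * system.inner_diameter / system.viscosity


def dean_number(system: CapillarySystem, reynolds_number: float) -> float:
    """Dean number k = sqrt(H/(2R))·Re for a capillary coiled at turn radius R."""
    return math.sqrt(system.inner_diameter / (2.0 * system.turn_radius)) * reynolds_number


def focusing_length(
    system: CapillarySystem,
    particle_radius_a: float,
    lift_factor_fe: float = 0.05,
    u_m: Optional[float] = None,
) -> float:
    """Inertial-focusing length L_f = π·μ·H²/(ρ·U_m·a²·f_e), m.

    ``u_m`` defaults to the physical maximum velocity; pass it explicitly to
    reproduce a published substitution.  ``lift_factor_fe`` is the lift-force
    coefficient, usually 0.02–0.05.
    """
    if particle_radius_a <= 0:
        raise ConfigError("particle radius must be positive")
    if not (0.0 < lift_factor_fe <= 0.1):
        raise ConfigError("lift factor f_e must lie in (0, 0.1]")
    if u_m is None:
        u_m = max_velocity(system, PHYSICAL)
    h = system.inner_diameter
    return (math.pi * system.viscosity * h ** 2
            / (system.density * u_m * particle_radius_a ** 2 * lift_factor_fe))


def wall_shear_stress(system: CapillarySystem, u_mean: Optional[float] = None) -> float:
    """Wall shear stress τ_w = γ_w·μ = (8·U_mean/D)·μ, Pa.

    Standard fully-developed pipe result with the mean velocity; ``u_mean``
    defaults to the physical mean velocity of the system.
    """
    if u_mean is None:
        u_mean = mean_velocity(system, PHYSICAL)
    return 8.0 * u_mean * system.viscosity / system.inner_diameter


@dataclass
class FlowDerived:
    """All closed-form flow quantities for one capillary system."""

    u_max: float               # m/s
    u_mean: float              # m/s
    dead_time: float           # s
    fill_time: float           # s
    reynolds: float
    dean_k: float
    focusing_length_lf: Optional[float]   # m, None when no particle radius given
    wall_shear_tau: float      # Pa (physical)
    wall_shear_printed: float  # Pa, published order-of-magnitude value (flagged discrepancy)
    mode: str

    @property
    def wall_shear_discrepancy(self) -> bool:
        """True when the physical wall shear disagrees with the published value."""
        return abs(self.wall_shear_tau - self.wall_shear_printed) > 0.01 * self.wall_shear_printed


def derive(
    system: CapillarySystem,
    particle_radius_a: Optional[float] = None,
    lift_factor_fe: float = 0.05,
    mode: str = PHYSICAL,
) -> FlowDerived:
    """Compute every flow quantity for one system in one call."""
    _check_mode(mode)
    u_max = max_velocity(system, mode)
    u_mean = u_max / 2.0
    re = reynolds(system, u_max)
    lf = None
    if particle_radius_a is not None:
        lf = focusing_length(system, particle_radius_a, lift_factor_fe, u_m=u_max)
    return FlowDerived(
        u_max=u_max,
        u_mean=u_mean,
        dead_time=system.length_l / u_max,
        fill_time=2.0 * system.length_l / u_max,
        reynolds=re,
        dean_k=dean_number(system, re),
        focusing_length_lf=lf,
        wall_shear_tau=wall_shear_stress(system, u_mean),
        wall_shear_printed=PAPER_PRINTED_WALL_SHEAR_PA,
        mode=mode,
    )
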