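"""Sphere-on-surface (Hertz) contact mechanics and device calibration.

Models the contact between a rigid spherical glass probe and the elastic
fillet/PDMS composite in the small-indentation regime d < r.  For a rigid
sphere of radius ``r`` pressed a depth ``d`` into an elastic half-space of
effective modulus ``E* = E/(1-ν²)`` the classical solution gives

    f   = (4/3) E* r^(1/2) d^(3/2)        total force
    a   = sqrt(r d)                       contact radius
    P0  = 3 f / (2 π a²)                  central pressure
    P(x)= P0 sqrt(1 - x²/a²)              pressure profile, x ≤ a

and the (spherical-cap) contact area A_c = 2πr (r - sqrt(r² - r d)).

Also implements the mechanical-device conversions: indentation depth from
piezo step minus beam deflection (d = D - B), the gravimetric water-step
force used to calibrate the strain gauge, and an ordinary least-squares
voltage-to-force calibration line.

Units: μm, mN, MPa throughout (see :mod:`nocimech.units`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .units import STANDARD_GRAVITY, WATER_DENSITY, un_to_mn

__all__ = [
    "ProbeSpec",
    "ElasticMedium",
    "IndentationState",
    "ContactState",
    "GaugeCalibration",
    "InvalidMediumError",
    "ModelValidityError",
    "effective_modulus",
    "indentation_depth",
    "contact_force",
    "contact_radius",
    "contact_area",
    "central_pressure",
    "pressure_profile",
    "water_step_force",
    "fit_gauge_calibration",
    "model_force_bounds",
]


class InvalidMediumError(ValueError):
    """Raised for non-physical elastic constants (E ≤ 0 or ν outside [0, 0.5))."""


class ModelValidityError(ValueError):
    """Raised when inputs leave the validity domain of the contact model."""


@dataclass(frozen=True)
class ProbeSpec:
    """Spherical probe geometry.

    Probe "sizes" are quoted as tip *diameters* (30, 60, 100, 200 μm);
    all contact formulas use the radius ``r = diameter / 2``.
    """

    diameter: float  # μm

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ValueError(f"probe diameter must be positive, got {self.diameter}")

    @property
    def radius(self) -> float:
        """Tip radius r in μm."""
        return self.diameter / 2.0


@dataclass(frozen=True)
class ElasticMedium:
    """Isotropic linear-elastic material: modulus E (MPa), Poisson ratio ν."""

    modulus: float  # MPa
    poisson: float = 0.45

    def __post_init__(self) -> None:
        if not self.modulus > 0 or not (0.0 <= self.poisson < 0.5):
            raise InvalidMediumError(
                f"need E > 0 and 0 <= nu < 0.5, got E={self.modulus}, nu={self.poisson}"
            )


@dataclass(frozen=True)
class IndentationState:
    """Kinematics of one poke: piezo step D, beam deflection B, depth d = D - B (μm)."""

    piezo_step: float
    beam_deflection: float
    depth: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "depth", indentation_depth(self.piezo_step, self.beam_deflection)
        )


@dataclass(frozen=True)
class ContactState:
    """Derived contact quantities for one (probe, medium, depth) combination."""

    force: float  # mN
    contact_radius: float  # μm
    contact_area: float  # μm²
    central_pressure: float  # MPa

    @classmethod
    def evaluate(
        cls, medium: ElasticMedium, probe: ProbeSpec, d: float
    ) -> "ContactState":
        estar = effective_modulus(medium)
        f = contact_force(estar, probe, d)
        a = contact_radius(probe, d)
        ac = contact_area(probe, d)
        p0 = central_pressure(f, a) if a > 0 else 0.0
        return cls(force=f, contact_radius=a, contact_area=ac, central_pressure=p0)


@dataclass(frozen=True)
class GaugeCalibration:
    """Strain-gauge voltage → force map: force = slope·voltage + intercept."""

    slope: float  # mN / V
    intercept: float  # mN
    residual: float  # rms residual, mN

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"calibration slope must be positive, got {self.slope}")

    def force(self, voltage: float | np.ndarray) -> float | np.ndarray:
        """Convert a raw gauge readout (V) to force (mN)."""
        return self.slope * np.asarray(voltage, dtype=float) + self.intercept


def effective_modulus(medium: ElasticMedium) -> float:
    """Effective contact modulus E* = E / (1 - ν²) in MPa (rigid indenter)."""
    return medium.modulus / (1.0 - medium.poisson**2)


def indentation_depth(piezo_step: float, beam_deflection: float) -> float:
    """Indentation depth d = D - B (μm); errors if B > D or either is negative."""
    if beam_deflection < 0 or piezo_step < 0:
        raise ValueError("piezo step and beam deflection must be nonnegative")
    if beam_deflection > piezo_step:
        raise ValueError(
            f"beam deflection B={beam_deflection} exceeds piezo step D={piezo_step}: "
            "negative indentation depth"
        )
    return piezo_step - beam_deflection


def _check_depth(probe: ProbeSpec, d: float) -> None:
    if d < 0:
        raise ModelValidityError(f"indentation depth must be nonnegative, got {d}")
    if d >= probe.radius:
        raise ModelValidityError(
            f"contact model requires d < r; got d={d} μm, r={probe.radius} μm"
        )


def contact_force(estar: float, probe: ProbeSpec, d: float) -> float:
    """Hertz force f = (4/3) E* r^(1/2) d^(3/2), returned in mN.

    ``estar`` in MPa, lengths in μm.  Valid for 0 ≤ d < r.
    """
    _check_depth(probe, d)
    if estar <= 0:
        raise InvalidMediumError(f"effective modulus must be positive, got {estar}")
    f_un = (4.0 / 3.0) * estar * np.sqrt(probe.radius) * d**1.5
    return un_to_mn(f_un)


def contact_radius(probe: ProbeSpec, d: float) -> float:
    """Contact-patch radius a = sqrt(r d) in μm, for 0 ≤ d < r."""
    _check_depth(probe, d)
    return float(np.sqrt(probe.radius * d))


def contact_area(probe: ProbeSpec, d: float) -> float:
    """Spherical-cap contact area A_c = 2πr (r - sqrt(r² - r d)) in μm².

    Exceeds the projected disc area π a² because the interface is a
    spherical crown, not a flat disc; A_c → π r d as d/r → 0.
    """
    _check_depth(probe, d)
    r = probe.radius
    return float(2.0 * np.pi * r * (r - np.sqrt(r * r - r * d)))


def central_pressure(f: float, a: float) -> float:
    """Peak (central) Hertz pressure P0 = 3 f / (2 π a²) in MPa; f in mN, a in μm."""
    if a <= 0:
        raise ModelValidityError("central pressure undefined for zero contact radius")
    if f < 0:
        raise ValueError("force must be nonnegative")
    f_un = f * 1000.0
    return float(3.0 * f_un / (2.0 * np.pi * a * a))


def pressure_profile(
    p0: float, a: float, x: float | np.ndarray
) -> float | np.ndarray:
    """Hertz pressure P(x) = P0 sqrt(1 - x²/a²) inside the patch, 0 outside.

    Total on x ≥ 0; the profile vanishes identically for x > a since no
    contact pressure is transmitted outside the patch.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise ValueError("distance from contact center must be nonnegative")
    inside = x_arr <= a
    out = np.zeros_like(x_arr)
    out[inside] = p0 * np.sqrt(np.clip(1.0 - (x_arr[inside] / a) ** 2, 0.0, None))
    if np.isscalar(x) or x_arr.ndim == 0:
        return float(out)
    return out


def water_step_force(volume_ul: float) -> float:
    """Weight of a water aliquot in mN: volume (μL) × 1 g/mL × 9.8 m/s².

    100 μL of water weighs exactly 0.98 mN, the minimal calibration step of
    the gravimetric gauge calibration.
    """
    if volume_ul < 0:
        raise ValueError(f"water volume must be nonnegative, got {volume_ul}")
    # μL × g/mL = mg; mg × (m/s²) = μN; /1000 → mN
    return volume_ul * WATER_DENSITY * STANDARD_GRAVITY / 1000.0


def fit_gauge_calibration(
    points: Sequence[tuple[float, float]] | np.ndarray,
) -> GaugeCalibration:
    """Ordinary least-squares line through (force mN, voltage V) calibration points.

    Fits force = slope·voltage + intercept with a free intercept and returns
    the rms residual in mN.  Requires at least two points with distinct
    voltages.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two (force, voltage) calibration points")
    force, voltage = pts[:, 0], pts[:, 1]
    if np.ptp(voltage) == 0:
        raise ValueError("degenerate calibration: all voltages identical")
    design = np.column_stack([voltage, np.ones_like(voltage)])
    (slope, intercept), *_ = np.linalg.lstsq(design, force, rcond=None)
    resid = float(np.sqrt(np.mean((design @ [slope, intercept] - force) ** 2)))
    return GaugeCalibration(slope=float(slope), intercept=float(intercept), residual=resid)


def model_force_bounds(
    probe: ProbeSpec,
    d_grid: Sequence[float] | np.ndarray,
    e_low: float,
    e_high: float,
    poisson: float = 0.45,
) -> tuple[np.ndarray, np.ndarray]:
    """Lower/upper Hertz force-depth curves (mN) bracketing the substrate modulus.

    The bracketing moduli are the literature extremes for PDMS (1.6 and
    4 MPa); since f is linear in E*, the two curves differ by the constant
    factor e_high / e_low.
    """
    if not e_low < e_high:
        raise ValueError(f"need E_low < E_high, got {e_low} >= {e_high}")
    lo = effective_modulus(ElasticMedium(e_low, poisson))
    hi = effective_modulus(ElasticMedium(e_high, poisson))
    d_arr = np.asarray(d_grid, dtype=float)
    f_lo = np.array([contact_force(lo, probe, d) for d in d_arr])
    f_hi = np.array([contact_force(hi, probe, d) for d in d_arr])
    return f_lo, f_hi
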