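"""Synthetic inputs: dendritic arbors, force-response curves, toy fields.

The arbor generator emulates the statistics of imaged class-IV (c4da)
dendritic-arborization neurons rather than their developmental mechanism:
a space-filling branching growth process expands radially from the soma in
thin shells, splitting the widest angular gaps so that the number of
branches crossing radius ρ tracks a target modified-Sholl density D(ρ).

Calibration targets (wild-type c4da): total dendritic length
19,560 ± 1,667 μm over a ~220 μm territory; near-uniform Sholl density
between 20 and 180 μm; ≥95% of the territory within 20 μm of a dendrite.
The cut-knockdown variant (``c4da_cti``) matches the wild type proximally
(ρ < 100 μm) and decays distally; ``c3da`` is sparse throughout.

Force-response presets carry the measured half/full-activation forces:
f50 ≈ 3 mN and f90 ≈ 4 mN for the 60 μm probe, f50 ≈ 0.7 mN and
f90 ≈ 1.5 mN for the 30 μm probe.  Mutant-like presets are qualitative
fixtures only.  All generators are pure functions of (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .fields import FieldMap
from .morphology import DEFAULT_TERRITORY_RADIUS, Arbor
from .response import ForceResponseCurve, boltzmann

__all__ = [
    "ArborGenParams",
    "ResponsePreset",
    "PRESETS",
    "generate_arbor",
    "generate_response_curves",
    "toy_field",
    "LN9",
]

LN9 = float(np.log(9.0))


@dataclass(frozen=True)
class ArborGenParams:
    """Parameters of the shell-growth arbor generator.

    ``target_total_length`` (μm) and ``territory_radius`` (μm) set the mean
    Sholl density D0 = L/(π R²) of the uniform (wild-type) profile; the
    density profile shape is selected by ``class_label``.  ``shell_step`` is
    the radial growth increment and ``angle_jitter`` the per-step lateral
    meander (arc-length std, μm).  ``self_avoidance`` blends each tip's
    heading toward the bisector of its angular gap, keeping neighbours
    apart.
    """

    class_label: str = "c4da_wt"
    target_total_length: float = 19560.0
    territory_radius: float = DEFAULT_TERRITORY_RADIUS
    shell_step: float = 2.0
    angle_jitter: float = 0.6  # μm of arc per shell step
    self_avoidance: float = 0.25  # 0..1 pull toward the local gap bisector
    start_radius: float = 5.0
    decay_start: float = 100.0  # c4da_cti: uniform out to here ...
    decay_scale: float = 35.0  # ... then exp decay with this scale (μm)

    def __post_init__(self) -> None:
        if self.target_total_length <= 0 or self.territory_radius <= 0:
            raise ValueError("target length and territory radius must be positive")

    def density_profile(self, scale: float = 1.0) -> Callable[[float], float]:
        """Target Sholl density D(ρ) (μm⁻¹).

        ``c4da_wt``/``custom`` are uniform and normalized so the radial
        integral of 2πρ·D equals the target length; ``c4da_cti`` keeps the
        *same proximal density* as a wild type of equal target (its total
        length is consequently lower — distal branches are lost, proximal
        ones unchanged); ``c3da`` is normalized to its own (small) target.
        ``scale`` is an overall calibration factor (see generate_arbor).
        """
        if self.class_label in ("c4da_wt", "custom", "c4da_cti"):
            shape = lambda rho: 1.0  # noqa: E731 — wt-matched proximal density
        elif self.class_label == "c3da":
            shape = lambda rho: float(np.exp(-rho / 80.0))  # noqa: E731
        else:
            raise ValueError(f"unknown arbor class {self.class_label!r}")
        rr = np.linspace(self.start_radius, self.territory_radius, 400)
        integral = np.trapezoid([2 * np.pi * r * shape(r) for r in rr], rr)
        d0 = scale * self.target_total_length / integral
        if self.class_label == "c4da_cti":
            return lambda rho: d0 * (
                1.0
                if rho <= self.decay_start
                else float(np.exp(-(rho - self.decay_start) / self.decay_scale))
            )
        return lambda rho: d0 * shape(rho)


def generate_arbor(params: ArborGenParams, seed: int | np.random.Generator = 0) -> Arbor:
    """Grow one synthetic planar arbor; identical output for identical seed.

    Tips advance outward in shells of ``shell_step`` μm.  After each shell
    the number of live tips is adjusted to the target crossing count
    N(ρ) = 2πρ·D(ρ): deficits are covered by bifurcating the tips with the
    widest angular gaps, surpluses by retiring the most crowded tips.  Tip
    headings meander with mean-reversion toward the local gap bisector
    (self-avoidance), so the arbor fills space without fasciculation.

    Growth adds a few percent of structural overhead (branch chords,
    meander) over the density-profile integral, so the density scale is
    auto-calibrated: grow, compare realized to intended length, rescale,
    regrow (≤ 4 rounds, same seed each round).
    """
    if isinstance(seed, np.random.Generator):
        seed = int(seed.integers(2**31))
    # intended length = radial integral of the (unscaled) density profile
    dens1 = params.density_profile(scale=1.0)
    rr = np.linspace(params.start_radius, params.territory_radius, 400)
    l_intended = float(np.trapezoid([2 * np.pi * r * dens1(r) for r in rr], rr))
    scale = 1.0
    from .morphology import total_length  # local import avoids cycle at import time

    for _ in range(4):
        arbor = _grow(params, params.density_profile(scale=scale), np.random.default_rng(seed))
        realized = total_length(arbor)
        if abs(realized - l_intended) <= 0.025 * l_intended:
            return arbor
        scale *= l_intended / realized
    raise RuntimeError(
        f"arbor calibration did not converge: realized length {realized:.0f} μm "
        f"vs intended {l_intended:.0f} μm"
    )


def _grow(
    params: ArborGenParams, dens: Callable[[float], float], rng: np.random.Generator
) -> Arbor:
    R = params.territory_radius
    step = params.shell_step

    nodes: list[np.ndarray] = [np.zeros(2)]
    parents: list[int] = [-1]

    rho0 = params.start_radius
    n0 = max(3, int(round(2 * np.pi * rho0 * dens(rho0))))
    base = rng.uniform(0, 2 * np.pi)
    angles = np.sort((base + np.arange(n0) * 2 * np.pi / n0
                      + rng.normal(0, 0.1, n0)) % (2 * np.pi))
    tip_nodes: list[int] = []
    tip_angles: list[float] = []
    for th in angles:
        nodes.append(rho0 * np.array([np.cos(th), np.sin(th)]))
        parents.append(0)
        tip_nodes.append(len(nodes) - 1)
        tip_angles.append(float(th))

    rho = rho0
    while rho + step <= R + 1e-9:
        rho_new = rho + step
        target = int(round(2 * np.pi * rho_new * dens(rho_new)))
        order = np.argsort(tip_angles)
        tip_nodes = [tip_nodes[i] for i in order]
        tip_angles = [tip_angles[i] for i in order]
        n = len(tip_nodes)

        if target > n:
            gaps = _angular_gaps(tip_angles)
            for _ in range(target - n):
                j = int(np.argmax(gaps))
                # spawn a sibling inside the widest gap
                new_angle = (tip_angles[j] + 0.5 * gaps[j]) % (2 * np.pi)
                tip_nodes.append(tip_nodes[j])  # same parent node: bifurcation
                tip_angles.append(float(new_angle))
                gaps[j] *= 0.5
                gaps = np.append(gaps, gaps[j])
            order = np.argsort(tip_angles)
            tip_nodes = [tip_nodes[i] for i in order]
            tip_angles = [tip_angles[i] for i in order]
        elif target < n and target >= 1:
            gaps = _angular_gaps(tip_angles)
            room = gaps + np.roll(gaps, 1)  # space around each tip
            drop = np.argsort(room)[: n - target]
            keep = np.setdiff1d(np.arange(n), drop)
            tip_nodes = [tip_nodes[i] for i in keep]
            tip_angles = [tip_angles[i] for i in keep]

        n = len(tip_nodes)
        gaps = _angular_gaps(tip_angles)
        jitter = rng.normal(0.0, params.angle_jitter / max(rho_new, 1.0), n)
        new_angles: list[float] = []
        new_nodes: list[int] = []
        for i in range(n):
            gap_next = gaps[i]
            gap_prev = gaps[i - 1]
            # drift toward the bisector of the local free space
            drift = params.self_avoidance * 0.5 * (gap_next - gap_prev)
            th = (tip_angles[i] + drift + jitter[i]) % (2 * np.pi)
            pos = rho_new * np.array([np.cos(th), np.sin(th)])
            nodes.append(pos)
            parents.append(tip_nodes[i])
            new_nodes.append(len(nodes) - 1)
            new_angles.append(float(th))
        tip_nodes, tip_angles = new_nodes, new_angles
        rho = rho_new

    return Arbor(
        nodes=np.asarray(nodes),
        parents=np.asarray(parents),
        class_label=params.class_label if params.class_label != "custom" else "custom",
    )


def _angular_gaps(sorted_angles: list[float]) -> np.ndarray:
    """Gap from each angle to its successor (wrapping), for sorted input."""
    th = np.asarray(sorted_angles)
    return np.diff(np.append(th, th[0] + 2 * np.pi))


# ---------------------------------------------------------------------------
# force-response presets


@dataclass(frozen=True)
class ResponsePreset:
    """Boltzmann ground truth for one probe/genotype condition."""

    label: str
    plateau: float
    f50: float  # mN
    f90: float  # mN
    noise_sd: float = 0.1  # fraction of plateau
    n_cells: int = 12
    force_grid: tuple[float, ...] = tuple(np.arange(0.0, 5.01, 0.5))

    def __post_init__(self) -> None:
        if not 0 < self.f50 < self.f90:
            raise ValueError("need 0 < f50 < f90")
        if len(self.force_grid) == 0:
            raise ValueError("force grid must be nonempty")

    @property
    def width(self) -> float:
        """Boltzmann width w = (f90 - f50)/ln 9 (mN)."""
        return (self.f90 - self.f50) / LN9


#: packaged presets; wild-type amplitudes/forces reflect the measured
#: f50/f90, mutant-like entries are qualitative fixtures.
PRESETS: dict[str, ResponsePreset] = {
    "wt_60um": ResponsePreset("wt_60um", plateau=1.0, f50=3.0, f90=4.0),
    "wt_30um": ResponsePreset(
        "wt_30um", plateau=1.5, f50=0.7, f90=1.5,
        force_grid=tuple(np.arange(0.0, 2.01, 0.2)),
    ),
    # qualitative mutants: piezo-like loses small-probe sensitivity,
    # ppk26-like attenuates globally, the double mutant is near-silent
    "piezo_like_30um": ResponsePreset(
        "piezo_like_30um", plateau=0.5, f50=1.2, f90=1.9,
        force_grid=tuple(np.arange(0.0, 2.01, 0.2)),
    ),
    "ppk26_like_60um": ResponsePreset("ppk26_like_60um", plateau=0.35, f50=3.2, f90=4.4),
    "double_mutant_60um": ResponsePreset("double_mutant_60um", plateau=0.05, f50=3.0, f90=4.0),
}


def generate_response_curves(
    preset: ResponsePreset, seed: int | np.random.Generator = 0
) -> ForceResponseCurve:
    """Simulate per-cell force-response measurements from a preset.

    Each cell's response at each grid force is the Boltzmann value plus
    additive Gaussian noise (sd = noise_sd × plateau), truncated at 0.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    forces = np.asarray(preset.force_grid, dtype=float)
    w = preset.width
    rows = []
    for cell in range(preset.n_cells):
        clean = boltzmann(forces, preset.plateau, preset.f50, w)
        noisy = np.clip(
            clean + rng.normal(0.0, preset.noise_sd * preset.plateau, len(forces)),
            0.0,
            None,
        )
        rows.append(
            pd.DataFrame(
                {"cell_id": f"cell{cell:02d}", "force_mN": forces, "dff": noisy}
            )
        )
    return ForceResponseCurve(pd.concat(rows, ignore_index=True))


# ---------------------------------------------------------------------------
# toy fields


def toy_field(
    kind: str,
    peak: float = 1.0,
    radius: float = 50.0,
    sigma: float = 25.0,
    pixel_size: float = 1.0,
    extent: float = 150.0,
    channels: tuple[str, ...] = ("P_P", "T_L"),
) -> FieldMap:
    """Analytic field fixtures for activation-model oracles.

    ``tophat``: value = peak for pixel distance ≤ radius, else 0.
    ``gaussian``: peak·exp(-ρ²/(2σ²)).  ``zero``: all zeros.  The pattern is
    written into the requested ``channels``; the other channel is zero.
    """
    n = 2 * int(round(extent / pixel_size)) + 1
    ax = (np.arange(n) - (n - 1) / 2.0) * pixel_size
    gx, gy = np.meshgrid(ax, ax)
    rho = np.hypot(gx, gy)
    if kind == "tophat":
        vals = np.where(rho <= radius, peak, 0.0)
    elif kind == "gaussian":
        vals = peak * np.exp(-(rho**2) / (2.0 * sigma**2))
    elif kind == "zero":
        vals = np.zeros_like(rho)
    else:
        raise ValueError(f"unknown toy field kind {kind!r}")
    zero = np.zeros_like(vals)
    return FieldMap(
        p_perp=vals if "P_P" in channels else zero.copy(),
        t_lat=vals if "T_L" in channels else zero.copy(),
        pixel_size=pixel_size,
    )
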