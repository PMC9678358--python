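"""Calcium-response quantification and Boltzmann force-response fitting.

ΔF/F0 is the fractional change of the somatic GCaMP fluorescence relative
to its pre-stimulus baseline.  Force-response relations are summarized by a
Boltzmann sigmoid with zero lower asymptote,

    R(f) = A / (1 + exp((f0 - f) / w)),

where A is the response plateau, f0 the half-activation force and w the
transition width.  The half- and full-activation forces follow in closed
form: f50 = f0 and f90 = f0 + w·ln 9, and more generally the force at a
fraction q of the plateau is f0 + w·ln(q/(1-q)).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "FluorescenceTrace",
    "ForceResponseCurve",
    "BoltzmannFit",
    "FitError",
    "dff",
    "boltzmann",
    "fit_boltzmann",
    "f_at_fraction",
]


class FitError(RuntimeError):
    """Raised when the Boltzmann fit cannot be performed or does not converge."""


@dataclass
class FluorescenceTrace:
    """Fluorescence time series with a pre-stimulus baseline window.

    ``time`` in s, ``F`` in arbitrary units; ``baseline`` is the (t0, t1)
    interval whose mean defines F0.
    """

    time: np.ndarray
    F: np.ndarray
    baseline: tuple[float, float]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.time.shape != self.F.shape:
            raise ValueError("time and F must have the same shape")


@dataclass
class ForceResponseCurve:
    """Per-cell (force mN, ΔF/F0) measurements in tidy form.

    ``data`` has columns cell_id, force_mN, dff.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"cell_id", "force_mN", "dff"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"force-response table needs columns {sorted(required)}")
        if (self.data["force_mN"] < 0).any():
            raise ValueError("forces must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.data["cell_id"].nunique()

    def force_levels(self) -> np.ndarray:
        return np.sort(self.data["force_mN"].unique())

    def per_force_mean(self) -> pd.DataFrame:
        """Mean ± sem of ΔF/F0 per force level across cells."""
        g = self.data.groupby("force_mN")["dff"]
        return pd.DataFrame(
            {"mean": g.mean(), "sem": g.sem(ddof=1).fillna(0.0), "n": g.size()}
        ).reset_index()

    @classmethod
    def from_csv(cls, path: str | Path | io.TextIOBase, sep: str = ",") -> "ForceResponseCurve":
        return cls(pd.read_csv(path, sep=sep))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class BoltzmannFit:
    """Fitted Boltzmann parameters with derived half/full-activation forces."""

    plateau: float  # A
    half_force: float  # f0, mN
    width: float  # w, mN
    residual: float  # rms residual of the fit
    f50: float = field(init=False)
    f90: float = field(init=False)

    def __post_init__(self) -> None:
        if self.plateau <= 0 or self.width <= 0:
            raise FitError(
                f"non-physical Boltzmann fit: A={self.plateau}, w={self.width}"
            )
        self.f50 = self.half_force
        self.f90 = f_at_fraction(self, 0.9)

    def __call__(self, f: float | np.ndarray) -> float | np.ndarray:
        return boltzmann(f, self.plateau, self.half_force, self.width)

    @property
    def slope_at_half(self) -> float:
        """Slope of the fitted sigmoid at f0, equal to A/(4w)."""
        return self.plateau / (4.0 * self.width)


def dff(trace: FluorescenceTrace) -> np.ndarray:
    """ΔF/F0 time series: (F - F0)/F0 with F0 the mean over the baseline window."""
    t0, t1 = trace.baseline
    mask = (trace.time >= t0) & (trace.time <= t1)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    f0 = float(trace.F[mask].mean())
    if f0 <= 0:
        raise ValueError(f"baseline fluorescence must be positive, got F0={f0}")
    return (trace.F - f0) / f0


def boltzmann(f, plateau, half_force, width):
    """Boltzmann sigmoid R(f) = A / (1 + exp((f0 - f)/w))."""
    z = np.clip((half_force - np.asarray(f, dtype=float)) / width, -500, 500)
    return plateau / (1.0 + np.exp(z))


def fit_boltzmann(curve: ForceResponseCurve, per_cell: bool = False):
    """Least-squares Boltzmann fit of a force-response curve.

    By default fits the per-force mean ΔF/F0 across cells (the curves are
    plotted as mean ± sem).  With ``per_cell=True`` returns a dict mapping
    cell_id to its individual fit.

    Initialization: A = max response; f0 = force at half-max by linear
    interpolation; w = force span / 4.
    """
    if per_cell:
        return {
            cid: _fit_single(sub["force_mN"].to_numpy(), sub["dff"].to_numpy())
            for cid, sub in curve.data.groupby("cell_id")
        }
    means = curve.per_force_mean()
    return _fit_single(means["force_mN"].to_numpy(), means["mean"].to_numpy())


def _fit_single(force: np.ndarray, resp: np.ndarray) -> BoltzmannFit:
    order = np.argsort(force)
    force, resp = force[order], resp[order]
    if len(np.unique(force)) < 4:
        raise FitError("need at least 4 distinct force levels for a Boltzmann fit")
    rmax = float(resp.max())
    if rmax <= 0 or np.ptp(resp) < 1e-12 or np.ptp(resp) < 0.05 * abs(rmax):
        raise FitError("degenerate (flat or non-positive) force-response data")
    a0 = rmax
    half = 0.5 * a0
    above = np.flatnonzero(resp >= half)
    if len(above) == 0 or above[0] == 0:
        f0_0 = force[0]
    else:
        i = above[0]
        frac = (half - resp[i - 1]) / (resp[i] - resp[i - 1])
        f0_0 = force[i - 1] + frac * (force[i] - force[i - 1])
    w0 = max(np.ptp(force) / 4.0, 1e-6)
    p0 = (a0, f0_0, w0)
    try:
        popt, _ = curve_fit(
            boltzmann,
            force,
            resp,
            p0=p0,
            bounds=([1e-9, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy convergence failure
        raise FitError(f"Boltzmann fit did not converge (initial guess {p0}): {exc}") from exc
    resid = float(np.sqrt(np.mean((boltzmann(force, *popt) - resp) ** 2)))
    return BoltzmannFit(plateau=float(popt[0]), half_force=float(popt[1]),
                        width=float(popt[2]), residual=resid)


def f_at_fraction(fit: BoltzmannFit, q: float) -> float:
    """Force at which the fitted sigmoid reaches fraction ``q`` of its plateau.

    Closed form f0 + w·ln(q/(1-q)); q=0.5 gives f50, q=0.9 gives f90.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"fraction must lie in (0, 1), got {q}")
    return float(fit.half_force + fit.width * np.log(q / (1.0 - q)))
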