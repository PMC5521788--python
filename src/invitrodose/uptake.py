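"""Receptor-binding uptake kinetics and activity -> molecules-per-cell arithmetic.

Two empirical uptake models are used for somatostatin-analogue binding assays:

* time course at fixed (tracer-level) concentration — internalised activity
  grows linearly with incubation time while the membrane-bound fraction stays
  at a constant plateau;
* uptake after a fixed incubation as a function of peptide concentration —
  a single-exponential saturation curve  u([M]) = A * exp(-k [M]) + B,
  falling from A + B at tracer level to the plateau B when the receptors are
  saturated by peptide.

Percentages (%A, percent of the applied activity found cell-associated) are
kept on the percent scale throughout this module; callers converting to
absolute bound activity divide by 100.

The molecules-per-cell arithmetic converts an applied activity through the
molar activity of the labelled peptide into an amount of substance and thence
a molecule count, scaled by the bound fraction and the number of cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "AVOGADRO",
    "TimeKinetics",
    "ConcentrationUptake",
    "MolarActivity",
    "internalized_fraction",
    "uptake_at_concentration",
    "fit_time_kinetics",
    "fit_concentration_uptake",
    "scale_uptake",
    "molecules_per_cell",
]

AVOGADRO = 6.02214076e23  # mol^-1


@dataclass(frozen=True)
class TimeKinetics:
    """Linear internalisation kinetics with a constant membrane plateau.

    slope_pct_per_min: internalised fraction growth, in %A per minute.
    membrane_pct: time-independent membrane-bound level, in %A.
    """

    slope_pct_per_min: float
    membrane_pct: float
    slope_se: float | None = None
    membrane_se: float | None = None

    def __post_init__(self) -> None:
        if self.slope_pct_per_min < 0.0 or self.membrane_pct < 0.0:
            raise ValueError("kinetic parameters must be non-negative")


@dataclass(frozen=True)
class ConcentrationUptake:
    """Saturating uptake vs peptide concentration: u = A exp(-k [M]) + B.

    amplitude_pct (A) and plateau_pct (B) in %A; k_per_umol in L/umol
    (concentration in umol/L).
    """

    amplitude_pct: float
    k_per_umol: float
    plateau_pct: float
    se: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if min(self.amplitude_pct, self.k_per_umol, self.plateau_pct) < 0.0:
            raise ValueError("uptake model parameters must be non-negative")


@dataclass(frozen=True)
class MolarActivity:
    """Radioactivity per amount of labelled peptide, MBq/nmol."""

    mbq_per_nmol: float

    def __post_init__(self) -> None:
        if not self.mbq_per_nmol > 0.0:
            raise ValueError("molar activity must be positive")


def internalized_fraction(t_min: float, kin: TimeKinetics) -> tuple[float, float]:
    """(f_int, f_mem) in %A after ``t_min`` minutes of incubation."""
    if t_min < 0.0:
        raise ValueError("incubation time must be non-negative")
    return kin.slope_pct_per_min * t_min, kin.membrane_pct


def uptake_at_concentration(conc_umol_per_l: float, model: ConcentrationUptake) -> float:
    """Cell-associated activity (%A) at a given peptide concentration (umol/L)."""
    if conc_umol_per_l < 0.0:
        raise ValueError("concentration must be non-negative")
    return (
        model.amplitude_pct * math.exp(-model.k_per_umol * conc_umol_per_l)
        + model.plateau_pct
    )


def fit_time_kinetics(
    t_min: np.ndarray,
    internalized_pct: np.ndarray,
    membrane_pct: np.ndarray | None = None,
) -> TimeKinetics:
    """Fit the time-course model: zero-intercept line through the internalised
    data, mean level for the membrane data."""
    t = np.asarray(t_min, dtype=float)
    y = np.asarray(internalized_pct, dtype=float)
    if t.size != y.size or t.size < 2:
        raise ValueError("need at least two matching (t, f_int) points")
    stt = float(np.sum(t * t))
    if stt == 0.0:
        raise ValueError("all time points are zero; slope is undetermined")
    slope = float(np.sum(t * y) / stt)
    resid = y - slope * t
    dof = max(t.size - 1, 1)
    slope_se = float(np.sqrt(np.sum(resid**2) / dof / stt))
    mem = mem_se = None
    if membrane_pct is not None:
        m = np.asarray(membrane_pct, dtype=float)
        mem = float(np.mean(m))
        mem_se = float(np.std(m, ddof=1) / np.sqrt(m.size)) if m.size > 1 else 0.0
    return TimeKinetics(
        slope_pct_per_min=max(slope, 0.0),
        membrane_pct=mem if mem is not None else 0.0,
        slope_se=slope_se,
        membrane_se=mem_se,
    )


def fit_concentration_uptake(
    conc_umol_per_l: np.ndarray, percent_applied: np.ndarray
) -> ConcentrationUptake:
    """Nonlinear least-squares fit of A exp(-k [M]) + B to uptake data.

    Starting values come from the data range (plateau from the highest
    concentrations, amplitude from the intercept, k from the grid scale);
    parameters are constrained non-negative.
    """
    x = np.asarray(conc_umol_per_l, dtype=float)
    y = np.asarray(percent_applied, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need at least four matching (conc, %A) points")
    order = np.argsort(x)
    b0 = max(float(np.mean(y[order][-max(2, x.size // 4):])), 1e-6)
    a0 = max(float(np.mean(y[order][: max(2, x.size // 4)])) - b0, 1e-6)
    k0 = 1.0 / max(float(np.median(x[x > 0])) if np.any(x > 0) else 1.0, 1e-12)

    def model(xx, a, k, b):
        return a * np.exp(-k * xx) + b

    popt, pcov = optimize.curve_fit(
        model,
        x,
        y,
        p0=[a0, k0, b0],
        bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    se = tuple(float(s) for s in np.sqrt(np.diag(pcov)))
    return ConcentrationUptake(
        amplitude_pct=float(popt[0]),
        k_per_umol=float(popt[1]),
        plateau_pct=float(popt[2]),
        se=se,
    )


def scale_uptake(f_pct: float, n_assay: int, n_target: int) -> float:
    """Extrapolate a %A measured with ``n_assay`` cells to ``n_target`` cells.

    Proportional (dilute-limit) scaling: with receptors far from saturation
    the bound fraction is proportional to the number of cells present, so a
    plate with fewer cells binds proportionally less of the applied activity.
    """
    if n_assay <= 0 or n_target <= 0:
        raise ValueError("cell counts must be positive")
    if f_pct < 0.0:
        raise ValueError("uptake must be non-negative")
    return f_pct * (n_target / n_assay)


def molecules_per_cell(
    a_applied_mbq: float,
    ma: MolarActivity,
    f_bound: float,
    n_cells: int,
) -> float:
    """Number of labelled-peptide molecules bound per cell.

    ``a_applied_mbq / MA`` gives the applied amount in nmol; times Avogadro's
    number (per 1e9, nmol -> mol) the applied molecule count; the bound
    fraction and the cell count give the per-cell load.
    """
    if a_applied_mbq <= 0.0:
        raise ValueError("applied activity must be positive")
    if f_bound < 0.0:
        raise ValueError("bound fraction must be non-negative")
    if n_cells <= 0:
        raise ValueError("cell count must be positive")
    nmol = a_applied_mbq / ma.mbq_per_nmol
    return nmol * 1e-9 * AVOGADRO * f_bound / n_cells
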