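"""Seeded generators emulating the three wet-lab assays.

Each generator is a pure function of a :class:`SimulationConfig` — the seed
fixes every output bit-for-bit — and writes the same tabular schemas the
analysis stages read, so the whole pipeline is testable without laboratory
data.

* clonogenic assay: colonies per well are Poisson with mean
  seeded * pe * SF(D) under an LQ (or linear) survival model, plus 0-dose
  control wells that carry the plating efficiency;
* internalisation time course: linear growth of the internalised fraction
  with a constant membrane plateau, homoscedastic Gaussian noise in %A;
* uptake vs peptide concentration: single-exponential saturation
  A exp(-k[M]) + B with Gaussian noise in %A.

Default parameter values reproduce the study conditions these assays emulate
(triplicate wells, 500 cells seeded, plating efficiency 0.4, the Cs-137 LQ
parameters alpha = 0.21/Gy and beta = 0.05/Gy^2, internalisation slope
0.096 %A/min with a 0.56 %A membrane plateau, concentration-curve parameters
A = 1.0 %A, k = 39 L/umol, B = 0.38 %A over 15-390 nmol/L).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import ClonogenicDataset

__all__ = [
    "SimulationConfig",
    "simulate_clonogenic",
    "simulate_uptake_timecourse",
    "simulate_concentration_series",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters for all three assay generators (seed fixes all randomness)."""

    seed: int = 0
    n_replicates: int = 3

    # clonogenic assay
    doses_gy: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 5.0, 6.0, 8.0, 10.0)
    seeded: int = 500
    plating_efficiency: float = 0.4
    alpha_per_gy: float = 0.21
    beta_per_gy2: float = 0.05
    n_control_wells: int = 3

    # internalisation time course
    times_min: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0)
    slope_pct_per_min: float = 0.096
    membrane_pct: float = 0.56
    sigma_time_pct: float = 0.1

    # uptake vs concentration (umol/L; 15-390 nmol/L range)
    concentrations_umol_per_l: tuple[float, ...] = (
        0.015, 0.030, 0.060, 0.090, 0.150, 0.240, 0.300, 0.390,
    )
    amplitude_pct: float = 1.0
    k_per_umol: float = 39.0
    plateau_pct: float = 0.38
    sigma_conc_pct: float = 0.15

    def __post_init__(self) -> None:
        if self.n_replicates < 1 or self.seeded < 1:
            raise ValueError("replicate and seeded counts must be positive")
        if min(self.sigma_time_pct, self.sigma_conc_pct) < 0.0:
            raise ValueError("noise levels must be non-negative")
        for grid in (self.doses_gy, self.times_min, self.concentrations_umol_per_l):
            if len(grid) == 0:
                raise ValueError("grids must be non-empty")
        if not (0.0 < self.plating_efficiency <= 1.0):
            raise ValueError("plating efficiency must be in (0, 1]")


def expected_colonies(cfg: SimulationConfig, dose_gy: float) -> float:
    """Closed-form Poisson mean: seeded * pe * exp(-alpha D - beta D^2)."""
    sf = np.exp(-cfg.alpha_per_gy * dose_gy - cfg.beta_per_gy2 * dose_gy**2)
    return cfg.seeded * cfg.plating_efficiency * float(sf)


def simulate_clonogenic(cfg: SimulationConfig) -> ClonogenicDataset:
    """Poisson colony counts under the configured survival model.

    Includes ``n_control_wells`` unirradiated wells whose counts define the
    empirical plating efficiency of the dataset.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for rep in range(cfg.n_control_wells):
        mean = cfg.seeded * cfg.plating_efficiency
        rows.append((0.0, int(min(rng.poisson(mean), cfg.seeded)), cfg.seeded, rep))
    for dose in cfg.doses_gy:
        mean = expected_colonies(cfg, dose)
        for rep in range(cfg.n_replicates):
            rows.append((dose, int(min(rng.poisson(mean), cfg.seeded)), cfg.seeded, rep))
    df = pd.DataFrame(rows, columns=["dose_gy", "colonies", "seeded", "replicate"])
    return ClonogenicDataset(records=df)


def simulate_uptake_timecourse(cfg: SimulationConfig) -> pd.DataFrame:
    """Internalised and membrane-bound %A vs incubation time.

    Returns a table with columns ``time_min``, ``compartment``
    ('internalized' | 'membrane'), ``percent_applied``, ``replicate``;
    negative noise excursions are clipped at 0 (%A is a fraction of applied
    activity).
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for t in cfg.times_min:
        for rep in range(cfg.n_replicates):
            f_int = cfg.slope_pct_per_min * t + rng.normal(0.0, cfg.sigma_time_pct)
            f_mem = cfg.membrane_pct + rng.normal(0.0, cfg.sigma_time_pct)
            rows.append((t, "internalized", max(f_int, 0.0), rep))
            rows.append((t, "membrane", max(f_mem, 0.0), rep))
    return pd.DataFrame(
        rows, columns=["time_min", "compartment", "percent_applied", "replicate"]
    )


def simulate_concentration_series(cfg: SimulationConfig) -> pd.DataFrame:
    """Total cell-associated %A vs peptide concentration (umol/L).

    Columns: ``conc_umol_per_l``, ``percent_applied``, ``replicate``.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for conc in cfg.concentrations_umol_per_l:
        mean = cfg.amplitude_pct * np.exp(-cfg.k_per_umol * conc) + cfg.plateau_pct
        for rep in range(cfg.n_replicates):
            val = mean + rng.normal(0.0, cfg.sigma_conc_pct)
            rows.append((conc, max(float(val), 0.0), rep))
    return pd.DataFrame(rows, columns=["conc_umol_per_l", "percent_applied", "replicate"])
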