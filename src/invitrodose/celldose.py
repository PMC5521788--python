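"""Cellular self-dose from receptor-bound activity, MIRD cellular S-values.

Activity specifically bound to a cell delivers dose to that cell through the
cellular S-values S(C<-C) (activity distributed throughout the cell) and
S(C<-CS) (activity on the cell surface).  With a fraction f_int internalised
and f_mem on the membrane, the mean self-dose is

    D_cell = A~_cell * [ f_int * S(C<-C) + f_mem * S(C<-CS) ]

per chain member, with A~_cell the member's cumulated activity over the
colony-formation period.  For a chain fed by a single parent the per-decay
S-values combine with the cumulative branching fractions, e.g. for Bi-213:

    S_chain = S_Bi + BR_Po * S_Po + BR_Tl * S_Tl + 1 * S_Pb

Cross-dose S-values at tabulated inter-cell distances bound the contribution
from activity on neighbouring cells; in sparsely plated assays (inter-cell
distances far beyond the alpha range) it is negligible and the tabulated
values serve as an upper bound only.

The packaged set holds MIRDcell S-values for a 6 um radius cell for the
Bi-213 chain members and Lu-177 (mGy/MBq*s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

from .decaychain import DecayChain, cumulated_activity_chain
from .welldose import DoseBreakdown, MGY_PER_GY

__all__ = [
    "CellSValueSet",
    "UptakeFractions",
    "load_cell_s_values",
    "packaged_cell_s_values",
    "combine_chain_s",
    "cell_mean_dose",
    "cross_dose_bound",
]

SECONDS_PER_DAY = 86400.0
#: default colony-formation dose-integration window: bound activity measured
#: at the end of the 1 h incubation, followed up for 12 days
DEFAULT_WINDOW_S = (3600.0, 12.0 * SECONDS_PER_DAY)


@dataclass(frozen=True)
class UptakeFractions:
    """Partition of cell-associated activity between compartments.

    f_int is internalised (dose via S(C<-C)), f_mem membrane-bound (dose via
    S(C<-CS)); for the dose partition they must sum to 1.
    """

    f_int: float
    f_mem: float

    def __post_init__(self) -> None:
        if self.f_int < 0.0 or self.f_mem < 0.0:
            raise ValueError("uptake fractions must be non-negative")
        if self.f_int + self.f_mem > 0.0 and not math.isclose(
            self.f_int + self.f_mem, 1.0, rel_tol=1e-9
        ):
            raise ValueError(
                f"f_int + f_mem must equal 1 (got {self.f_int + self.f_mem:.6g})"
            )


@dataclass(frozen=True)
class CellSValueSet:
    """Cellular S-values (mGy/MBq*s) for a fixed cell radius.

    ``table`` is indexed by nuclide with columns ``s_self``, ``s_surface`` and
    ``s_cross_<d>um`` for each tabulated inter-cell distance; cross entries
    beyond the emission range are NaN ("out of range").
    """

    table: pd.DataFrame
    cell_radius_um: float = 6.0

    def s_self(self, nuclide: str) -> float:
        return float(self._row(nuclide)["s_self"])

    def s_surface(self, nuclide: str) -> float:
        return float(self._row(nuclide)["s_surface"])

    def cross_distances_um(self) -> list[float]:
        return sorted(
            float(c.removeprefix("s_cross_").removesuffix("um"))
            for c in self.table.columns
            if c.startswith("s_cross_")
        )

    def s_cross(self, nuclide: str, distance_um: float) -> float:
        """Cross S-value at a tabulated distance; NaN if out of emission range."""
        col = f"s_cross_{distance_um:g}um"
        if col not in self.table.columns:
            raise KeyError(f"no tabulated cross distance {distance_um} um")
        return float(self._row(nuclide)[col])

    def _row(self, nuclide: str) -> pd.Series:
        try:
            return self.table.loc[nuclide]
        except KeyError:
            raise KeyError(f"no cellular S-values for nuclide {nuclide!r}") from None


def load_cell_s_values(path: str | Path, cell_radius_um: float = 6.0) -> CellSValueSet:
    """Read a cellular S-value CSV; "OOR" marks cross-dose entries out of range."""
    try:
        df = pd.read_csv(path, na_values=["OOR"])
    except pd.errors.EmptyDataError:
        raise ValueError(f"cell S-value table {path} is empty") from None
    required = {"nuclide", "s_self", "s_surface"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"cell S-value CSV must have columns {sorted(required)}, got {list(df.columns)}"
        )
    df = df.set_index("nuclide")
    for nuc, row in df.iterrows():
        if not (row["s_self"] > 0.0 and row["s_surface"] > 0.0):
            raise ValueError(f"{nuc}: self/surface S-values must be positive")
        if row["s_self"] < row["s_surface"]:
            raise ValueError(f"{nuc}: S(C<-C) must be >= S(C<-CS)")
        for col in df.columns:
            if col.startswith("s_cross_") and not pd.isna(row[col]):
                if not (0.0 < row[col] <= row["s_surface"]):
                    raise ValueError(f"{nuc}: cross S-value {col} outside (0, S_surface]")
    return CellSValueSet(table=df, cell_radius_um=cell_radius_um)


def packaged_cell_s_values() -> CellSValueSet:
    """Packaged MIRDcell S-values for a 6 um cell (Bi-213 chain and Lu-177)."""
    with resources.as_file(
        resources.files("invitrodose.data") / "cell_s_values_6um.csv"
    ) as p:
        return load_cell_s_values(p, cell_radius_um=6.0)


def combine_chain_s(
    svals: CellSValueSet | Mapping[str, float],
    chain: DecayChain,
    site: str = "self",
) -> float:
    """Branching-weighted combined S-value per parent decay (mGy/MBq*s).

    Weights each member's S-value by the cumulative branching fraction, i.e.
    the expected number of that member's decays per parent decay.
    """
    if site not in ("self", "surface"):
        raise ValueError("site must be 'self' or 'surface'")
    total = 0.0
    for nuc in chain.members:
        if isinstance(svals, CellSValueSet):
            s = svals.s_self(nuc.name) if site == "self" else svals.s_surface(nuc.name)
        else:
            try:
                s = float(svals[nuc.name])
            except KeyError:
                raise KeyError(f"no S-value supplied for chain member {nuc.name!r}") from None
        total += chain.branching_fraction(nuc.name) * s
    return total


def cell_mean_dose(
    a_cell: float,
    chain: DecayChain,
    fractions: UptakeFractions,
    svals: CellSValueSet,
    window: tuple[float, float] = DEFAULT_WINDOW_S,
) -> DoseBreakdown:
    """Mean self-absorbed dose (Gy) to a cell from bound activity.

    ``a_cell`` is the parent activity (MBq) bound to the cell at the window
    start T0 (the end of the incubation); progeny are taken as zero there and
    build in as the chain decays, with no clearance of bound ligand.  The
    window (T0, T) is in seconds from the start of incubation; integration
    runs over its duration T - T0.
    """
    t0, t1 = window
    if t1 < t0:
        raise ValueError(f"window end {t1} precedes start {t0}")
    if a_cell < 0.0:
        raise ValueError("bound activity must be non-negative")
    cum = cumulated_activity_chain(a_cell, chain, 0.0, t1 - t0)
    components: dict[tuple[str, str], float] = {}
    for nuc in chain.members:
        s_eff = (
            fractions.f_int * svals.s_self(nuc.name)
            + fractions.f_mem * svals.s_surface(nuc.name)
        )
        components[(nuc.name, "all")] = cum[nuc.name] * s_eff / MGY_PER_GY
    return DoseBreakdown(components=components)


def cross_dose_bound(
    svals: CellSValueSet,
    nuclide: str,
    distance_um: float,
    a_cum: float,
) -> tuple[float, bool]:
    """Upper bound (Gy) on the dose to a neighbour cell at a given distance.

    Uses the cross S-value at the nearest tabulated distance not exceeding
    ``distance_um`` (cross-dose falls with distance, so this bounds the true
    value). Beyond the largest tabulated distance, or where the table marks
    the emission range exceeded, returns ``(0.0, True)`` with the second
    element flagging "out of tabulated range".
    """
    if a_cum < 0.0:
        raise ValueError("cumulated activity must be non-negative")
    distances = svals.cross_distances_um()
    if not distances:
        raise ValueError("S-value set has no cross-dose columns")
    if distance_um < distances[0]:
        raise ValueError(
            f"distance {distance_um} um below smallest tabulated ({distances[0]} um); "
            "no bound available"
        )
    if distance_um > distances[-1]:
        return 0.0, True
    nearest = max(d for d in distances if d <= distance_um)
    s = svals.s_cross(nuclide, nearest)
    if pd.isna(s):
        return 0.0, True
    return a_cum * s / MGY_PER_GY, False
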