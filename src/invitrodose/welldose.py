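"""Absorbed dose to the bottom cell layer of a well from activity in the medium.

During a radioligand incubation the cells sit on the bottom of a well filled
with medium in which the activity is distributed homogeneously.  The mean
absorbed dose to the bottom layer (where the seeded cells lie) is, in the
MIRD schema,

    D(layer <- fluid) = A~_fluid x S(layer <- fluid)

summed over every member of the decay chain and every radiation class
(alpha, beta, Auger/internal-conversion electrons, gamma), where A~ is the
cumulated activity of the chain member over the incubation window and S the
tabulated dose rate per unit activity for the well geometry.  S-values for a
2 mL cylindrical 6-well cavity, scored in the bottom 25 um, are packaged for
the Bi-213 chain; other geometries or nuclides take a user-supplied table.

Units: S in mGy/(MBq*s) with A~ in MBq*s; doses reported in Gy.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

from .decaychain import DecayChain, cumulated_activity_chain

__all__ = [
    "RADIATION_CLASSES",
    "LayerSValueTable",
    "DoseBreakdown",
    "load_layer_s_values",
    "packaged_layer_s_values",
    "medium_dose",
]

RADIATION_CLASSES = ("alpha", "beta", "auger_ic", "gamma")

MGY_PER_GY = 1.0e3


@dataclass(frozen=True)
class LayerSValueTable:
    """Per-(nuclide, radiation class) S-values for one target layer.

    ``table`` is indexed by (nuclide, radiation_class) with columns
    ``phi`` (absorbed fraction of emitted energy, dimensionless) and
    ``s_mGy_per_MBq_s``.
    """

    table: pd.DataFrame
    target: str = "bottom 25 um"

    def nuclides(self) -> list[str]:
        return sorted(self.table.index.get_level_values("nuclide").unique())

    def s(self, nuclide: str, radiation_class: str) -> float:
        try:
            return float(self.table.loc[(nuclide, radiation_class), "s_mGy_per_MBq_s"])
        except KeyError:
            return 0.0

    def classes_for(self, nuclide: str) -> list[str]:
        if nuclide not in self.table.index.get_level_values("nuclide"):
            return []
        return list(self.table.loc[nuclide].index)

    def total_s(self, nuclide: str) -> float:
        """Sum of the class S-values of one nuclide."""
        if nuclide not in self.table.index.get_level_values("nuclide"):
            raise KeyError(f"no S-values for nuclide {nuclide!r}")
        return float(self.table.loc[nuclide, "s_mGy_per_MBq_s"].sum())


@dataclass(frozen=True)
class DoseBreakdown:
    """Absorbed dose split per (nuclide, radiation class), in Gy.

    ``alpha_fraction`` is the share delivered by alpha particles; it is None
    when the components carry no radiation-class information (e.g. cellular
    S-values, which are not class-resolved).
    """

    components: Mapping[tuple[str, str], float]

    @property
    def total(self) -> float:
        return float(sum(self.components.values()))

    @property
    def alpha_fraction(self) -> float | None:
        total = self.total
        if total == 0.0:
            return 0.0
        classes = {cls for _, cls in self.components}
        if classes == {"all"}:
            return None
        alpha = sum(d for (_, cls), d in self.components.items() if cls == "alpha")
        return alpha / total

    def per_nuclide(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for (nuc, _), d in self.components.items():
            out[nuc] = out.get(nuc, 0.0) + d
        return out

    def to_dict(self) -> dict:
        return {
            "components_gy": {f"{n}/{c}": v for (n, c), v in self.components.items()},
            "per_nuclide_gy": self.per_nuclide(),
            "total_gy": self.total,
            "alpha_fraction": self.alpha_fraction,
        }


def load_layer_s_values(path: str | Path, target: str = "bottom 25 um") -> LayerSValueTable:
    """Read and validate a layer S-value CSV.

    Expected header: ``nuclide, radiation_class, phi, s_mGy_per_MBq_s``.
    Blank phi/S cells are read as 0 (a nuclide simply lacking that emission).
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"layer S-value table {path} is empty") from None
    required = {"nuclide", "radiation_class", "phi", "s_mGy_per_MBq_s"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"layer S-value CSV must have columns {sorted(required)}, got {list(df.columns)}"
        )
    if df.empty:
        raise ValueError(f"layer S-value table {path} is empty")
    df = df.copy()
    df["phi"] = df["phi"].fillna(0.0)
    df["s_mGy_per_MBq_s"] = df["s_mGy_per_MBq_s"].fillna(0.0)
    for i, row in df.iterrows():
        if row["radiation_class"] not in RADIATION_CLASSES:
            raise ValueError(
                f"row {i}: unknown radiation class {row['radiation_class']!r}"
            )
        if not (0.0 <= row["phi"] <= 1.0):
            raise ValueError(f"row {i}: absorbed fraction {row['phi']} outside [0, 1]")
        if row["s_mGy_per_MBq_s"] < 0.0:
            raise ValueError(f"row {i}: negative S-value {row['s_mGy_per_MBq_s']}")
    dup = df.duplicated(subset=["nuclide", "radiation_class"])
    if dup.any():
        raise ValueError(f"duplicate (nuclide, class) rows at index {list(df[dup].index)}")
    table = df.set_index(["nuclide", "radiation_class"])[["phi", "s_mGy_per_MBq_s"]]
    return LayerSValueTable(table=table, target=target)


def packaged_layer_s_values() -> LayerSValueTable:
    """The packaged bottom-25 um S-value table for the Bi-213 chain (6-well, 2 mL)."""
    with resources.as_file(
        resources.files("invitrodose.data") / "layer_s_values_bi213.csv"
    ) as p:
        return load_layer_s_values(p)


def medium_dose(
    a0: float,
    chain: DecayChain,
    incubation: tuple[float, float],
    table: LayerSValueTable,
) -> DoseBreakdown:
    """Mean absorbed dose to the bottom layer from activity in the medium.

    Parameters
    ----------
    a0
        Parent activity (MBq) in the well at t = 0.
    chain
        Decay chain of the parent (progeny contribute with their own S-values).
    incubation
        Integration window (t0, t1) in seconds, typically (0, 3600).
    table
        Layer S-value table covering every chain member with nonzero emissions.

    Raises
    ------
    KeyError
        If a chain member accumulates activity but has no table entry at all.
    """
    if a0 < 0.0:
        raise ValueError("activity must be non-negative")
    t0, t1 = incubation
    cum = cumulated_activity_chain(a0, chain, t0, t1)
    components: dict[tuple[str, str], float] = {}
    for nuc in chain.members:
        a_cum = cum[nuc.name]
        if a_cum == 0.0:
            continue
        classes = table.classes_for(nuc.name)
        if not classes:
            raise KeyError(
                f"no layer S-values for chain member {nuc.name!r} "
                f"(cumulated activity {a_cum:.4g} MBq*s)"
            )
        for cls in classes:
            components[(nuc.name, cls)] = a_cum * table.s(nuc.name, cls) / MGY_PER_GY
    if not components:
        components = {(chain.parent.name, cls): 0.0 for cls in ("alpha", "beta")}
    return DoseBreakdown(components=components)
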