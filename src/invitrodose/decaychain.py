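"""Closed-form activities and cumulated activities for short radioactive decay chains.

The chains of interest here are the two used for receptor-targeted
radioligand work: the branched three-generation alpha chain

    Bi-213 --(97.84%, beta)--> Po-213 --> Pb-209
    Bi-213 --( 2.16%, alpha)--> Tl-209 --> Pb-209

and the single beta emitter Lu-177.  Activities of every chain member are
sums of exponentials (Bateman solutions); the cumulated activity
A~ = integral of A(t) over a time window is obtained by integrating each
exponential term in closed form.  A numerically delicate regime occurs when a
daughter decays vastly faster than its parent (Po-213, half-life 4.2 us,
against Bi-213, 45.59 min): the daughter's own transient term underflows
within milliseconds, and the daughter is treated as in secular equilibrium
with its feed (activity = branching ratio x parent activity).

Units: time in seconds, activity in MBq, cumulated activity in MBq*s.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Nuclide",
    "DecayChain",
    "CumulatedActivity",
    "load_chain",
    "cumulated_activity_parent",
    "cumulated_activity_chain",
    "fraction_of_decays_by",
]

LN2 = math.log(2.0)

#: daughter/parent decay-constant ratio beyond which the daughter is treated
#: as in secular equilibrium with the feeding term (its transient underflows)
SECULAR_EQUILIBRIUM_RATIO = 1.0e6


@dataclass(frozen=True)
class Nuclide:
    """A radionuclide identified by name and physical half-life (seconds)."""

    name: str
    half_life_s: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("nuclide name must be non-empty")
        if not (self.half_life_s > 0.0) or not math.isfinite(self.half_life_s):
            raise ValueError(
                f"half-life must be positive and finite, got {self.half_life_s!r} "
                f"for {self.name!r}"
            )

    @property
    def decay_constant(self) -> float:
        """Decay constant lambda = ln2 / T_1/2, in s^-1."""
        return LN2 / self.half_life_s


@dataclass(frozen=True)
class CumulatedActivity:
    """Time-integrated activity per chain member over a window, in MBq*s."""

    window: tuple[float, float]
    per_nuclide: Mapping[str, float]

    def __getitem__(self, name: str) -> float:
        return self.per_nuclide[name]

    def total(self) -> float:
        return float(sum(self.per_nuclide.values()))


class DecayChain:
    """An acyclic decay chain with branching.

    Parameters
    ----------
    nuclides
        Chain members. The first nuclide with no feeding edge is the parent
        whose initial activity normalises everything downstream.
    edges
        ``(parent_name, daughter_name, branching_ratio)`` triples. Branching
        ratios out of any node must sum to at most 1.
    """

    def __init__(
        self,
        nuclides: Iterable[Nuclide],
        edges: Iterable[tuple[str, str, float]] = (),
    ) -> None:
        self.nuclides: dict[str, Nuclide] = {}
        for nuc in nuclides:
            if nuc.name in self.nuclides:
                raise ValueError(f"duplicate nuclide {nuc.name!r}")
            self.nuclides[nuc.name] = nuc
        self.edges: list[tuple[str, str, float]] = []
        for parent, daughter, br in edges:
            for name in (parent, daughter):
                if name not in self.nuclides:
                    raise ValueError(f"edge references unknown nuclide {name!r}")
            if not (0.0 <= br <= 1.0):
                raise ValueError(f"branching ratio {br} outside [0, 1]")
            self.edges.append((parent, daughter, float(br)))
        self._validate()

    # -- structure -------------------------------------------------------

    def _validate(self) -> None:
        out: dict[str, float] = {}
        for parent, _, br in self.edges:
            out[parent] = out.get(parent, 0.0) + br
        for parent, total in out.items():
            if total > 1.0 + 1e-9:
                raise ValueError(
                    f"branching ratios out of {parent!r} sum to {total:.6g} > 1"
                )
        roots = [n for n in self.nuclides if not any(d == n for _, d, _ in self.edges)]
        if len(roots) != 1:
            raise ValueError(
                f"chain must have exactly one parent nuclide, found {roots!r}"
            )
        self._root = roots[0]
        self._topo_order()  # raises on cycles

    def _topo_order(self) -> list[str]:
        order: list[str] = []
        indeg = {n: 0 for n in self.nuclides}
        for _, d, _ in self.edges:
            indeg[d] += 1
        queue = [n for n, k in indeg.items() if k == 0]
        while queue:
            n = queue.pop(0)
            order.append(n)
            for p, d, _ in self.edges:
                if p == n:
                    indeg[d] -= 1
                    if indeg[d] == 0:
                        queue.append(d)
        if len(order) != len(self.nuclides):
            raise ValueError("decay chain contains a cycle")
        return order

    @property
    def parent(self) -> Nuclide:
        """The chain head (the nuclide supplied at t = 0)."""
        return self.nuclides[self._root]

    @property
    def members(self) -> list[Nuclide]:
        return [self.nuclides[n] for n in self._topo_order()]

    def parents_of(self, name: str) -> list[tuple[str, float]]:
        return [(p, br) for p, d, br in self.edges if d == name]

    def branching_fraction(self, name: str) -> float:
        """Cumulative probability that one parent decay eventually decays as `name`."""
        frac = {self._root: 1.0}
        for node in self._topo_order():
            if node == self._root:
                continue
            frac[node] = sum(frac[p] * br for p, br in self.parents_of(node))
        return frac[name]

    # -- Bateman terms ---------------------------------------------------

    def activity_terms(self, a0: float) -> dict[str, dict[float, float]]:
        """Per-nuclide activity as a sum of exponentials.

        Returns ``{nuclide: {lambda_j: c_j}}`` such that
        ``A_nuclide(t) = sum_j c_j * exp(-lambda_j * t)`` for an initial parent
        activity ``a0`` at t = 0 with all progeny at zero.

        A daughter whose decay constant exceeds that of a feeding term by more
        than :data:`SECULAR_EQUILIBRIUM_RATIO` inherits the feeding exponential
        directly (secular-equilibrium limit); its own transient, which decays
        within a few daughter half-lives, is dropped.
        """
        if a0 < 0.0:
            raise ValueError("initial activity must be non-negative")
        terms: dict[str, dict[float, float]] = {}
        for name in self._topo_order():
            lam = self.nuclides[name].decay_constant
            if name == self._root:
                terms[name] = {lam: a0}
                continue
            acc: dict[float, float] = {}
            for pname, br in self.parents_of(name):
                for lam_j, c in terms[pname].items():
                    feed = br * c
                    if feed == 0.0:
                        continue
                    if lam_j > 0.0 and lam / lam_j > SECULAR_EQUILIBRIUM_RATIO:
                        acc[lam_j] = acc.get(lam_j, 0.0) + feed
                        continue
                    if math.isclose(lam, lam_j, rel_tol=1e-12):
                        raise ValueError(
                            f"degenerate decay constants ({name!r} vs feeding term); "
                            "equal-lambda Bateman terms are not supported"
                        )
                    f = lam / (lam - lam_j)
                    acc[lam_j] = acc.get(lam_j, 0.0) + feed * f
                    acc[lam] = acc.get(lam, 0.0) - feed * f
            terms[name] = acc
        return terms

    def activity(self, a0: float, t: float) -> dict[str, float]:
        """Instantaneous activity (MBq) of every member at time t (s)."""
        if t < 0.0:
            raise ValueError("time must be non-negative")
        out = {}
        for name, term in self.activity_terms(a0).items():
            out[name] = max(
                0.0, sum(c * math.exp(-lam * t) for lam, c in term.items())
            )
        return out

    # -- I/O -------------------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path) -> "DecayChain":
        """Read a chain from a CSV with columns nuclide, half_life_s, parent, branching_ratio.

        A nuclide fed by several parents appears on one row per feeding edge;
        rows with an empty parent declare the chain head.
        """
        nuclides: dict[str, Nuclide] = {}
        edges: list[tuple[str, str, float]] = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"nuclide", "half_life_s", "parent", "branching_ratio"}
            if reader.fieldnames is None or not required.issubset(reader.fieldnames):
                raise ValueError(
                    f"chain CSV must have columns {sorted(required)}, "
                    f"got {reader.fieldnames}"
                )
            for row in reader:
                name = row["nuclide"].strip()
                hl = float(row["half_life_s"])
                if name not in nuclides:
                    nuclides[name] = Nuclide(name, hl)
                elif not math.isclose(nuclides[name].half_life_s, hl):
                    raise ValueError(f"conflicting half-lives for {name!r}")
                parent = (row["parent"] or "").strip()
                if parent:
                    edges.append((parent, name, float(row["branching_ratio"])))
        if not nuclides:
            raise ValueError(f"no nuclides found in {path}")
        return cls(nuclides.values(), edges)


def load_chain(name: str) -> DecayChain:
    """Load a packaged chain specification: ``"bi213"`` or ``"lu177"``."""
    fname = {"bi213": "bi213_chain.csv", "lu177": "lu177.csv"}.get(name)
    if fname is None:
        raise ValueError(f"unknown packaged chain {name!r}; use 'bi213' or 'lu177'")
    with resources.as_file(resources.files("invitrodose.data") / fname) as p:
        return DecayChain.from_csv(p)


def _integral_exp(lam: float, t0: float, t1: float) -> float:
    """Integral of exp(-lam*t) over [t0, t1], stable for small and huge lam."""
    dt = t1 - t0
    if lam == 0.0 or lam * dt < 1e-14:
        return math.exp(-lam * t0) * dt
    try:
        head = math.exp(-lam * t0)
    except OverflowError:  # pragma: no cover - lam*t0 hugely negative impossible
        raise
    if head == 0.0:
        return 0.0
    return head * (-math.expm1(-lam * dt)) / lam


def cumulated_activity_parent(
    a0: float, nuclide: Nuclide, t0: float, t1: float
) -> float:
    """Cumulated activity (MBq*s) of a lone decaying nuclide over [t0, t1].

    ``a0`` is the activity at t = 0; the result is
    ``a0 * (exp(-lam*t0) - exp(-lam*t1)) / lam``, with the no-decay limit
    ``a0 * (t1 - t0)`` as lam -> 0.
    """
    _check_window(t0, t1)
    if a0 < 0.0:
        raise ValueError("activity must be non-negative")
    return a0 * _integral_exp(nuclide.decay_constant, t0, t1)


def cumulated_activity_chain(
    a0_parent: float, chain: DecayChain, t0: float, t1: float
) -> CumulatedActivity:
    """Cumulated activity of every chain member over [t0, t1].

    The parent has activity ``a0_parent`` (MBq) at t = 0 and all progeny start
    at zero. Short-lived daughters in the secular-equilibrium regime carry
    their feed's time dependence (see :meth:`DecayChain.activity_terms`).
    """
    _check_window(t0, t1)
    if a0_parent < 0.0:
        raise ValueError("activity must be non-negative")
    per: dict[str, float] = {}
    for name, terms in chain.activity_terms(a0_parent).items():
        val = sum(c * _integral_exp(lam, t0, t1) for lam, c in terms.items())
        per[name] = max(0.0, val)  # clamp float-cancellation dust
    return CumulatedActivity(window=(t0, t1), per_nuclide=per)


def fraction_of_decays_by(nuclide: Nuclide, t: float) -> float:
    """Fraction of an initial stock of `nuclide` that has decayed by time t."""
    if t < 0.0:
        raise ValueError("time must be non-negative")
    return -math.expm1(-nuclide.decay_constant * t)


def _check_window(t0: float, t1: float) -> None:
    if t0 < 0.0 or t1 < 0.0:
        raise ValueError("time window must be non-negative")
    if t1 < t0:
        raise ValueError(f"window end {t1} precedes start {t0}")
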