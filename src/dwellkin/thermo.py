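"""Derived equilibrium constants and repeat-array folding energetics.

Two independent pieces live here:

* equilibrium summaries of a fitted rate-constant set, including the
  composite apparent affinity

      K_app = K_free * K2 * (1 + k3/km3) / (1 + K_free)

  with ``K_free = k1/km1`` and ``K2 = k2/km2`` (reported in nM, reproducing
  the printed arithmetic of the source tables verbatim);

* free energies of partly folded conformations of a nearest-neighbor
  repeat-array model: a conformation is scored as the sum of intrinsic
  energies of its folded repeats plus interfacial energies of its intact
  interfaces, and differences to the fully folded state are exact weight
  ratios (no partition-function sum needed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scheme import RateConstantSet

__all__ = [
    "EquilibriumSummary",
    "IsingEnergyModel",
    "Conformation",
    "equilibrium_summary",
    "conformation_free_energy",
    "state_catalog",
    "read_rate_table",
]


@dataclass(frozen=True)
class EquilibriumSummary:
    """Equilibrium constants derived from the six microscopic rates."""

    k_eq_free: float     # k1/km1, dimensionless
    k_eq_bound: float    # k3/km3, dimensionless
    k2_over_km2: float   # nM^-1
    k_app: float         # composite affinity, reported in nM

    def as_dict(self) -> dict[str, float]:
        return {
            "K_eq_free": self.k_eq_free,
            "K_eq_bound": self.k_eq_bound,
            "K2": self.k2_over_km2,
            "K_app_nM": self.k_app,
        }


def equilibrium_summary(rates: RateConstantSet | dict) -> EquilibriumSummary:
    """Derived equilibrium constants, with the composite affinity K_app.

    Raises on a zero denominator, naming the offending constant.
    """
    rd = rates.as_dict() if isinstance(rates, RateConstantSet) else dict(rates)
    for name in ("km1", "km2", "km3"):
        if rd[name] == 0:
            raise ZeroDivisionError(f"rate constant {name!r} is zero; ratio undefined")
    k_free = rd["k1"] / rd["km1"]
    k_bound = rd["k3"] / rd["km3"]
    k2 = rd["k2"] / rd["km2"]
    k_app = k_free * k2 * (1.0 + k_bound) / (1.0 + k_free)
    return EquilibriumSummary(
        k_eq_free=k_free, k_eq_bound=k_bound, k2_over_km2=k2, k_app=k_app
    )


@dataclass(frozen=True)
class IsingEnergyModel:
    """Nearest-neighbor energetics of an n-repeat array.

    ``dg_intrinsic[i]`` is the folding free energy of repeat ``i`` (may be
    heterogeneous by repeat type); ``dg_interface[j]`` couples repeats ``j``
    and ``j + 1``. ``rt`` sets the temperature scale (kcal/mol).
    """

    dg_intrinsic: tuple[float, ...]
    dg_interface: tuple[float, ...]
    rt: float = 0.593  # kcal/mol at 298 K

    def __post_init__(self) -> None:
        if len(self.dg_interface) != len(self.dg_intrinsic) - 1:
            raise ValueError("need exactly n - 1 interfaces for n repeats")
        if self.rt <= 0:
            raise ValueError("rt must be positive")

    @property
    def n_repeats(self) -> int:
        return len(self.dg_intrinsic)

    @classmethod
    def uniform(cls, n_repeats: int, dg_intrinsic: float, dg_interface: float,
                rt: float = 0.593) -> "IsingEnergyModel":
        return cls(
            dg_intrinsic=(dg_intrinsic,) * n_repeats,
            dg_interface=(dg_interface,) * (n_repeats - 1),
            rt=rt,
        )


@dataclass(frozen=True)
class Conformation:
    """Folded/intact masks for repeats and interfaces.

    An interface can be intact only when both flanking repeats are folded.
    """

    folded: tuple[bool, ...]
    intact: tuple[bool, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.intact) != len(self.folded) - 1:
            raise ValueError("need exactly n - 1 interfaces for n repeats")
        for j, ok in enumerate(self.intact):
            if ok and not (self.folded[j] and self.folded[j + 1]):
                raise ValueError(
                    f"interface {j} intact but a flanking repeat is unfolded"
                )

    @classmethod
    def fully_folded(cls, n: int, label: str = "folded") -> "Conformation":
        return cls(folded=(True,) * n, intact=(True,) * (n - 1), label=label)

    @classmethod
    def with_unfolded(cls, n: int, unfolded: tuple[int, ...],
                      label: str = "") -> "Conformation":
        """All-folded conformation with the given repeats unfolded; every
        interface touching an unfolded repeat is broken."""
        folded = [i not in unfolded for i in range(n)]
        intact = [folded[j] and folded[j + 1] for j in range(n - 1)]
        return cls(folded=tuple(folded), intact=tuple(intact), label=label)


def _energy(model: IsingEnergyModel, conf: Conformation) -> float:
    g = 0.0
    for dg, ok in zip(model.dg_intrinsic, conf.folded):
        if ok:
            g += dg
    for dg, ok in zip(model.dg_interface, conf.intact):
        if ok:
            g += dg
    return g


def conformation_free_energy(model: IsingEnergyModel, conf: Conformation) -> float:
    """Free energy of a conformation relative to the fully folded state.

    Equal to ``-RT ln(w(conf)/w(folded))`` with Boltzmann weights
    ``w = exp(-G/RT)``; the weight ratio collapses to the energy difference
    ``G(conf) - G(folded)``, exact for pairwise state comparisons.
    """
    if model.n_repeats != len(conf.folded):
        raise ValueError("model and conformation sizes differ")
    ref = Conformation.fully_folded(model.n_repeats)
    return _energy(model, conf) - _energy(model, ref)


def state_catalog(n_repeats: int) -> list[Conformation]:
    """Fully folded plus the three canonical partly folded states.

    End-frayed: first repeat unfolded. Internally unfolded: repeat
    ``ceil(n/2)`` unfolded. Interfacially fractured: all repeats folded,
    interface between repeats ``ceil(n/2)`` and ``ceil(n/2) + 1`` broken.
    """
    if n_repeats < 3:
        raise ValueError("need at least 3 repeats for the canonical catalog")
    n = n_repeats
    mid = int(np.ceil(n / 2))  # 1-based repeat index
    folded = Conformation.fully_folded(n)
    end_frayed = Conformation.with_unfolded(n, (0,), label="end-frayed")
    internal = Conformation.with_unfolded(n, (mid - 1,), label="internally-unfolded")
    intact = [True] * (n - 1)
    intact[mid - 1] = False
    fractured = Conformation(
        folded=(True,) * n, intact=tuple(intact), label="interfacially-fractured"
    )
    return [folded, end_frayed, internal, fractured]


def read_rate_table(path) -> dict[str, RateConstantSet]:
    """Read a rate-constant table CSV (construct, k1, km1, k2, km2, k3, km3)."""
    df = pd.read_csv(path, comment="#")
    required = {"construct", "k1", "km1", "k2", "km2", "k3", "km3"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"rate table missing columns: {sorted(missing)}")
    out: dict[str, RateConstantSet] = {}
    for _, row in df.iterrows():
        out[str(row["construct"])] = RateConstantSet(
            k1=row["k1"], km1=row["km1"], k2=row["k2"],
            km2=row["km2"], k3=row["k3"], km3=row["km3"],
        )
    return out
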