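"""Kinetic scheme representation for a four-state binding mechanism.

The canonical mechanism has two unbound conformers -- a binding-incompetent
state ``U`` and a binding-competent state ``A`` -- and two bound states --
the directly-dissociating state ``B1`` and a long-lived state ``B2`` that
must convert back to ``B1`` before dissociating::

    U  <--k1/km1-->  A  <--k2*[L]/km2-->  B1  <--k3/km3-->  B2

Association is the single ligand-dependent (pseudo-first-order) step.
Schemes are data-driven: states, transitions and observable classes are
declared, so condensed (absorbing) variants reuse all machinery.

Convention: column generator, ``dp/dt = M @ p`` with ``M[i, j]`` the rate
from state ``j`` into state ``i``; columns of conservative schemes sum to 0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "RateConstantSet",
    "Transition",
    "KineticScheme",
    "build_four_state_scheme",
    "binding_subscheme",
    "unbinding_subscheme",
    "rate_matrix",
    "stationary_distribution",
    "transient_block",
]

UNBOUND = "unbound"
BOUND = "bound"


@dataclass(frozen=True)
class RateConstantSet:
    """The six microscopic rate constants.

    Units: ``k2`` is a bimolecular constant in nM^-1 s^-1; all others are
    first-order constants in s^-1.

    Attributes
    ----------
    k1 : float
        Unbound isomerization, incompetent -> competent (s^-1).
    km1 : float
        Unbound isomerization, competent -> incompetent (s^-1).
    k2 : float
        Association, competent + ligand -> bound-1 (nM^-1 s^-1).
    km2 : float
        Dissociation, bound-1 -> competent (s^-1).
    k3 : float
        Bound isomerization, bound-1 -> bound-2 (s^-1).
    km3 : float
        Bound isomerization, bound-2 -> bound-1 (s^-1).
    """

    k1: float
    km1: float
    k2: float
    km2: float
    k3: float
    km3: float

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"rate constant {name!r} must be finite and >= 0, got {value}")

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    def replace(self, **kwargs: float) -> "RateConstantSet":
        d = self.as_dict()
        d.update(kwargs)
        return RateConstantSet(**d)


@dataclass(frozen=True)
class Transition:
    """A single reaction channel.

    ``ligand_order`` is 0 for unimolecular steps and 1 for the
    pseudo-first-order association step (propensity ``rate * [L]``).
    """

    source: str
    target: str
    rate_symbol: str
    ligand_order: int = 0


@dataclass(frozen=True)
class KineticScheme:
    """States, transitions and per-state observable class.

    ``absorbing`` states have had their outgoing transitions removed
    (condensed schemes); for those the accumulated occupancy equals the
    first-passage-time CDF of the original chain.
    """

    states: tuple[str, ...]
    transitions: tuple[Transition, ...]
    observable_class: Mapping[str, str]
    absorbing: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        known = set(self.states)
        for tr in self.transitions:
            if tr.source not in known or tr.target not in known:
                raise ValueError(f"transition {tr} references unknown state")
            if tr.source in self.absorbing:
                raise ValueError(f"absorbing state {tr.source!r} has an outgoing transition")
            if tr.ligand_order not in (0, 1):
                raise ValueError("ligand_order must be 0 or 1")
        missing = known - set(self.observable_class)
        if missing:
            raise ValueError(f"states without observable class: {sorted(missing)}")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        return self.states.index(state)

    def states_of_class(self, cls: str) -> tuple[str, ...]:
        return tuple(s for s in self.states if self.observable_class[s] == cls)

    # -- serialization --------------------------------------------------

    def to_dict(self, rates: RateConstantSet | None = None) -> dict:
        doc: dict = {
            "states": list(self.states),
            "observable_class": dict(self.observable_class),
            "absorbing": sorted(self.absorbing),
            "transitions": [asdict(tr) for tr in self.transitions],
        }
        if rates is not None:
            doc["rate_constants"] = rates.as_dict()
            doc["units"] = {"k2": "nM^-1 s^-1", "others": "s^-1"}
        return doc

    @classmethod
    def from_dict(cls, doc: Mapping) -> "KineticScheme":
        return cls(
            states=tuple(doc["states"]),
            transitions=tuple(Transition(**tr) for tr in doc["transitions"]),
            observable_class=dict(doc["observable_class"]),
            absorbing=frozenset(doc.get("absorbing", ())),
        )

    def to_json(self, path, rates: RateConstantSet | None = None) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(rates), fh, indent=2)

    def to_yaml(self, path, rates: RateConstantSet | None = None) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(rates), fh, sort_keys=False)

    @classmethod
    def from_file(cls, path) -> "KineticScheme":
        with open(path) as fh:
            text = fh.read()
        try:
            doc = json.loads(text)
        except json.JSONDecodeError:
            doc = yaml.safe_load(text)
        return cls.from_dict(doc)


# canonical state ids
STATE_INCOMPETENT = "U"
STATE_COMPETENT = "A"
STATE_BOUND_SHORT = "B1"
STATE_BOUND_LONG = "B2"


def build_four_state_scheme() -> KineticScheme:
    """Return the canonical four-state scheme with symbolic rates."""
    return KineticScheme(
        states=(STATE_INCOMPETENT, STATE_COMPETENT, STATE_BOUND_SHORT, STATE_BOUND_LONG),
        transitions=(
            Transition("U", "A", "k1"),
            Transition("A", "U", "km1"),
            Transition("A", "B1", "k2", ligand_order=1),
            Transition("B1", "A", "km2"),
            Transition("B1", "B2", "k3"),
            Transition("B2", "B1", "km3"),
        ),
        observable_class={"U": UNBOUND, "A": UNBOUND, "B1": BOUND, "B2": BOUND},
    )


def _require_canonical(scheme: KineticScheme) -> None:
    canonical = build_four_state_scheme()
    if scheme.states != canonical.states or set(scheme.transitions) != set(canonical.transitions):
        raise ValueError("expected the canonical four-state scheme")


def binding_subscheme(scheme: KineticScheme) -> KineticScheme:
    """Condense for unbound dwells: first bound state absorbing, second dropped.

    The transient block spans (U, A); accumulated B1 occupancy is the
    unbound-dwell first-passage CDF.
    """
    _require_canonical(scheme)
    return KineticScheme(
        states=("U", "A", "B1"),
        transitions=(
            Transition("U", "A", "k1"),
            Transition("A", "U", "km1"),
            Transition("A", "B1", "k2", ligand_order=1),
        ),
        observable_class={"U": UNBOUND, "A": UNBOUND, "B1": BOUND},
        absorbing=frozenset({"B1"}),
    )


def unbinding_subscheme(scheme: KineticScheme) -> KineticScheme:
    """Condense for bound dwells: competent unbound state absorbing.

    The transient block spans (B1, B2); accumulated A occupancy is the
    bound-dwell first-passage CDF.
    """
    _require_canonical(scheme)
    return KineticScheme(
        states=("B1", "B2", "A"),
        transitions=(
            Transition("B1", "B2", "k3"),
            Transition("B2", "B1", "km3"),
            Transition("B1", "A", "km2"),
        ),
        observable_class={"B1": BOUND, "B2": BOUND, "A": UNBOUND},
        absorbing=frozenset({"A"}),
    )


def rate_matrix(scheme: KineticScheme, rates: RateConstantSet, dna: float) -> np.ndarray:
    """Column-convention generator M with ``dp/dt = M @ p``.

    Off-diagonals are non-negative; for conservative schemes every column
    sums to zero, and columns of absorbing states are identically zero.
    """
    if dna < 0 or not np.isfinite(dna):
        raise ValueError(f"ligand concentration must be finite and >= 0, got {dna}")
    rd = rates.as_dict()
    n = scheme.n_states
    m = np.zeros((n, n))
    for tr in scheme.transitions:
        k = rd[tr.rate_symbol]
        if tr.ligand_order == 1:
            k = k * dna
        i, j = scheme.index(tr.target), scheme.index(tr.source)
        m[i, j] += k
        m[j, j] -= k
    return m


def stationary_distribution(
    scheme: KineticScheme, rates: RateConstantSet, dna: float
) -> np.ndarray:
    """Stationary distribution: normalized null-space vector of the generator.

    At ``dna == 0`` the bound states are unreachable from the unbound pair;
    the unique stationary vector then puts all mass on the unbound states
    (ratio ``k1/km1`` between competent and incompetent) and a warning is
    emitted for the reducible chain.
    """
    m = rate_matrix(scheme, rates, dna)
    if dna == 0 and any(tr.ligand_order == 1 for tr in scheme.transitions):
        warnings.warn(
            "scheme is reducible at zero ligand concentration; "
            "returning the distribution over reachable (unbound) states",
            stacklevel=2,
        )
    w, v = np.linalg.eig(m)
    idx = int(np.argmin(np.abs(w)))
    pi = np.real(v[:, idx])
    pi = np.abs(pi)
    total = pi.sum()
    if total <= 0:
        raise np.linalg.LinAlgError("could not normalize stationary vector")
    return pi / total


def transient_block(
    sub: KineticScheme, rates: RateConstantSet, dna: float
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Generator restricted to the non-absorbing states of a condensed scheme.

    Returns ``(Q, state_order)`` with Q in column convention; for the
    canonical condensations Q is the 2x2 block whose eigenvalues are the
    (negated) apparent dwell rates.
    """
    if not sub.absorbing:
        raise ValueError("scheme has no absorbing state; nothing to condense")
    m = rate_matrix(sub, rates, dna)
    keep = [i for i, s in enumerate(sub.states) if s not in sub.absorbing]
    order = tuple(sub.states[i] for i in keep)
    return m[np.ix_(keep, keep)], order
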