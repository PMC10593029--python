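"""Post-exposure event chains and the feasible outcome space.

After exposure to a pathogen an individual may experience a sequence of
binary events — by default infection (I), symptoms (S), diagnosis (D),
hospitalization (H), ICU admission (C), and death (M).  An *outcome* is one
binary vector over these events.  With six unconstrained events there are
2**6 = 64 outcomes; precedence constraints (e.g. no symptoms without
infection) shrink the feasible set, but not all the way down to a strict
linear chain: an individual may die without ever entering the ICU.  This
module represents the chain, its precedence relation, and enumerates the
feasible outcome vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "EventChain",
    "OutcomeVector",
    "ConstraintError",
    "ShapeError",
    "default_chain",
    "strict_chain",
    "unconstrained_chain",
    "enumerate_feasible",
    "is_feasible",
]

DEFAULT_EVENTS = ("I", "S", "D", "H", "C", "M")

#: Shipped default precedence: symptoms and diagnosis require infection,
#: hospitalization requires diagnosis, ICU requires hospitalization, and
#: death requires hospitalization only — death may skip the ICU.
DEFAULT_REQUIRES = (("I", "S"), ("I", "D"), ("D", "H"), ("H", "C"), ("H", "M"))


class ConstraintError(ValueError):
    """The precedence relation is invalid (cyclic, unknown labels, ...)."""


class ShapeError(ValueError):
    """An outcome vector does not match the chain's length."""


@dataclass(frozen=True)
class EventChain:
    """An ordered set of post-exposure events with a precedence relation.

    Parameters
    ----------
    events
        Ordered, unique event labels.  The order is also the enumeration
        order (first event is the most significant bit).
    requires
        Pairs ``(a, b)`` meaning event ``b`` can occur only if event ``a``
        occurred.  Each pair must respect the event order (``a`` before
        ``b``) and the relation must be acyclic.
    """

    events: tuple[str, ...]
    requires: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        object.__setattr__(
            self, "requires", frozenset(tuple(p) for p in self.requires)
        )
        if len(set(self.events)) != len(self.events):
            raise ConstraintError(f"event labels are not unique: {self.events}")
        known = set(self.events)
        for a, b in self.requires:
            if a not in known or b not in known:
                raise ConstraintError(f"requires pair ({a}, {b}) names unknown event")
            if a == b:
                raise ConstraintError(f"self-dependency on event {a!r}")
            if self.index(a) >= self.index(b):
                raise ConstraintError(
                    f"requires pair ({a}, {b}) contradicts chain order "
                    f"{self.events}: prerequisite must come first"
                )
        if not nx.is_directed_acyclic_graph(self.graph()):
            raise ConstraintError("requires relation is cyclic")

    # -- structure ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.events)

    def index(self, label: str) -> int:
        try:
            return self.events.index(label)
        except ValueError:
            raise ConstraintError(f"unknown event label {label!r}") from None

    def graph(self) -> "nx.DiGraph":
        g = nx.DiGraph()
        g.add_nodes_from(self.events)
        g.add_edges_from(self.requires)
        return g

    def prerequisites(self, label: str) -> set[str]:
        """Direct prerequisites of ``label``."""
        self.index(label)
        return {a for a, b in self.requires if b == label}

    def required_ancestors(self, label: str) -> set[str]:
        """All events that must equal 1 for ``label`` to occur (transitive)."""
        self.index(label)
        return set(nx.ancestors(self.graph(), label))

    def permits_without(self, event: str, ancestor: str) -> bool:
        """True if ``event`` may occur while ``ancestor`` did not."""
        return ancestor not in self.required_ancestors(event)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "events": list(self.events),
            "requires": sorted([a, b] for a, b in self.requires),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EventChain":
        return cls(tuple(d["events"]), frozenset(tuple(p) for p in d["requires"]))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "EventChain":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class OutcomeVector:
    """Binary indicator per event of a chain, in chain order."""

    values: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(int(v) for v in self.values))
        if any(v not in (0, 1) for v in self.values):
            raise ShapeError(f"outcome values must be 0/1, got {self.values}")

    def __getitem__(self, i: int) -> int:
        return self.values[i]

    def __len__(self) -> int:
        return len(self.values)

    def as_dict(self, chain: EventChain) -> dict[str, int]:
        if len(self.values) != len(chain):
            raise ShapeError(
                f"vector length {len(self.values)} != chain length {len(chain)}"
            )
        return dict(zip(chain.events, self.values))


def default_chain() -> EventChain:
    """The shipped six-event chain with the death-may-skip-ICU precedence."""
    return EventChain(DEFAULT_EVENTS, frozenset(DEFAULT_REQUIRES))


def strict_chain(events: Sequence[str] = DEFAULT_EVENTS) -> EventChain:
    """A strictly linear chain: each event requires the one before it."""
    events = tuple(events)
    return EventChain(events, frozenset(zip(events[:-1], events[1:])))


def unconstrained_chain(events: Sequence[str] = DEFAULT_EVENTS) -> EventChain:
    """A chain with no precedence constraints at all (2**n outcomes)."""
    return EventChain(tuple(events), frozenset())


def _coerce(v: OutcomeVector | Sequence[int]) -> tuple[int, ...]:
    if isinstance(v, OutcomeVector):
        return v.values
    return tuple(int(x) for x in v)


def is_feasible(v: OutcomeVector | Sequence[int], chain: EventChain) -> bool:
    """True iff ``v`` satisfies every precedence pair of the chain."""
    vals = _coerce(v)
    if len(vals) != len(chain):
        raise ShapeError(
            f"vector length {len(vals)} != chain length {len(chain)}"
        )
    idx = {e: i for i, e in enumerate(chain.events)}
    return all(vals[idx[b]] == 0 or vals[idx[a]] == 1 for a, b in chain.requires)


def enumerate_feasible(chain: EventChain) -> list[OutcomeVector]:
    """Every feasible outcome vector, in lexicographic order.

    The first event of the chain is the most significant bit, so the
    all-zeros vector comes first and the all-ones vector last.  For a
    six-event unconstrained chain this returns all 64 vectors; a strict
    linear chain returns the n+1 prefix-of-ones vectors.
    """
    out = []
    for bits in product((0, 1), repeat=len(chain)):
        if is_feasible(bits, chain):
            out.append(OutcomeVector(bits))
    return out
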