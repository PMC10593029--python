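"""Exact algebra relating marginal, joint, and conditional effectiveness.

Three vaccine-effectiveness measures appear when parameterizing an
individual-based model from post-exposure outcome data:

* ``VE_S``    — effectiveness against symptomatic infection,
* ``VE_SH``   — effectiveness against symptomatic hospitalization (the
  joint event: symptomatic infection *and* hospitalization),
* ``VE_H|S``  — effectiveness against hospitalization among the
  symptomatically infected.

Because each VE is one minus a risk ratio and the conditional risk is a
quotient of the joint and marginal risks, the three are tied by the exact
identity::

    VE_H|S = 1 - (1 - VE_SH) / (1 - VE_S)

Analogous algebra converts between a joint distribution over outcome
vectors (fates fixed at exposure) and a table of step-wise progression
probabilities (fates drawn stage by stage), and composes a symptomatic
case-fatality ratio from severity-pyramid levels, sCFR = r_M|H * r_H|S.

All VE values are proportions in (-inf, 1]; negative values represent
harm.  Percent formatting (nearest integer, half-up) happens only at the
reporting layer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .outcome_space import (
    EventChain,
    OutcomeVector,
    enumerate_feasible,
    is_feasible,
)

__all__ = [
    "UNDEFINED",
    "UndefinedQuotientError",
    "DecompositionError",
    "IncompleteTableError",
    "VEProfile",
    "JointOutcomeDistribution",
    "ProgressionTable",
    "ve_conditional",
    "ve_compose",
    "scfr_compose",
    "joint_to_conditional",
    "conditional_to_joint",
    "ve_waning_table",
    "percent",
]

_MASS_TOL = 1e-12


class UndefinedQuotientError(ZeroDivisionError):
    """VE_S = 1 leaves no unvaccinated-equivalent denominator in Eq. of VE_H|S."""


class DecompositionError(ValueError):
    """The pyramid product is not the sCFR for this chain."""


class IncompleteTableError(KeyError):
    """A reachable history is missing from a progression table."""


class _Undefined:
    """Sentinel for conditionals on zero-probability histories.

    Distinct from 0: it means "this history is never reached", not "the
    event never happens from this history".
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "UNDEFINED"


UNDEFINED = _Undefined()


# ---------------------------------------------------------------------------
# Scalar VE algebra
# ---------------------------------------------------------------------------


def ve_conditional(ve_s: float, ve_sh: float) -> float:
    """Conditional VE against hospitalization among the symptomatic.

    Returns ``1 - (1 - ve_sh) / (1 - ve_s)``.  Monotone increasing in
    ``ve_sh`` and decreasing in ``ve_s``, which is why the conditional
    measure can *rise* over time when protection against infection wanes
    faster than protection against hospitalization.

    Raises
    ------
    UndefinedQuotientError
        If ``ve_s == 1`` (no symptomatic infections among the vaccinated,
        so the conditional risk ratio has an empty denominator).
    """
    if ve_s > 1 or ve_sh > 1:
        raise ValueError(f"VE values cannot exceed 1, got ve_s={ve_s}, ve_sh={ve_sh}")
    if ve_s == 1:
        raise UndefinedQuotientError(
            "ve_s = 1: no symptomatic infections occur among the vaccinated, "
            "so VE_H|S is undefined"
        )
    return 1.0 - (1.0 - ve_sh) / (1.0 - ve_s)


def ve_compose(ve_s: float, ve_h_given_s: float) -> float:
    """Inverse of :func:`ve_conditional`: rebuild VE_SH from its factors.

    Returns ``1 - (1 - ve_s) * (1 - ve_h_given_s)``.
    """
    if ve_s > 1 or ve_h_given_s > 1:
        raise ValueError(
            f"VE values cannot exceed 1, got ve_s={ve_s}, ve_h_given_s={ve_h_given_s}"
        )
    return 1.0 - (1.0 - ve_s) * (1.0 - ve_h_given_s)


def percent(v: float) -> int:
    """Nearest-integer percent with half-up rounding (0.42857 -> 43)."""
    return int(math.floor(v * 100.0 + 0.5))


def scfr_compose(
    r_death_given_hosp: float,
    r_hosp_given_symptoms: float,
    chain: EventChain | None = None,
    death_event: str = "M",
    hosp_event: str = "H",
) -> float:
    """Symptomatic case-fatality ratio from severity-pyramid levels.

    ``sCFR = r_M|H * r_H|S``.  The product equals Pr(death | symptomatic)
    only when every death passes through hospitalization; if a ``chain``
    is supplied that permits death without hospitalization the
    decomposition is refused.
    """
    for name, r in (
        ("r_death_given_hosp", r_death_given_hosp),
        ("r_hosp_given_symptoms", r_hosp_given_symptoms),
    ):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {r}")
    if chain is not None and chain.permits_without(death_event, hosp_event):
        raise DecompositionError(
            f"chain permits {death_event}=1 with {hosp_event}=0; "
            "the pyramid product is not the sCFR"
        )
    return r_death_given_hosp * r_hosp_given_symptoms


# ---------------------------------------------------------------------------
# VE profiles / waning table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VEProfile:
    """A (VE_S, VE_SH) pair for one time-since-vaccination stratum."""

    stratum_label: str
    ve_s: float
    ve_sh: float

    def __post_init__(self) -> None:
        if self.ve_s > 1 or self.ve_sh > 1:
            raise ValueError(f"VE values cannot exceed 1: {self}")


def ve_waning_table(profiles: Sequence[VEProfile]) -> pd.DataFrame:
    """Fill VE_H|S for each stratum, preserving input order.

    Preserving order matters: the conditional measure can be non-monotone
    across strata even when both inputs wane, and the trend is the point.
    """
    rows = []
    for p in profiles:
        rows.append(
            {
                "stratum_label": p.stratum_label,
                "ve_s": p.ve_s,
                "ve_h_given_s": ve_conditional(p.ve_s, p.ve_sh),
                "ve_sh": p.ve_sh,
            }
        )
    return pd.DataFrame(rows, columns=["stratum_label", "ve_s", "ve_h_given_s", "ve_sh"])


# ---------------------------------------------------------------------------
# Joint distributions and progression tables
# ---------------------------------------------------------------------------


@dataclass
class JointOutcomeDistribution:
    """Probability mass over feasible outcome vectors of a chain.

    ``stratum`` optionally records the covariate level / vaccination arm /
    variant the distribution is conditional on; the algebra ignores it.
    """

    chain: EventChain
    mass: dict[tuple[int, ...], float]
    stratum: Mapping[str, object] | None = None

    def __post_init__(self) -> None:
        self.mass = {tuple(int(b) for b in k): float(v) for k, v in self.mass.items()}
        for vec, p in self.mass.items():
            if p < 0:
                raise ValueError(f"negative mass {p} on {vec}")
            if not is_feasible(vec, self.chain):
                raise ValueError(f"mass on infeasible vector {vec}")
        total = sum(self.mass.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"masses sum to {total}, not 1")

    def prob(self, **events: int) -> float:
        """Pr(listed events take the listed values), summing the mass."""
        idx = {e: i for i, e in enumerate(self.chain.events)}
        for e in events:
            if e not in idx:
                raise KeyError(f"unknown event {e!r}")
        return sum(
            p
            for vec, p in self.mass.items()
            if all(vec[idx[e]] == v for e, v in events.items())
        )

    def conditional(self, event: str, **given: int) -> float | _Undefined:
        denom = self.prob(**given)
        if denom == 0.0:
            return UNDEFINED
        return self.prob(**{event: 1, **given}) / denom

    # -- io ----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {**dict(zip(self.chain.events, vec)), "probability": p}
            for vec, p in sorted(self.mass.items())
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, chain: EventChain) -> "JointOutcomeDistribution":
        mass = {
            tuple(int(row[e]) for e in chain.events): float(row["probability"])
            for _, row in df.iterrows()
        }
        return cls(chain, mass)

    @classmethod
    def from_csv(cls, path, chain: EventChain) -> "JointOutcomeDistribution":
        return cls.from_frame(pd.read_csv(path), chain)

    def to_json(self) -> str:
        return json.dumps(
            {
                "chain": self.chain.to_dict(),
                "mass": [{"outcome": list(k), "probability": v} for k, v in sorted(self.mass.items())],
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "JointOutcomeDistribution":
        d = json.loads(s)
        chain = EventChain.from_dict(d["chain"])
        mass = {tuple(e["outcome"]): e["probability"] for e in d["mass"]}
        return cls(chain, mass)


def reachable_histories(chain: EventChain) -> dict[str, list[tuple[int, ...]]]:
    """For each event, the feasible realizations of all prior events."""
    feasible = [v.values for v in enumerate_feasible(chain)]
    out: dict[str, list[tuple[int, ...]]] = {}
    for i, event in enumerate(chain.events):
        out[event] = sorted({vec[:i] for vec in feasible})
    return out


def _history_feasible_for(chain: EventChain, event: str, history: tuple[int, ...]) -> bool:
    """Can ``event`` occur given this realization of the prior events?"""
    i = chain.index(event)
    idx = {e: j for j, e in enumerate(chain.events)}
    return all(history[idx[a]] == 1 for a in chain.prerequisites(event))


@dataclass
class ProgressionTable:
    """Step-wise conditional probabilities Pr(event | full prior history).

    Keys are ``(event, history)`` where ``history`` is the realized 0/1
    tuple of all events preceding ``event`` in chain order.  Entries for
    histories in which the event's prerequisites are unmet are absent (the
    probability is structurally zero); entries whose history has zero
    probability under a source joint distribution carry the UNDEFINED
    sentinel rather than a silent 0.
    """

    chain: EventChain
    entries: dict[tuple[str, tuple[int, ...]], float | _Undefined]

    def __post_init__(self) -> None:
        clean: dict[tuple[str, tuple[int, ...]], float | _Undefined] = {}
        for (event, hist), p in self.entries.items():
            key = (event, tuple(int(b) for b in hist))
            if p is not UNDEFINED:
                p = float(p)
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"entry {key} = {p} outside [0, 1]")
            clean[key] = p
        self.entries = clean

    def get(self, event: str, history: tuple[int, ...]) -> float | _Undefined:
        return self.entries[(event, tuple(history))]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (event, hist), p in sorted(self.entries.items(), key=lambda kv: (self.chain.index(kv[0][0]), kv[0][1])):
            prior = self.chain.events[: self.chain.index(event)]
            rows.append(
                {
                    "event": event,
                    "history": ";".join(f"{e}={v}" for e, v in zip(prior, hist)),
                    "probability": float("nan") if p is UNDEFINED else p,
                    "defined": p is not UNDEFINED,
                }
            )
        return pd.DataFrame(rows, columns=["event", "history", "probability", "defined"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, chain: EventChain) -> "ProgressionTable":
        entries: dict[tuple[str, tuple[int, ...]], float | _Undefined] = {}
        for _, row in df.iterrows():
            hist_str = row["history"]
            hist = tuple(
                int(item.split("=")[1]) for item in str(hist_str).split(";") if "=" in str(item)
            ) if isinstance(hist_str, str) and hist_str else ()
            defined = bool(row["defined"]) if "defined" in df.columns else not pd.isna(row["probability"])
            entries[(row["event"], hist)] = row["probability"] if defined else UNDEFINED
        return cls(chain, entries)

    @classmethod
    def from_csv(cls, path, chain: EventChain) -> "ProgressionTable":
        return cls.from_frame(pd.read_csv(path, keep_default_na=True), chain)


def joint_to_conditional(j: JointOutcomeDistribution) -> ProgressionTable:
    """Derive Pr(event | full prior history) by summing joint mass.

    Histories with zero marginal mass yield UNDEFINED entries; histories
    in which an event's prerequisites are unmet are omitted entirely.
    """
    chain = j.chain
    entries: dict[tuple[str, tuple[int, ...]], float | _Undefined] = {}
    for i, event in enumerate(chain.events):
        for hist in reachable_histories(chain)[event]:
            if not _history_feasible_for(chain, event, hist):
                continue
            denom = sum(p for vec, p in j.mass.items() if vec[:i] == hist)
            if denom == 0.0:
                entries[(event, hist)] = UNDEFINED
            else:
                num = sum(
                    p for vec, p in j.mass.items() if vec[:i] == hist and vec[i] == 1
                )
                entries[(event, hist)] = num / denom
    return ProgressionTable(chain, entries)


def conditional_to_joint(t: ProgressionTable) -> JointOutcomeDistribution:
    """Multiply conditionals along each feasible vector to rebuild the joint.

    An UNDEFINED entry is only ever consulted on paths that already carry
    zero probability, where it contributes nothing; a genuinely missing
    entry on a positive-probability path raises IncompleteTableError.
    """
    chain = t.chain
    mass: dict[tuple[int, ...], float] = {}
    for vec in enumerate_feasible(chain):
        p = 1.0
        for i, event in enumerate(chain.events):
            if p == 0.0:
                break
            hist = vec.values[:i]
            if not _history_feasible_for(chain, event, hist):
                # prerequisites unmet: event is structurally 0
                if vec[i] == 1:
                    p = 0.0
                continue
            try:
                q = t.get(event, hist)
            except KeyError:
                raise IncompleteTableError(
                    f"no entry for event {event!r} given history {hist} "
                    f"(reachable with positive probability)"
                ) from None
            if q is UNDEFINED:
                # consistent tables only carry UNDEFINED on zero-probability
                # histories, which the `p == 0` break already skipped
                raise IncompleteTableError(
                    f"entry for event {event!r} given history {hist} is "
                    "UNDEFINED but the history has positive probability"
                )
            p *= q if vec[i] == 1 else 1.0 - q
        if p > 0.0:
            mass[vec.values] = p
    return JointOutcomeDistribution(chain, mass)
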