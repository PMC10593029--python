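"""Study-design emulators: observe a simulated population the way a
real design would.

Each emulator selects and masks individuals from a freshly simulated
population and returns a :class:`StudySample` whose rows contain only
what that design can see — measured (possibly misclassified) covariates,
vaccination status, and the observed events from its ascertainment point
onward.  Counterfactual columns are never included, so downstream
estimators physically cannot peek at ground truth.

Designs:

* ``challenge_trial`` — vaccination *and* exposure both assigned; the
  ideal design, every post-exposure event observed.
* ``rct``             — vaccination randomized, exposure occurs naturally
  and is not recorded (as in real blinded trials).
* ``cohort``          — vaccination by the scenario's (possibly
  confounded) mechanism; measured covariates carried for adjustment.
* ``contact_tracing`` — exposed individuals only, with an optional
  covariate-dependent selection rule (non-exchangeable selection is
  first-class).
* ``progression_study`` — individuals ascertained at a later event
  (e.g. symptoms), observing only that event and downstream ones.
* ``severity_pyramid`` — composes level-specific conditional risks from
  separate component studies into a composite risk such as the sCFR.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .outcome_space import EventChain
from .scm import (
    ExposureMechanism,
    Population,
    ScenarioConfig,
    VaccinationMechanism,
    child_rng,
    sample_population,
)

__all__ = [
    "StudySample",
    "MaskingError",
    "EmptySampleError",
    "BlindingError",
    "CompositionError",
    "challenge_trial",
    "rct",
    "cohort",
    "contact_tracing",
    "progression_study",
    "severity_pyramid",
    "PyramidResult",
]


class MaskingError(RuntimeError):
    """A study sample would expose counterfactual columns."""


class EmptySampleError(ValueError):
    """The design's selection rule produced no rows."""


class BlindingError(ValueError):
    """The scenario violates the design's blinding premise."""


class CompositionError(ValueError):
    """Severity-pyramid components do not form a valid level sequence."""


#: Column name fragments that would leak ground truth into a study sample.
_FORBIDDEN_SUFFIXES = ("_a0", "_a1")

_MEASURED_COVARIATES = (
    "age_group",
    "age_index",
    "sex",
    "comorbidity_count",
    "prior_infection",
    "calendar_time",
)


@dataclass
class StudySample:
    """Observed records from one emulated study.

    ``rows`` carries measured covariates (``immunocompromised`` and
    ``variant`` columns are the *measured* versions), a ``vaccinated``
    column, and observed event indicators.  Potential-outcome columns are
    forbidden and their presence raises :class:`MaskingError`.
    """

    design: str
    rows: pd.DataFrame
    chain: EventChain
    ascertainment_event: str | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [
            c
            for c in self.rows.columns
            if c.endswith(_FORBIDDEN_SUFFIXES) or c == "frailty"
        ]
        if bad:
            raise MaskingError(f"counterfactual/latent columns in study rows: {bad}")

    @property
    def n(self) -> int:
        return len(self.rows)

    def to_csv(self, path) -> None:
        """Write rows as CSV with a JSON sidecar describing the design."""
        self.rows.to_csv(path, index=False)
        sidecar = {
            "design": self.design,
            "ascertainment_event": self.ascertainment_event,
            "chain": self.chain.to_dict(),
            "provenance": self.provenance,
        }
        with open(f"{path}.meta.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def from_csv(cls, path) -> "StudySample":
        with open(f"{path}.meta.json") as fh:
            sidecar = json.load(fh)
        return cls(
            design=sidecar["design"],
            rows=pd.read_csv(path),
            chain=EventChain.from_dict(sidecar["chain"]),
            ascertainment_event=sidecar.get("ascertainment_event"),
            provenance=sidecar.get("provenance", {}),
        )


def _observed_rows(
    pop: Population,
    events: Sequence[str],
    include_exposure: bool = False,
    include_variant: bool = False,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Extract design-visible rows: measured covariates + events."""
    df = pop.df if mask is None else pop.df.loc[mask]
    out = df.loc[:, list(_MEASURED_COVARIATES)].copy()
    out["immunocompromised"] = df["measured_immunocompromised"].to_numpy()
    out["vaccinated"] = df["a_observed"].to_numpy()
    if include_exposure:
        out["exposed"] = df["exposed"].to_numpy()
    if include_variant:
        out["variant"] = df["measured_variant"].to_numpy()
    for event in events:
        out[event] = df[event].to_numpy()
    return out.reset_index(drop=True)


def challenge_trial(
    cfg: ScenarioConfig, n: int, p_vacc: float = 0.5, variant: str | None = None
) -> StudySample:
    """Randomize both vaccination and exposure; observe every event.

    Everyone is exposed to a single configured ``variant`` (default: the
    scenario's first variant), vaccination is Bernoulli(``p_vacc``).
    """
    if not 0.0 < p_vacc < 1.0:
        raise ValueError(f"p_vacc must be in (0, 1), got {p_vacc}")
    variant = variant or cfg.exposure.variants[0]
    cfg2 = replace(
        cfg,
        vaccination=VaccinationMechanism.randomized(p_vacc),
        exposure=ExposureMechanism(
            p_exposure=1.0, variant_mixture=({variant: 1.0},), a_multiplier=1.0
        ),
    )
    pop = sample_population(cfg2, n)
    rows = _observed_rows(pop, cfg.chain.events, include_exposure=True, include_variant=True)
    # the challenge strain is assigned, hence known without error
    rows["variant"] = variant
    return StudySample(
        design="challenge_trial",
        rows=rows,
        chain=cfg.chain,
        provenance={"seed": cfg.seed, "n": n, "p_vacc": p_vacc, "variant": variant},
    )


def rct(cfg: ScenarioConfig, n: int, p_vacc: float = 0.5) -> StudySample:
    """Blinded placebo-controlled trial: exposure unobserved.

    Vaccination is randomized; exposure occurs through the scenario's
    natural mechanism but is *not* recorded in the rows, mirroring real
    trials where only downstream clinical events are seen.  A scenario in
    which vaccination changes exposure probability is refused — it
    violates the blinding premise the design relies on.
    """
    if cfg.exposure.a_multiplier != 1.0:
        raise BlindingError(
            f"scenario has a vaccination->exposure multiplier of "
            f"{cfg.exposure.a_multiplier}; a blinded trial presumes no direct "
            "effect of vaccination on exposure (a_multiplier = 1)"
        )
    cfg2 = replace(cfg, vaccination=VaccinationMechanism.randomized(p_vacc))
    pop = sample_population(cfg2, n)
    rows = _observed_rows(pop, cfg.chain.events)
    return StudySample(
        design="rct",
        rows=rows,
        chain=cfg.chain,
        provenance={"seed": cfg.seed, "n": n, "p_vacc": p_vacc},
    )


def cohort(cfg: ScenarioConfig, n: int) -> StudySample:
    """Observational cohort: vaccination by the scenario's own mechanism.

    Rows carry measured covariates so exchangeability-restoring
    stratification can be attempted downstream.
    """
    pop = sample_population(cfg, n)
    rows = _observed_rows(pop, cfg.chain.events)
    return StudySample(
        design="cohort",
        rows=rows,
        chain=cfg.chain,
        provenance={"seed": cfg.seed, "n": n, "vaccination": cfg.vaccination.kind},
    )


def contact_tracing(
    cfg: ScenarioConfig,
    n: int,
    selection_rule: Callable[[pd.DataFrame], np.ndarray] | None = None,
) -> StudySample:
    """Follow exposed contacts of known cases.

    ``selection_rule`` maps the design-visible rows of the exposed
    population to non-negative selection weights (any scale); inclusion
    is Bernoulli with probability proportional to the weight, so
    covariate-dependent, non-exchangeable selection is expressible.
    """
    pop = sample_population(cfg, n)
    exposed = pop.exposed_mask()
    if not exposed.any():
        raise EmptySampleError("no exposed individuals in the scenario")
    rows = _observed_rows(
        pop, cfg.chain.events, include_exposure=True, include_variant=True, mask=exposed
    )
    if selection_rule is not None:
        w = np.asarray(selection_rule(rows), dtype=float)
        if w.shape != (len(rows),) or (w < 0).any():
            raise ValueError("selection_rule must return non-negative weights, one per row")
        if w.max() <= 0:
            raise EmptySampleError("selection rule assigned zero weight to every contact")
        keep = child_rng(cfg.seed, "selection").random(len(rows)) < w / w.max()
        rows = rows.loc[keep].reset_index(drop=True)
        if rows.empty:
            raise EmptySampleError("selection rule removed every contact")
    return StudySample(
        design="contact_tracing",
        rows=rows,
        chain=cfg.chain,
        provenance={
            "seed": cfg.seed,
            "n": n,
            "selection": "uniform" if selection_rule is None else "weighted",
        },
    )


def progression_study(cfg: ScenarioConfig, n: int, ascertainment_event: str) -> StudySample:
    """Ascertain individuals at a post-exposure event (e.g. symptoms) and
    observe that event plus downstream ones.

    Rows are individuals with the ascertainment event observed; covariates
    are the measured (possibly misclassified) versions, because this is
    the design in which residual confounding from mismeasured variant or
    immunocompromised status matters most.
    """
    idx = cfg.chain.index(ascertainment_event)  # validates the label
    pop = sample_population(cfg, n)
    mask = pop.df[ascertainment_event].to_numpy(bool)
    if not mask.any():
        raise EmptySampleError(
            f"no individuals experienced ascertainment event {ascertainment_event!r}"
        )
    events = cfg.chain.events[idx:]
    rows = _observed_rows(pop, events, include_variant=True, mask=mask)
    return StudySample(
        design="progression_study",
        rows=rows,
        chain=cfg.chain,
        ascertainment_event=ascertainment_event,
        provenance={"seed": cfg.seed, "n": n},
    )


@dataclass
class PyramidResult:
    """Composite conditional-risk table from a severity pyramid."""

    levels: pd.DataFrame  # columns: from_event, to_event, risk, n, design, provenance
    product: float
    label: str

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PyramidResult({self.label} = {self.product:.4g})\n{self.levels}"


def severity_pyramid(
    components: Sequence[StudySample],
    chain: EventChain,
    levels: Sequence[tuple[str, str]],
) -> PyramidResult:
    """Synthesize per-level conditional risks into a composite risk.

    ``levels`` is an ordered list of ``(from_event, to_event)`` pairs that
    must chain (each ``to`` is the next ``from``); each pair is estimated
    from the component ascertained at its ``from`` event.  The product is
    the implied composite risk (e.g. ``sCFR = r_M|H * r_H|S`` for levels
    ``[("S","H"), ("H","M")]``), which equals the directly estimated
    composite risk only if individuals clearing one level in one study are
    exchangeable with those entering the next level in another.
    """
    from .estimators import progression_risk

    if not levels:
        raise CompositionError("no levels supplied")
    for (a, b), (c, _) in zip(levels[:-1], levels[1:]):
        if b != c:
            raise CompositionError(
                f"levels do not chain: ({a}->{b}) followed by ({c}->...)"
            )
    by_event: dict[str, StudySample] = {}
    for comp in components:
        if comp.ascertainment_event is None:
            raise CompositionError(
                f"component {comp.design!r} has no ascertainment event"
            )
        if comp.ascertainment_event in by_event:
            raise CompositionError(
                f"two components ascertain at {comp.ascertainment_event!r}"
            )
        by_event[comp.ascertainment_event] = comp
    missing = [a for a, _ in levels if a not in by_event]
    if missing:
        raise CompositionError(f"no component ascertains at level(s) {missing}")

    rows = []
    product = 1.0
    for a, b in levels:
        comp = by_event[a]
        est = progression_risk(comp, a, b)
        product *= est.estimate
        rows.append(
            {
                "from_event": a,
                "to_event": b,
                "risk": est.estimate,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "n": est.n_effective,
                "design": comp.design,
                "provenance": json.dumps(comp.provenance),
            }
        )
    label = f"r_{levels[-1][1]}|{levels[0][0]}"
    return PyramidResult(levels=pd.DataFrame(rows), product=product, label=label)
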