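"""Structural-causal-model simulator for post-exposure outcomes.

Generates synthetic populations in which every individual carries
*both* potential outcome vectors — the post-exposure fate they would have
under vaccination and under no vaccination — so that every causal
estimand (VE against symptomatic infection, against symptomatic
hospitalization, the conditional VE among the symptomatic, per-stratum
risks) has a computable ground truth to benchmark study designs against.

The data-generating process follows a DAG in which baseline covariates
(age, calendar time, variant mixture, immunocompromised status, prior
infection, comorbidities) may influence vaccination, exposure, and each
post-exposure event; vaccination may optionally influence exposure (a
behavioral pathway that a blinded trial excludes).  Per-event risks are
multiplicative: a baseline conditional probability per event times
covariate, variant, vaccination, and frailty factors, clipped to [0, 1]
with a logged counter.  Event draws use common random numbers across the
two vaccination arms — one uniform per (individual, event) — so an
individual's potential outcomes are well defined and arm contrasts are
not inflated by independent noise.

Transmission dynamics are intentionally replaced by a single binary
exposure contact with a variant drawn from the calendar-period mixture:
the estimation questions studied here concern post-exposure fates, not
epidemic curves.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .outcome_space import EventChain, OutcomeVector, default_chain, is_feasible
from .param_algebra import UNDEFINED, ve_compose, ve_conditional

__all__ = [
    "CovariateLaws",
    "VaccinationMechanism",
    "ExposureMechanism",
    "RiskModel",
    "Misclassification",
    "ScenarioConfig",
    "ScenarioValidationError",
    "Population",
    "SimulatedIndividual",
    "sample_population",
    "true_estimands",
    "apply_misclassification",
]

logger = logging.getLogger(__name__)

# Fixed child-stream labels: adding a stream never perturbs the others.
_STREAMS = {
    "covariates": 0,
    "vaccination": 1,
    "exposure": 2,
    "frailty": 3,
    "events": 4,
    "misclassification": 5,
    "selection": 6,
}


def child_rng(seed: int, stream: str, *extra: int) -> np.random.Generator:
    """Derive a named child generator from the scenario root seed."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream], *extra))
    )


class ScenarioValidationError(ValueError):
    """Raised with the full list of offending fields."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("invalid scenario config:\n  - " + "\n  - ".join(problems))


# ---------------------------------------------------------------------------
# Configuration blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CovariateLaws:
    """Sampling laws for the baseline covariate vector L."""

    age_groups: tuple[str, ...] = ("0-17", "18-49", "50-64", "65+")
    age_probs: tuple[float, ...] = (0.20, 0.40, 0.25, 0.15)
    sex_levels: tuple[str, ...] = ("F", "M")
    sex_probs: tuple[float, ...] = (0.5, 0.5)
    comorbidity_mean: float = 0.8  # Poisson mean for comorbidity count
    prior_infection_prob: float = 0.3
    immunocompromised_prob: float = 0.05
    n_periods: int = 4
    period_probs: tuple[float, ...] | None = None  # default: uniform

    def problems(self) -> list[str]:
        out = []
        for name, levels, probs in (
            ("age", self.age_groups, self.age_probs),
            ("sex", self.sex_levels, self.sex_probs),
        ):
            if len(levels) != len(probs):
                out.append(f"covariate_laws.{name}: {len(levels)} levels vs {len(probs)} probs")
            elif abs(sum(probs) - 1.0) > 1e-9:
                out.append(f"covariate_laws.{name}_probs sum to {sum(probs)}, not 1")
        if self.comorbidity_mean < 0:
            out.append(f"covariate_laws.comorbidity_mean = {self.comorbidity_mean} < 0")
        for name in ("prior_infection_prob", "immunocompromised_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                out.append(f"covariate_laws.{name} = {v} outside [0, 1]")
        if self.n_periods < 1:
            out.append(f"covariate_laws.n_periods = {self.n_periods} < 1")
        if self.period_probs is not None:
            if len(self.period_probs) != self.n_periods:
                out.append("covariate_laws.period_probs length != n_periods")
            elif abs(sum(self.period_probs) - 1.0) > 1e-9:
                out.append("covariate_laws.period_probs do not sum to 1")
        return out


@dataclass(frozen=True)
class VaccinationMechanism:
    """Randomized (Bernoulli p) or confounded (logistic in covariates).

    Confounded coefficients act on the log-odds scale; supported feature
    names: ``age_index``, ``comorbidity_count``, ``prior_infection``,
    ``immunocompromised``, ``calendar_time``, ``sex_male``.
    """

    kind: str = "randomized"
    p: float = 0.5
    intercept: float = 0.0
    coefficients: Mapping[str, float] = field(default_factory=dict)

    FEATURES = (
        "age_index",
        "comorbidity_count",
        "prior_infection",
        "immunocompromised",
        "calendar_time",
        "sex_male",
    )

    @classmethod
    def randomized(cls, p: float = 0.5) -> "VaccinationMechanism":
        return cls(kind="randomized", p=p)

    @classmethod
    def confounded(cls, intercept: float = 0.0, **coefficients: float) -> "VaccinationMechanism":
        return cls(kind="confounded", intercept=intercept, coefficients=dict(coefficients))

    def problems(self) -> list[str]:
        out = []
        if self.kind not in ("randomized", "confounded"):
            out.append(f"vaccination.kind = {self.kind!r}, expected randomized|confounded")
        if self.kind == "randomized" and not 0.0 <= self.p <= 1.0:
            out.append(f"vaccination.p = {self.p} outside [0, 1]")
        for k in self.coefficients:
            if k not in self.FEATURES:
                out.append(
                    f"vaccination.coefficients names unknown feature {k!r} "
                    f"(known: {', '.join(self.FEATURES)})"
                )
        return out


@dataclass(frozen=True)
class ExposureMechanism:
    """A single binary exposure contact with a period-specific variant mix.

    ``a_multiplier`` is the multiplicative effect of vaccination on the
    exposure probability (risk-tolerance / behavioral pathway); 1.0 means
    no direct effect, the blinded-trial premise.
    """

    p_exposure: float = 0.5
    variant_mixture: tuple[Mapping[str, float], ...] = ({"wildtype": 1.0},)
    a_multiplier: float = 1.0

    def mixture_for_period(self, t: int, n_periods: int) -> Mapping[str, float]:
        if len(self.variant_mixture) == 1:
            return self.variant_mixture[0]
        return self.variant_mixture[t]

    @property
    def variants(self) -> tuple[str, ...]:
        names: list[str] = []
        for mix in self.variant_mixture:
            for v in mix:
                if v not in names:
                    names.append(v)
        return tuple(names)

    def problems(self, n_periods: int) -> list[str]:
        out = []
        if not 0.0 <= self.p_exposure <= 1.0:
            out.append(f"exposure.p_exposure = {self.p_exposure} outside [0, 1]")
        if self.a_multiplier < 0:
            out.append(f"exposure.a_multiplier = {self.a_multiplier} < 0")
        if len(self.variant_mixture) not in (1, n_periods):
            out.append(
                f"exposure.variant_mixture has {len(self.variant_mixture)} entries; "
                f"expected 1 or n_periods={n_periods}"
            )
        for t, mix in enumerate(self.variant_mixture):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                out.append(f"exposure.variant_mixture[{t}] sums to {sum(mix.values())}, not 1")
            if any(p < 0 for p in mix.values()):
                out.append(f"exposure.variant_mixture[{t}] has negative probabilities")
        return out


@dataclass(frozen=True)
class RiskModel:
    """Per-event baseline conditional probability and multiplicative factors.

    ``baseline[event]`` is the probability of the event given its
    prerequisites are met (and exposure, for the infection event), for an
    unvaccinated reference individual.  Factors missing for an event
    default to 1.  ``age[event]`` is one multiplier per age group.
    """

    baseline: Mapping[str, float]
    vaccine: Mapping[str, float] = field(default_factory=dict)
    immunocompromised: Mapping[str, float] = field(default_factory=dict)
    prior_infection: Mapping[str, float] = field(default_factory=dict)
    age: Mapping[str, Sequence[float]] = field(default_factory=dict)
    variant: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def problems(self, chain: EventChain, n_age_groups: int, variants: Sequence[str]) -> list[str]:
        out = []
        for ev in chain.events:
            if ev not in self.baseline:
                out.append(f"risk.baseline missing event {ev!r}")
            elif not 0.0 <= self.baseline[ev] <= 1.0:
                out.append(f"risk.baseline[{ev}] = {self.baseline[ev]} outside [0, 1]")
        for name in ("baseline", "vaccine", "immunocompromised", "prior_infection", "age"):
            for ev in getattr(self, name):
                if ev not in chain.events:
                    out.append(f"risk.{name} names unknown event {ev!r}")
        for ev, mults in self.age.items():
            if len(mults) != n_age_groups:
                out.append(
                    f"risk.age[{ev}] has {len(mults)} multipliers for {n_age_groups} age groups"
                )
        for var, evmap in self.variant.items():
            if var not in variants:
                out.append(f"risk.variant names unknown variant {var!r}")
            for ev in evmap:
                if ev not in chain.events:
                    out.append(f"risk.variant[{var}] names unknown event {ev!r}")
        for name in ("vaccine", "immunocompromised", "prior_infection"):
            for ev, m in getattr(self, name).items():
                if m < 0:
                    out.append(f"risk.{name}[{ev}] = {m} < 0")
        return out


@dataclass(frozen=True)
class Misclassification:
    """Sensitivity/specificity of the measured variant call and of
    measured immunocompromised status.

    The variant call is a binary proxy (e.g. S-gene target failure):
    ``positive_variant`` names the variant the proxy detects.  Perfect
    values (the default) leave measured fields equal to truth.
    """

    variant_sensitivity: float = 1.0
    variant_specificity: float = 1.0
    immunocompromised_sensitivity: float = 1.0
    immunocompromised_specificity: float = 1.0
    positive_variant: str | None = None

    @property
    def is_perfect(self) -> bool:
        return (
            self.variant_sensitivity == 1.0
            and self.variant_specificity == 1.0
            and self.immunocompromised_sensitivity == 1.0
            and self.immunocompromised_specificity == 1.0
        )

    def problems(self, variants: Sequence[str]) -> list[str]:
        out = []
        for name in (
            "variant_sensitivity",
            "variant_specificity",
            "immunocompromised_sensitivity",
            "immunocompromised_specificity",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                out.append(f"misclassification.{name} = {v} outside [0, 1]")
        variant_imperfect = (
            self.variant_sensitivity != 1.0 or self.variant_specificity != 1.0
        )
        if variant_imperfect:
            if self.positive_variant is None:
                out.append(
                    "misclassification: variant sensitivity/specificity set but "
                    "positive_variant is None"
                )
            elif self.positive_variant not in variants:
                out.append(
                    f"misclassification.positive_variant {self.positive_variant!r} "
                    f"not among scenario variants {tuple(variants)}"
                )
            elif len(variants) != 2:
                out.append(
                    "misclassification of the variant call requires exactly two "
                    f"variants in the scenario, found {tuple(variants)}"
                )
        return out


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of the data-generating process."""

    chain: EventChain = field(default_factory=default_chain)
    covariate_laws: CovariateLaws = field(default_factory=CovariateLaws)
    vaccination: VaccinationMechanism = field(default_factory=VaccinationMechanism)
    exposure: ExposureMechanism = field(default_factory=ExposureMechanism)
    risk: RiskModel = field(default_factory=lambda: RiskModel(baseline={e: 0.0 for e in default_chain().events}))
    frailty_sd: float = 0.0
    misclassification: Misclassification = field(default_factory=Misclassification)
    seed: int = 0

    def validate(self) -> None:
        problems: list[str] = []
        problems += self.covariate_laws.problems()
        problems += self.vaccination.problems()
        problems += self.exposure.problems(self.covariate_laws.n_periods)
        problems += self.risk.problems(
            self.chain, len(self.covariate_laws.age_groups), self.exposure.variants
        )
        problems += self.misclassification.problems(self.exposure.variants)
        if self.frailty_sd < 0:
            problems.append(f"frailty_sd = {self.frailty_sd} < 0")
        first = self.chain.events[0]
        for ev in self.chain.events[1:]:
            if first not in self.chain.required_ancestors(ev):
                problems.append(
                    f"chain: event {ev!r} does not require {first!r}; the first "
                    "event (infection) must be ancestral to every other event"
                )
        if problems:
            raise ScenarioValidationError(problems)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        def block(obj):
            d = dataclasses.asdict(obj)
            for k, v in d.items():
                if isinstance(v, tuple):
                    d[k] = list(v)
            return d

        d = {
            "chain": self.chain.to_dict(),
            "covariate_laws": block(self.covariate_laws),
            "vaccination": block(self.vaccination),
            "exposure": {
                "p_exposure": self.exposure.p_exposure,
                "variant_mixture": [dict(m) for m in self.exposure.variant_mixture],
                "a_multiplier": self.exposure.a_multiplier,
            },
            "risk": {
                "baseline": dict(self.risk.baseline),
                "vaccine": dict(self.risk.vaccine),
                "immunocompromised": dict(self.risk.immunocompromised),
                "prior_infection": dict(self.risk.prior_infection),
                "age": {k: list(v) for k, v in self.risk.age.items()},
                "variant": {k: dict(v) for k, v in self.risk.variant.items()},
            },
            "frailty_sd": self.frailty_sd,
            "misclassification": block(self.misclassification),
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        def tup(seq):
            return tuple(seq)

        cl = d.get("covariate_laws", {})
        cov = CovariateLaws(
            age_groups=tup(cl.get("age_groups", CovariateLaws.age_groups)),
            age_probs=tup(cl.get("age_probs", CovariateLaws.age_probs)),
            sex_levels=tup(cl.get("sex_levels", CovariateLaws.sex_levels)),
            sex_probs=tup(cl.get("sex_probs", CovariateLaws.sex_probs)),
            comorbidity_mean=cl.get("comorbidity_mean", CovariateLaws.comorbidity_mean),
            prior_infection_prob=cl.get("prior_infection_prob", CovariateLaws.prior_infection_prob),
            immunocompromised_prob=cl.get("immunocompromised_prob", CovariateLaws.immunocompromised_prob),
            n_periods=cl.get("n_periods", CovariateLaws.n_periods),
            period_probs=tup(cl["period_probs"]) if cl.get("period_probs") else None,
        )
        vm = d.get("vaccination", {})
        vac = VaccinationMechanism(
            kind=vm.get("kind", "randomized"),
            p=vm.get("p", 0.5),
            intercept=vm.get("intercept", 0.0),
            coefficients=dict(vm.get("coefficients", {})),
        )
        em = d.get("exposure", {})
        exp_ = ExposureMechanism(
            p_exposure=em.get("p_exposure", 0.5),
            variant_mixture=tuple(dict(m) for m in em.get("variant_mixture", [{"wildtype": 1.0}])),
            a_multiplier=em.get("a_multiplier", 1.0),
        )
        rk = d.get("risk", {})
        risk = RiskModel(
            baseline=dict(rk.get("baseline", {})),
            vaccine=dict(rk.get("vaccine", {})),
            immunocompromised=dict(rk.get("immunocompromised", {})),
            prior_infection=dict(rk.get("prior_infection", {})),
            age={k: tuple(v) for k, v in rk.get("age", {}).items()},
            variant={k: dict(v) for k, v in rk.get("variant", {}).items()},
        )
        mc = d.get("misclassification", {})
        mis = Misclassification(
            variant_sensitivity=mc.get("variant_sensitivity", 1.0),
            variant_specificity=mc.get("variant_specificity", 1.0),
            immunocompromised_sensitivity=mc.get("immunocompromised_sensitivity", 1.0),
            immunocompromised_specificity=mc.get("immunocompromised_specificity", 1.0),
            positive_variant=mc.get("positive_variant"),
        )
        return cls(
            chain=EventChain.from_dict(d["chain"]) if "chain" in d else default_chain(),
            covariate_laws=cov,
            vaccination=vac,
            exposure=exp_,
            risk=risk,
            frailty_sd=d.get("frailty_sd", 0.0),
            misclassification=mis,
            seed=d.get("seed", 0),
        )

    def to_yaml(self, path=None) -> str:
        s = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_yaml(cls, source) -> "ScenarioConfig":
        import os

        if hasattr(source, "read"):
            d = yaml.safe_load(source.read())
        elif isinstance(source, (str, os.PathLike)) and os.path.exists(source):
            with open(source) as fh:
                d = yaml.safe_load(fh)
        else:
            d = yaml.safe_load(str(source))
        return cls.from_dict(d)


# ---------------------------------------------------------------------------
# Population container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulatedIndividual:
    """Per-individual view of one simulated row."""

    covariates: dict
    frailty: float
    a_observed: int
    exposed: int
    variant: str | None
    outcome_a0: OutcomeVector
    outcome_a1: OutcomeVector
    outcome_observed: OutcomeVector
    measured_variant: str | None
    measured_immunocompromised: int


_COVARIATE_COLS = (
    "age_group",
    "age_index",
    "sex",
    "comorbidity_count",
    "prior_infection",
    "immunocompromised",
    "calendar_time",
)


class Population:
    """A simulated population: a DataFrame plus scenario bookkeeping.

    Columns: covariates, ``frailty``, ``a_observed``, per-arm exposure
    indicators ``exposed_a0``/``exposed_a1``, observed ``exposed`` and
    ``variant``, potential outcomes ``{event}_a0``/``{event}_a1``,
    observed events ``{event}``, and measured (possibly misclassified)
    ``measured_variant`` / ``measured_immunocompromised``.
    """

    def __init__(self, df: pd.DataFrame, cfg: ScenarioConfig, clip_count: int = 0):
        self.df = df
        self.cfg = cfg
        self.chain = cfg.chain
        self.clip_count = clip_count

    @property
    def n(self) -> int:
        return len(self.df)

    def exposed_mask(self, arm: int | None = None) -> np.ndarray:
        if arm is None:
            return self.df["exposed"].to_numpy(bool)
        return self.df[f"exposed_a{arm}"].to_numpy(bool)

    def outcome_columns(self, arm: int | None = None) -> list[str]:
        if arm is None:
            return list(self.chain.events)
        return [f"{e}_a{arm}" for e in self.chain.events]

    def individuals(self) -> Iterator[SimulatedIndividual]:
        events = self.chain.events
        for _, row in self.df.iterrows():
            yield SimulatedIndividual(
                covariates={c: row[c] for c in _COVARIATE_COLS},
                frailty=float(row["frailty"]),
                a_observed=int(row["a_observed"]),
                exposed=int(row["exposed"]),
                variant=row["variant"] if row["exposed"] else None,
                outcome_a0=OutcomeVector(tuple(int(row[f"{e}_a0"]) for e in events)),
                outcome_a1=OutcomeVector(tuple(int(row[f"{e}_a1"]) for e in events)),
                outcome_observed=OutcomeVector(tuple(int(row[e]) for e in events)),
                measured_variant=row["measured_variant"] if row["exposed"] else None,
                measured_immunocompromised=int(row["measured_immunocompromised"]),
            )

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _draw_covariates(cfg: ScenarioConfig, n: int) -> pd.DataFrame:
    rng = child_rng(cfg.seed, "covariates")
    laws = cfg.covariate_laws
    age_idx = rng.choice(len(laws.age_groups), size=n, p=laws.age_probs)
    sex = rng.choice(laws.sex_levels, size=n, p=laws.sex_probs)
    comorb = rng.poisson(laws.comorbidity_mean, size=n)
    prior = (rng.random(n) < laws.prior_infection_prob).astype(int)
    immuno = (rng.random(n) < laws.immunocompromised_prob).astype(int)
    if laws.period_probs is not None:
        period = rng.choice(laws.n_periods, size=n, p=laws.period_probs)
    else:
        period = rng.integers(0, laws.n_periods, size=n)
    return pd.DataFrame(
        {
            "age_group": np.asarray(laws.age_groups)[age_idx],
            "age_index": age_idx,
            "sex": sex,
            "comorbidity_count": comorb,
            "prior_infection": prior,
            "immunocompromised": immuno,
            "calendar_time": period,
        }
    )


def _vaccination_probability(cfg: ScenarioConfig, cov: pd.DataFrame) -> np.ndarray:
    mech = cfg.vaccination
    if mech.kind == "randomized":
        return np.full(len(cov), mech.p)
    feats = {
        "age_index": cov["age_index"].to_numpy(float),
        "comorbidity_count": cov["comorbidity_count"].to_numpy(float),
        "prior_infection": cov["prior_infection"].to_numpy(float),
        "immunocompromised": cov["immunocompromised"].to_numpy(float),
        "calendar_time": cov["calendar_time"].to_numpy(float),
        "sex_male": (cov["sex"].to_numpy() == "M").astype(float),
    }
    eta = np.full(len(cov), float(mech.intercept))
    for name, coef in mech.coefficients.items():
        eta += coef * feats[name]
    return 1.0 / (1.0 + np.exp(-eta))


def _draw_variants(cfg: ScenarioConfig, period: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    variants = cfg.exposure.variants
    n = len(period)
    u = rng.random(n)
    out = np.empty(n, dtype=object)
    for t in range(cfg.covariate_laws.n_periods):
        mix = cfg.exposure.mixture_for_period(t, cfg.covariate_laws.n_periods)
        names = list(mix)
        cum = np.cumsum([mix[v] for v in names])
        sel = period == t
        if not sel.any():
            continue
        idx = np.searchsorted(cum, u[sel], side="right")
        idx = np.minimum(idx, len(names) - 1)
        out[sel] = np.asarray(names, dtype=object)[idx]
    return out


def _event_multiplier(
    cfg: ScenarioConfig,
    event: str,
    cov: pd.DataFrame,
    variant: np.ndarray,
    frailty: np.ndarray,
) -> np.ndarray:
    """Covariate/variant/frailty multiplier for one event (vaccine excluded)."""
    risk = cfg.risk
    m = np.full(len(cov), risk.baseline[event])
    if event in risk.age:
        m *= np.asarray(risk.age[event])[cov["age_index"].to_numpy()]
    if event in risk.immunocompromised:
        m *= np.where(cov["immunocompromised"].to_numpy() == 1, risk.immunocompromised[event], 1.0)
    if event in risk.prior_infection:
        m *= np.where(cov["prior_infection"].to_numpy() == 1, risk.prior_infection[event], 1.0)
    if risk.variant:
        vmult = np.ones(len(cov))
        for var, evmap in risk.variant.items():
            if event in evmap:
                vmult = np.where(variant == var, evmap[event], vmult)
        m *= vmult
    return m * frailty


def sample_population(cfg: ScenarioConfig, n: int) -> Population:
    """Simulate ``n`` individuals; deterministic given ``(cfg.seed, n)``.

    Both potential-outcome vectors are generated with common random
    numbers (one uniform per individual and event, reused across arms).
    Misclassification of measured fields, if configured, is applied via
    :func:`apply_misclassification` before returning.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    cfg.validate()
    chain = cfg.chain
    cov = _draw_covariates(cfg, n)

    p_vacc = _vaccination_probability(cfg, cov)
    a_obs = (child_rng(cfg.seed, "vaccination").random(n) < p_vacc).astype(int)

    # Exposure: shared uniform across arms; vaccination may scale the
    # probability (behavioral pathway), so the two arms can differ.
    exp_rng = child_rng(cfg.seed, "exposure")
    u_exp = exp_rng.random(n)
    clip_count = 0
    p_e0 = np.full(n, cfg.exposure.p_exposure)
    p_e1 = p_e0 * cfg.exposure.a_multiplier
    clip_count += int((p_e1 > 1.0).sum())
    p_e1 = np.clip(p_e1, 0.0, 1.0)
    exposed = {0: u_exp < p_e0, 1: u_exp < p_e1}
    variant = _draw_variants(cfg, cov["calendar_time"].to_numpy(), exp_rng)

    if cfg.frailty_sd > 0:
        z = np.clip(child_rng(cfg.seed, "frailty").standard_normal(n), -3.0, 3.0)
        frailty = np.exp(cfg.frailty_sd * z - 0.5 * cfg.frailty_sd**2)
    else:
        frailty = np.ones(n)

    u_events = child_rng(cfg.seed, "events").random((n, len(chain)))
    outcomes: dict[int, dict[str, np.ndarray]] = {0: {}, 1: {}}
    for arm in (0, 1):
        occurred = outcomes[arm]
        for i, event in enumerate(chain.events):
            base = _event_multiplier(cfg, event, cov, variant, frailty)
            if arm == 1:
                base = base * cfg.risk.vaccine.get(event, 1.0)
            clip_count += int((base > 1.0).sum())
            p = np.clip(base, 0.0, 1.0)
            prereq = exposed[arm].copy()
            for req in chain.prerequisites(event):
                prereq &= occurred[req].astype(bool)
            occurred[event] = (prereq & (u_events[:, i] < p)).astype(int)

    if clip_count:
        logger.warning("multiplicative risk clipped to [0, 1] %d times", clip_count)

    df = cov.copy()
    df["frailty"] = frailty
    df["a_observed"] = a_obs
    df["exposed_a0"] = exposed[0].astype(int)
    df["exposed_a1"] = exposed[1].astype(int)
    obs_exposed = np.where(a_obs == 1, exposed[1], exposed[0]).astype(int)
    df["exposed"] = obs_exposed
    df["variant"] = np.where(obs_exposed == 1, variant, None)
    for arm in (0, 1):
        for event in chain.events:
            df[f"{event}_a{arm}"] = outcomes[arm][event]
    for event in chain.events:
        df[event] = np.where(a_obs == 1, outcomes[1][event], outcomes[0][event])
    df["measured_variant"] = df["variant"]
    df["measured_immunocompromised"] = df["immunocompromised"]

    pop = Population(df, cfg, clip_count)
    if not cfg.misclassification.is_perfect:
        pop = apply_misclassification(pop, cfg)
    return pop


def apply_misclassification(pop: Population, cfg: ScenarioConfig) -> Population:
    """Flip measured variant / immunocompromised fields per sens/spec.

    True fields are untouched; deterministic given the scenario seed.
    Returns a new Population.
    """
    mis = cfg.misclassification
    df = pop.df.copy()
    rng = child_rng(cfg.seed, "misclassification")
    n = len(df)

    # immunocompromised: measured = 1 w.p. sensitivity if truly 1,
    # w.p. (1 - specificity) if truly 0
    u = rng.random(n)
    truth = df["immunocompromised"].to_numpy()
    p_pos = np.where(truth == 1, mis.immunocompromised_sensitivity, 1.0 - mis.immunocompromised_specificity)
    df["measured_immunocompromised"] = (u < p_pos).astype(int)

    # variant call (binary proxy between exactly two variants)
    u2 = rng.random(n)
    if mis.positive_variant is not None and (
        mis.variant_sensitivity != 1.0 or mis.variant_specificity != 1.0
    ):
        variants = cfg.exposure.variants
        other = next(v for v in variants if v != mis.positive_variant)
        true_var = df["variant"].to_numpy(object)
        is_pos = true_var == mis.positive_variant
        call_pos = np.where(is_pos, u2 < mis.variant_sensitivity, u2 < 1.0 - mis.variant_specificity)
        measured = np.where(call_pos, mis.positive_variant, other).astype(object)
        measured[df["exposed"].to_numpy() == 0] = None
        df["measured_variant"] = measured
    else:
        df["measured_variant"] = df["variant"]

    return Population(df, cfg, pop.clip_count)


# ---------------------------------------------------------------------------
# Ground-truth estimands
# ---------------------------------------------------------------------------


def true_estimands(
    cfg: ScenarioConfig,
    n: int,
    symptomatic_event: str = "S",
    hospital_event: str = "H",
    pop: Population | None = None,
) -> dict:
    """Causal quantities from potential outcomes; deterministic given seed.

    Computes, among individuals exposed under each arm: per-event risks
    under both vaccination assignments, marginal VE per event, VE against
    the joint symptomatic-hospitalization event (``VE_SH``), and the
    conditional ``VE_H|S`` implied by the exact identity
    ``1 - (1 - VE_SH) / (1 - VE_S)``.  Per-age-stratum VEs are included
    under keys like ``VE_S|65+``.
    """
    if pop is None:
        pop = sample_population(cfg, n)
    chain = pop.chain
    df = pop.df
    out: dict[str, float] = {}

    def risks(mask_cols: pd.DataFrame) -> dict[str, dict[int, float]]:
        r: dict[str, dict[int, float]] = {}
        for arm in (0, 1):
            exposed = mask_cols[f"exposed_a{arm}"].to_numpy(bool)
            denom = exposed.sum()
            for event in chain.events:
                r.setdefault(event, {})[arm] = (
                    float(mask_cols.loc[exposed, f"{event}_a{arm}"].mean()) if denom else float("nan")
                )
            joint = (
                mask_cols[f"{symptomatic_event}_a{arm}"].to_numpy(bool)
                & mask_cols[f"{hospital_event}_a{arm}"].to_numpy(bool)
            )
            r.setdefault("_joint_sh", {})[arm] = (
                float(joint[exposed].mean()) if denom else float("nan")
            )
        return r

    def fill(prefix: str, sub: pd.DataFrame) -> None:
        r = risks(sub)
        for event in chain.events:
            out[f"{prefix}risk[{event}]|A=0"] = r[event][0]
            out[f"{prefix}risk[{event}]|A=1"] = r[event][1]
            if r[event][0] and r[event][0] > 0:
                out[f"{prefix}VE[{event}]"] = 1.0 - r[event][1] / r[event][0]
        out[f"{prefix}risk[SH]|A=0"] = r["_joint_sh"][0]
        out[f"{prefix}risk[SH]|A=1"] = r["_joint_sh"][1]
        ve_s = out.get(f"{prefix}VE[{symptomatic_event}]")
        if r["_joint_sh"][0] and r["_joint_sh"][0] > 0:
            ve_sh = 1.0 - r["_joint_sh"][1] / r["_joint_sh"][0]
            out[f"{prefix}VE_SH"] = ve_sh
            if ve_s is not None and ve_s < 1:
                out[f"{prefix}VE_H|S"] = ve_conditional(ve_s, ve_sh)
        if ve_s is not None:
            out[f"{prefix}VE_S"] = ve_s

    fill("", df)
    for group in cfg.covariate_laws.age_groups:
        sub = df[df["age_group"] == group]
        if len(sub):
            fill(f"age={group}:", sub)
    return out
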