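"""Canonical scenario configurations shipped with the package.

These define the study conditions used throughout the test-bench
experiments: a null scenario (vaccine does nothing), an effect scenario
with realistic multiplicative protection, an age-confounded cohort
scenario, a frailty-plus-misclassification scenario, and the collider
scenario in which immunocompromised status drives vaccination uptake as
well as symptom and hospitalization risk.

Shared anchor values: per-exposure infection probability 0.5, symptom
probability 0.25 given infection, diagnosis 0.8 given infection,
hospitalization 0.1 given diagnosis, ICU 0.2 and death 0.3 given
hospitalization — a plausible severity ladder for a respiratory pathogen
in an unvaccinated reference adult.  Vaccine multipliers 0.5 on the
symptom step and 0.6 on the hospitalization step give configured true
values VE_S = 0.5, VE_SH = 0.7 and VE_H|S = 0.4.
"""

from __future__ import annotations

from dataclasses import replace

from .outcome_space import EventChain, default_chain
from .scm import (
    CovariateLaws,
    ExposureMechanism,
    Misclassification,
    RiskModel,
    ScenarioConfig,
    VaccinationMechanism,
)

__all__ = [
    "null_scenario",
    "effect_scenario",
    "confounded_scenario",
    "frailty_misclassification_scenario",
    "collider_scenario",
    "pyramid_scenario",
    "configured_true_ve",
]

_BASELINE = {"I": 0.5, "S": 0.25, "D": 0.8, "H": 0.1, "C": 0.2, "M": 0.3}
_VACCINE = {"S": 0.5, "H": 0.6}
_AGE_S = (0.6, 1.0, 1.6, 2.4)
_AGE_H = (0.3, 1.0, 2.0, 5.0)


def configured_true_ve(cfg: ScenarioConfig) -> dict[str, float]:
    """Closed-form true VEs implied by a constant multiplicative risk model.

    With effects constant across strata, covariate weights cancel from
    every risk ratio, so VE_S = 1 - v_I * v_S, VE_SH = 1 - v_I*v_S*v_D*v_H,
    and VE_H|S = 1 - v_D * v_H, where v_e is the vaccine multiplier on
    event e's conditional step (1 when absent).
    """
    v = {e: cfg.risk.vaccine.get(e, 1.0) for e in cfg.chain.events}
    ve_s = 1.0 - v["I"] * v["S"]
    ve_sh = 1.0 - v["I"] * v["S"] * v["D"] * v["H"]
    return {"VE_S": ve_s, "VE_SH": ve_sh, "VE_H|S": 1.0 - v["D"] * v["H"]}


def _base_risk(vaccine: dict | None = None, with_age: bool = True) -> RiskModel:
    return RiskModel(
        baseline=dict(_BASELINE),
        vaccine=dict(vaccine or {}),
        age={"S": _AGE_S, "H": _AGE_H} if with_age else {},
        prior_infection={"I": 0.7},
    )


def null_scenario(seed: int = 0) -> ScenarioConfig:
    """Randomized vaccination with no effect on any event (all true VEs 0)."""
    return ScenarioConfig(
        chain=default_chain(),
        vaccination=VaccinationMechanism.randomized(0.5),
        exposure=ExposureMechanism(p_exposure=0.5),
        risk=_base_risk(vaccine=None),
        seed=seed,
    )


def effect_scenario(seed: int = 0, a_multiplier: float = 1.0) -> ScenarioConfig:
    """Randomized vaccination with multiplicative protection.

    ``a_multiplier`` scales exposure probability for the vaccinated
    (1.0 = blinded; >1 models risk-tolerance behavior after vaccination).
    """
    return ScenarioConfig(
        chain=default_chain(),
        vaccination=VaccinationMechanism.randomized(0.5),
        exposure=ExposureMechanism(p_exposure=0.5, a_multiplier=a_multiplier),
        risk=_base_risk(vaccine=_VACCINE),
        seed=seed,
    )


def confounded_scenario(seed: int = 0, age_coef: float = 0.9) -> ScenarioConfig:
    """Observational scenario: older individuals are more vaccinated and at
    higher symptom/hospitalization risk, confounding crude comparisons."""
    return ScenarioConfig(
        chain=default_chain(),
        vaccination=VaccinationMechanism.confounded(intercept=-1.2, age_index=age_coef),
        exposure=ExposureMechanism(p_exposure=0.5),
        risk=_base_risk(vaccine=_VACCINE),
        seed=seed,
    )


def frailty_misclassification_scenario(seed: int = 0, frailty_sd: float = 0.3) -> ScenarioConfig:
    """Shared frailty across events plus imperfect variant and
    immunocompromised measurement, with two co-circulating variants."""
    mixture = (
        {"delta": 1.0},
        {"delta": 0.8, "omicron": 0.2},
        {"delta": 0.4, "omicron": 0.6},
        {"delta": 0.1, "omicron": 0.9},
    )
    risk = RiskModel(
        baseline=dict(_BASELINE),
        vaccine=dict(_VACCINE),
        age={"S": _AGE_S, "H": _AGE_H},
        prior_infection={"I": 0.7},
        variant={"omicron": {"S": 0.8, "H": 0.5}},
    )
    return ScenarioConfig(
        chain=default_chain(),
        vaccination=VaccinationMechanism.randomized(0.5),
        exposure=ExposureMechanism(p_exposure=0.5, variant_mixture=mixture),
        risk=risk,
        frailty_sd=frailty_sd,
        misclassification=Misclassification(
            variant_sensitivity=0.9,
            variant_specificity=0.95,
            immunocompromised_sensitivity=0.9,
            immunocompromised_specificity=0.95,
            positive_variant="omicron",
        ),
        seed=seed,
    )


def collider_scenario(
    seed: int = 0,
    confounder_log_odds: float = 3.0,
    frailty_sd: float = 0.0,
    immunocompromised_sensitivity: float = 1.0,
    immunocompromised_specificity: float = 1.0,
) -> ScenarioConfig:
    """Immunocompromised status as a cause of vaccination, symptoms, and
    hospitalization.

    Conditioning on symptomatic infection (a collider-path ascertainment
    event) then distorts the crude conditional VE against hospitalization:
    with ``confounder_log_odds`` large, symptomatic vaccinated individuals
    are heavily enriched for the immunocompromised, whose hospitalization
    risk is five-fold higher, and the vaccine can appear harmful.  The
    confounder is measurable (optionally with error) so stratified
    adjustment can be studied.
    """
    return ScenarioConfig(
        chain=default_chain(),
        covariate_laws=CovariateLaws(immunocompromised_prob=0.15),
        vaccination=VaccinationMechanism.confounded(
            intercept=-0.405, immunocompromised=confounder_log_odds
        ),
        exposure=ExposureMechanism(p_exposure=0.5),
        risk=RiskModel(
            baseline=dict(_BASELINE),
            vaccine=dict(_VACCINE),
            immunocompromised={"S": 3.0, "H": 5.0},
        ),
        frailty_sd=frailty_sd,
        misclassification=Misclassification(
            immunocompromised_sensitivity=immunocompromised_sensitivity,
            immunocompromised_specificity=immunocompromised_specificity,
        ),
        seed=seed,
    )


def pyramid_scenario(
    seed: int = 0,
    age_probs: tuple[float, ...] = (0.20, 0.40, 0.25, 0.15),
) -> ScenarioConfig:
    """Scenario for severity-pyramid synthesis.

    Uses a chain in which diagnosis requires symptoms, so every
    hospitalization is symptomatic and the pyramid decomposition
    sCFR = r_M|H * r_H|S is exact.  ``age_probs`` lets a component study
    be drawn from an age-shifted subpopulation to break cross-study
    exchangeability on purpose.
    """
    chain = EventChain(
        ("I", "S", "D", "H", "C", "M"),
        frozenset((("I", "S"), ("S", "D"), ("D", "H"), ("H", "C"), ("H", "M"))),
    )
    return ScenarioConfig(
        chain=chain,
        covariate_laws=CovariateLaws(age_probs=age_probs),
        vaccination=VaccinationMechanism.randomized(0.5),
        exposure=ExposureMechanism(p_exposure=0.5),
        risk=RiskModel(
            baseline=dict(_BASELINE),
            age={"H": _AGE_H, "M": (0.3, 1.0, 1.5, 2.5)},
        ),
        seed=seed,
    )
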