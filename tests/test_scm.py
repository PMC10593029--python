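"""Structural-causal-model simulator: determinism, consistency, recovery."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from param_lab import scenarios
from param_lab.outcome_space import default_chain, is_feasible
from param_lab.param_algebra import ve_compose
from param_lab.scm import (
    CovariateLaws,
    ExposureMechanism,
    Misclassification,
    RiskModel,
    ScenarioConfig,
    ScenarioValidationError,
    VaccinationMechanism,
    apply_misclassification,
    sample_population,
    true_estimands,
)


def minimal_cfg(**kwargs):
    base = dict(
        chain=default_chain(),
        vaccination=VaccinationMechanism.randomized(0.5),
        exposure=ExposureMechanism(p_exposure=0.5),
        risk=RiskModel(baseline={"I": 0.5, "S": 0.25, "D": 0.8, "H": 0.1, "C": 0.2, "M": 0.3}),
        seed=0,
    )
    base.update(kwargs)
    return ScenarioConfig(**base)


class TestDegenerateConfigs:
    def test_zero_exposure_means_all_zero_outcomes(self):
        cfg = minimal_cfg(exposure=ExposureMechanism(p_exposure=0.0))
        pop = sample_population(cfg, 500)
        for arm in (0, 1):
            assert pop.df[pop.outcome_columns(arm)].to_numpy().sum() == 0

    def test_certain_infection_nothing_downstream(self):
        cfg = minimal_cfg(
            exposure=ExposureMechanism(p_exposure=1.0),
            risk=RiskModel(baseline={"I": 1.0, "S": 0.0, "D": 0.0, "H": 0.0, "C": 0.0, "M": 0.0}),
        )
        pop = sample_population(cfg, 500)
        for arm in (0, 1):
            out = pop.df[pop.outcome_columns(arm)].to_numpy()
            assert (out == [1, 0, 0, 0, 0, 0]).all()

    def test_invalid_config_lists_offending_fields(self):
        cfg = minimal_cfg(
            exposure=ExposureMechanism(p_exposure=1.5),
            vaccination=VaccinationMechanism(kind="lottery"),
        )
        with pytest.raises(ScenarioValidationError) as exc:
            sample_population(cfg, 10)
        msg = str(exc.value)
        assert "p_exposure" in msg and "kind" in msg

    def test_n_must_be_positive(self):
        with pytest.raises(ValueError):
            sample_population(minimal_cfg(), 0)


class TestInvariants:
    def test_consistency_and_feasibility(self):
        cfg = scenarios.frailty_misclassification_scenario(seed=21)
        pop = sample_population(cfg, 5000)
        df = pop.df
        a = df["a_observed"].to_numpy()
        for ev in cfg.chain.events:
            obs = df[ev].to_numpy()
            expected = np.where(a == 1, df[f"{ev}_a1"], df[f"{ev}_a0"])
            assert (obs == expected).all()
        # every potential-outcome vector satisfies the precedence relation
        idx = {e: i for i, e in enumerate(cfg.chain.events)}
        for arm in (0, 1):
            mat = df[pop.outcome_columns(arm)].to_numpy()
            for pre, post in cfg.chain.requires:
                assert not ((mat[:, idx[post]] == 1) & (mat[:, idx[pre]] == 0)).any()
        # unexposed individuals have all-zero observed outcomes
        unexposed = ~pop.exposed_mask()
        assert df.loc[unexposed, list(cfg.chain.events)].to_numpy().sum() == 0

    def test_bit_identical_reproducibility(self):
        cfg = scenarios.effect_scenario(seed=33)
        p1 = sample_population(cfg, 2000)
        p2 = sample_population(cfg, 2000)
        pd.testing.assert_frame_equal(p1.df, p2.df)
        p3 = sample_population(replace(cfg, seed=34), 2000)
        assert not p1.df["I"].equals(p3.df["I"])

    def test_randomized_arm_exposure_balance(self, effect_pop):
        df = effect_pop.df
        a = df["a_observed"].to_numpy()
        e = df["exposed"].to_numpy()
        p0, p1 = e[a == 0].mean(), e[a == 1].mean()
        se = np.sqrt(0.5 * 0.5 * (1 / (a == 0).sum() + 1 / (a == 1).sum()))
        assert abs(p1 - p0) < 3 * se

    def test_parameter_recovery_no_confounding(self):
        """Empirical conditional risks converge to configured risk model."""
        cfg = minimal_cfg(
            risk=RiskModel(
                baseline={"I": 0.5, "S": 0.25, "D": 0.8, "H": 0.1, "C": 0.2, "M": 0.3},
                vaccine={"S": 0.1},
            ),
            seed=44,
        )
        pop = sample_population(cfg, 200_000)
        df = pop.df
        e = pop.exposed_mask()
        a = df["a_observed"].to_numpy()
        s = df["S"].to_numpy(bool)
        r0 = s[e & (a == 0)].mean()
        r1 = s[e & (a == 1)].mean()
        ve = 1 - r1 / r0
        sd_log_rr = np.sqrt(
            (1 - r1) / s[e & (a == 1)].sum() + (1 - r0) / s[e & (a == 0)].sum()
        )
        assert abs(ve - 0.9) < 3 * (r1 / r0) * sd_log_rr
        # conditional risks among exposed unvaccinated track the configuration
        i0 = df["I"].to_numpy(bool)[e & (a == 0)].mean()
        assert i0 == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / (e & (a == 0)).sum()))


class TestTrueEstimands:
    def test_null_scenario_all_ves_zero(self):
        te = true_estimands(scenarios.null_scenario(seed=5), 100_000)
        for key in ("VE_S", "VE_SH", "VE_H|S"):
            assert abs(te[key]) < 0.05

    def test_symptom_only_effect_makes_conditional_ve_zero(self):
        cfg = minimal_cfg(
            risk=RiskModel(
                baseline={"I": 0.5, "S": 0.25, "D": 0.8, "H": 0.2, "C": 0.2, "M": 0.3},
                vaccine={"S": 0.1},
            ),
            seed=6,
        )
        pop = sample_population(cfg, 200_000)
        te = true_estimands(cfg, 200_000, pop=pop)
        assert te["VE_S"] == pytest.approx(te["VE_SH"], abs=0.03)
        # MC tolerance from the realized event counts: the conditional VE is
        # a ratio of two risk ratios, so its log-variance is bounded by the
        # summed reciprocal event counts
        df, e = pop.df, pop.exposed_mask()
        counts = []
        for arm in (0, 1):
            s = df.loc[e, f"S_a{arm}"].to_numpy(bool)
            h = df.loc[e, f"H_a{arm}"].to_numpy(bool)
            counts += [s.sum(), (s & h).sum()]
        sd = np.sqrt(sum(1.0 / c for c in counts))
        assert abs(te["VE_H|S"]) < 3 * sd

    def test_compose_identity_holds_exactly(self):
        te = true_estimands(scenarios.effect_scenario(seed=7), 50_000)
        assert ve_compose(te["VE_S"], te["VE_H|S"]) == pytest.approx(te["VE_SH"], abs=1e-12)


class TestMisclassification:
    def test_perfect_measurement_is_identity(self, effect_pop):
        pop2 = apply_misclassification(effect_pop, effect_pop.cfg)
        assert (
            pop2.df["measured_immunocompromised"].to_numpy()
            == pop2.df["immunocompromised"].to_numpy()
        ).all()

    def test_zero_specificity_marks_everyone(self):
        cfg = minimal_cfg(
            misclassification=Misclassification(
                immunocompromised_sensitivity=1.0, immunocompromised_specificity=0.0
            )
        )
        pop = sample_population(cfg, 1000)
        assert (pop.df["measured_immunocompromised"] == 1).all()

    def test_confusion_matrix_counts(self):
        cfg = minimal_cfg(
            covariate_laws=CovariateLaws(immunocompromised_prob=0.3),
            misclassification=Misclassification(
                immunocompromised_sensitivity=0.9, immunocompromised_specificity=0.95
            ),
            seed=8,
        )
        pop = sample_population(cfg, 50_000)
        truth = pop.df["immunocompromised"].to_numpy()
        meas = pop.df["measured_immunocompromised"].to_numpy()
        n1 = truth.sum()
        sens_hat = meas[truth == 1].mean()
        spec_hat = 1 - meas[truth == 0].mean()
        assert sens_hat == pytest.approx(0.9, abs=3 * np.sqrt(0.9 * 0.1 / n1))
        assert spec_hat == pytest.approx(
            0.95, abs=3 * np.sqrt(0.95 * 0.05 / (len(truth) - n1))
        )

    def test_variant_call_sensitivity(self):
        cfg = scenarios.frailty_misclassification_scenario(seed=9)
        pop = sample_population(cfg, 50_000)
        df = pop.df[pop.df["exposed"] == 1]
        true_pos = df["variant"] == "omicron"
        called_pos = df["measured_variant"] == "omicron"
        assert called_pos[true_pos].mean() == pytest.approx(0.9, abs=0.02)
        assert (~called_pos[~true_pos]).mean() == pytest.approx(0.95, abs=0.02)


class TestSerialization:
    def test_yaml_round_trip(self, tmp_path):
        cfg = scenarios.frailty_misclassification_scenario(seed=77)
        path = tmp_path / "scenario.yaml"
        cfg.to_yaml(path)
        cfg2 = ScenarioConfig.from_yaml(path)
        assert cfg2 == cfg

    def test_individuals_iterator(self):
        cfg = scenarios.effect_scenario(seed=3)
        pop = sample_population(cfg, 50)
        people = list(pop.individuals())
        assert len(people) == 50
        for person in people:
            assert is_feasible(person.outcome_a0, cfg.chain)
            assert is_feasible(person.outcome_a1, cfg.chain)
            expected = person.outcome_a1 if person.a_observed else person.outcome_a0
            assert person.outcome_observed == expected
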