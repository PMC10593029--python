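"""Design emulators: masking, selection behavior, and bias mechanics."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from param_lab import scenarios
from param_lab.estimators import progression_risk, ve_progression, ve_risk_ratio
from param_lab.outcome_space import default_chain
from param_lab.param_algebra import ve_conditional
from param_lab.scm import (
    ExposureMechanism,
    RiskModel,
    VaccinationMechanism,
    sample_population,
    true_estimands,
)
from param_lab.study_designs import (
    BlindingError,
    CompositionError,
    EmptySampleError,
    MaskingError,
    StudySample,
    challenge_trial,
    cohort,
    contact_tracing,
    progression_study,
    rct,
    severity_pyramid,
)


class TestMasking:
    def test_counterfactual_columns_rejected(self, chain):
        rows = pd.DataFrame({"vaccinated": [0, 1], "S": [0, 1], "S_a0": [0, 0]})
        with pytest.raises(MaskingError):
            StudySample("rct", rows, chain)

    def test_frailty_column_rejected(self, chain):
        rows = pd.DataFrame({"vaccinated": [0, 1], "frailty": [1.0, 1.2]})
        with pytest.raises(MaskingError):
            StudySample("cohort", rows, chain)

    @pytest.mark.parametrize(
        "build",
        [
            lambda cfg: challenge_trial(cfg, 2000),
            lambda cfg: rct(cfg, 2000),
            lambda cfg: cohort(cfg, 2000),
            lambda cfg: contact_tracing(cfg, 2000),
            lambda cfg: progression_study(cfg, 2000, "S"),
        ],
    )
    def test_no_design_leaks_ground_truth(self, build):
        sample = build(scenarios.effect_scenario(seed=50))
        assert not any(c.endswith(("_a0", "_a1")) for c in sample.rows.columns)
        assert "frailty" not in sample.rows.columns


class TestChallengeTrial:
    def test_everyone_exposed(self):
        sample = challenge_trial(scenarios.effect_scenario(seed=51), 3000)
        assert (sample.rows["exposed"] == 1).all()

    def test_null_scenario_arm_risks_equal(self):
        sample = challenge_trial(scenarios.null_scenario(seed=52), 50_000)
        res = ve_risk_ratio(sample, "S")
        assert abs(res.estimate) < 3 * res.se

    def test_recovers_true_ve(self):
        cfg = scenarios.effect_scenario(seed=53)
        sample = challenge_trial(cfg, 100_000)
        res = ve_risk_ratio(sample, "S")
        truth = scenarios.configured_true_ve(cfg)["VE_S"]
        assert abs(res.estimate - truth) < 3 * res.se

    def test_p_vacc_bounds(self):
        with pytest.raises(ValueError):
            challenge_trial(scenarios.null_scenario(), 100, p_vacc=1.0)


class TestRCT:
    def test_exposure_hidden(self):
        sample = rct(scenarios.effect_scenario(seed=54), 2000)
        assert "exposed" not in sample.rows.columns
        assert "variant" not in sample.rows.columns

    def test_refuses_behavioral_exposure_effect(self):
        with pytest.raises(BlindingError):
            rct(scenarios.effect_scenario(seed=55, a_multiplier=1.3), 2000)

    def test_zero_exposure_zero_events(self):
        cfg = replace(
            scenarios.effect_scenario(seed=56), exposure=ExposureMechanism(p_exposure=0.0)
        )
        sample = rct(cfg, 2000)
        assert sample.rows[list(cfg.chain.events)].to_numpy().sum() == 0

    def test_marginal_ve_equals_exposure_conditional(self):
        """Exposure factors out of the trial risk ratio when A has no
        effect on exposure (the identity the blinded design relies on)."""
        cfg = scenarios.effect_scenario(seed=57)
        pop = sample_population(
            replace(cfg, vaccination=VaccinationMechanism.randomized(0.5)), 100_000
        )
        df = pop.df
        a, s, e = (df[c].to_numpy() for c in ("a_observed", "S", "exposed"))
        marginal = 1 - s[a == 1].mean() / s[a == 0].mean()
        conditional = 1 - s[(a == 1) & (e == 1)].mean() / s[(a == 0) & (e == 1)].mean()
        assert marginal == pytest.approx(conditional, abs=0.03)


class TestCohort:
    def test_unconfounded_cohort_matches_rct(self):
        cfg = scenarios.effect_scenario(seed=58)  # randomized mechanism
        res_c = ve_risk_ratio(cohort(cfg, 100_000), "S")
        res_r = ve_risk_ratio(rct(replace(cfg, seed=59), 100_000), "S")
        assert abs(res_c.estimate - res_r.estimate) < 3 * np.hypot(res_c.se, res_r.se)

    def test_age_confounding_biases_crude_not_stratified(self):
        cfg = scenarios.confounded_scenario(seed=60)
        sample = cohort(cfg, 150_000)
        truth = scenarios.configured_true_ve(cfg)["VE_S"]
        crude = ve_risk_ratio(sample, "S")
        strat = ve_risk_ratio(sample, "S", strata=["age_group"])
        assert abs(crude.estimate - truth) > 3 * crude.se  # visibly biased
        assert abs(strat.estimate - truth) < 3 * strat.se
        # vaccinated skew older and older means sicker: crude VE looks worse
        assert crude.estimate < strat.estimate


class TestContactTracing:
    def test_only_exposed_followed(self):
        sample = contact_tracing(scenarios.effect_scenario(seed=61), 5000)
        assert (sample.rows["exposed"] == 1).all()

    def test_uniform_selection_matches_truth(self):
        cfg = scenarios.effect_scenario(seed=62)
        sample = contact_tracing(cfg, 100_000)
        te = true_estimands(cfg, 100_000)
        unvacc = sample.rows[sample.rows["vaccinated"] == 0]
        risk = unvacc["S"].mean()
        se = np.sqrt(risk * (1 - risk) / len(unvacc))
        assert risk == pytest.approx(te["risk[S]|A=0"], abs=3 * se + 0.005)

    def test_age_biased_selection_shifts_crude_risks(self):
        cfg = scenarios.effect_scenario(seed=63)
        uniform = contact_tracing(cfg, 150_000)
        old_biased = contact_tracing(
            cfg, 150_000, selection_rule=lambda rows: 0.05 + rows["age_index"].to_numpy() ** 2
        )
        # older contacts carry higher symptom risk, shifting the crude risk up
        assert old_biased.rows["S"].mean() > uniform.rows["S"].mean() + 0.01
        # within age strata the risks still agree
        for g in ("18-49", "65+"):
            u = uniform.rows[(uniform.rows["age_group"] == g) & (uniform.rows["I"] == 1)]
            b = old_biased.rows[(old_biased.rows["age_group"] == g) & (old_biased.rows["I"] == 1)]
            se = np.hypot(u["S"].std() / np.sqrt(len(u)), b["S"].std() / np.sqrt(len(b)))
            assert abs(u["S"].mean() - b["S"].mean()) < 4 * se

    def test_no_exposed_raises(self):
        cfg = replace(
            scenarios.effect_scenario(seed=64), exposure=ExposureMechanism(p_exposure=0.0)
        )
        with pytest.raises(EmptySampleError):
            contact_tracing(cfg, 1000)


class TestProgressionStudy:
    def test_rows_all_have_ascertainment_event(self):
        sample = progression_study(scenarios.effect_scenario(seed=65), 20_000, "S")
        assert (sample.rows["S"] == 1).all()
        assert sample.ascertainment_event == "S"
        # upstream events are not observed
        assert "I" not in sample.rows.columns

    def test_conditional_ve_matches_identity_when_unconfounded(self):
        cfg = scenarios.effect_scenario(seed=66)
        sample = progression_study(cfg, 200_000, "S")
        res = ve_progression(sample, "S", "H")
        te = true_estimands(cfg, 200_000)
        expected = ve_conditional(te["VE_S"], te["VE_SH"])
        assert abs(res.estimate - expected) < 3 * res.se

    def test_collider_distortion_with_unmeasured_confounder(self):
        cfg = scenarios.collider_scenario(seed=67, confounder_log_odds=3.0)
        sample = progression_study(cfg, 100_000, "S")
        crude = ve_progression(sample, "S", "H")
        adjusted = ve_progression(sample, "S", "H", strata=["immunocompromised"])
        benchmark = true_estimands(cfg, 100_000)["VE_H|S"]
        assert abs(crude.estimate - benchmark) > 3 * crude.se
        assert abs(adjusted.estimate - benchmark) < 3 * adjusted.se

    def test_unknown_event_rejected(self):
        with pytest.raises(Exception):
            progression_study(scenarios.effect_scenario(seed=68), 1000, "X")

    def test_zero_prevalence_event_raises(self):
        cfg = replace(
            scenarios.effect_scenario(seed=69),
            risk=RiskModel(
                baseline={"I": 0.5, "S": 0.25, "D": 0.8, "H": 0.0, "C": 0.2, "M": 0.3}
            ),
        )
        with pytest.raises(EmptySampleError):
            progression_study(cfg, 2000, "H")


class TestSeverityPyramid:
    def test_matched_components_agree_with_direct(self):
        cfg = scenarios.pyramid_scenario(seed=70)
        comp_s = progression_study(cfg, 150_000, "S")
        comp_h = progression_study(replace(cfg, seed=71), 150_000, "H")
        pyramid = severity_pyramid([comp_s, comp_h], cfg.chain, [("S", "H"), ("H", "M")])
        direct = progression_risk(progression_study(replace(cfg, seed=72), 150_000, "S"), "S", "M")
        assert pyramid.product == pytest.approx(direct.estimate, abs=4 * direct.se)

    def test_mismatched_age_mix_deviates_upward(self):
        cfg = scenarios.pyramid_scenario(seed=73)
        old_cfg = replace(
            scenarios.pyramid_scenario(age_probs=(0.02, 0.08, 0.30, 0.60)), seed=74
        )
        comp_s = progression_study(cfg, 150_000, "S")
        comp_h_old = progression_study(old_cfg, 150_000, "H")
        pyramid = severity_pyramid([comp_s, comp_h_old], cfg.chain, [("S", "H"), ("H", "M")])
        direct = progression_risk(progression_study(replace(cfg, seed=75), 150_000, "S"), "S", "M")
        # hospitalized patients sourced from an older population die more often
        assert pyramid.product > direct.estimate + 3 * direct.se

    def test_single_component_covers_whole_chain(self):
        cfg = scenarios.pyramid_scenario(seed=76)
        comp = progression_study(cfg, 50_000, "S")
        pyramid = severity_pyramid([comp], cfg.chain, [("S", "M")])
        direct = progression_risk(comp, "S", "M")
        assert pyramid.product == pytest.approx(direct.estimate, abs=1e-12)

    def test_composition_errors(self, chain):
        cfg = scenarios.pyramid_scenario(seed=77)
        comp_s = progression_study(cfg, 5000, "S")
        with pytest.raises(CompositionError):
            severity_pyramid([comp_s], cfg.chain, [("S", "H"), ("H", "M")])  # missing level
        with pytest.raises(CompositionError):
            severity_pyramid([comp_s], cfg.chain, [("S", "H"), ("D", "M")])  # does not chain
        with pytest.raises(CompositionError):
            severity_pyramid([comp_s, comp_s], cfg.chain, [("S", "M")])  # duplicate level

    def test_csv_round_trip(self, tmp_path):
        sample = progression_study(scenarios.effect_scenario(seed=78), 2000, "S")
        path = tmp_path / "study.csv"
        sample.to_csv(path)
        back = StudySample.from_csv(path)
        assert back.design == "progression_study"
        assert back.ascertainment_event == "S"
        pd.testing.assert_frame_equal(back.rows, sample.rows)
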