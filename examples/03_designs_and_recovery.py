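"""Simulate a population and recover configured VEs through study designs.

The effect scenario protects multiplicatively (VE_S = 0.5, VE_SH = 0.7);
a challenge trial and a blinded RCT both recover it, while an
age-confounded cohort needs stratification: older individuals are both
more vaccinated and at higher risk, so the crude VE is biased down.
"""

from param_lab import challenge_trial, cohort, rct, ve_risk_ratio
from param_lab.scenarios import confounded_scenario, configured_true_ve, effect_scenario

n = 100_000
effect = effect_scenario(seed=7)
truth = configured_true_ve(effect)
print(f"configured truth: VE_S={truth['VE_S']:.2f}, VE_SH={truth['VE_SH']:.2f}")

for name, sample in [
    ("challenge trial", challenge_trial(effect, n)),
    ("blinded RCT    ", rct(effect, n)),
]:
    res = ve_risk_ratio(sample, "S")
    print(f"{name}: VE_S = {res.estimate:.3f} [95% CI {res.ci_low:.3f}, {res.ci_high:.3f}]")

conf = confounded_scenario(seed=8)
sample = cohort(conf, n)
crude = ve_risk_ratio(sample, "S")
strat = ve_risk_ratio(sample, "S", strata=["age_group"])
print(f"confounded cohort, crude      : VE_S = {crude.estimate:.3f}  (biased)")
print(f"confounded cohort, age-strat. : VE_S = {strat.estimate:.3f}  (recovers 0.50)")
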