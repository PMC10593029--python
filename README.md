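# param-lab

A simulation laboratory for studying how epidemiologic study designs
recover the causal parameters needed to drive individual-based
infectious-disease models — and how they fail.

Transmission models need per-individual probabilities of post-exposure
events (infection **I**, symptoms **S**, diagnosis **D**, hospitalization
**H**, ICU **C**, death **M**) as functions of covariates *L*, vaccination
*A*, and the infecting variant *e*: quantities like
Pr(H^{e,a} = 1 | L = l).  Real studies deliver something else — marginal
risk ratios, post-ascertainment conditional risks, severity-pyramid
fragments — and the mapping between the two is where bias lives.
`param-lab` gives you:

* **Exact algebra.**  The feasible outcome space of an event chain under
  precedence constraints (between n+1 and 2^n outcomes for n events);
  conversion between joint outcome distributions and step-wise
  progression tables; the conditional-VE identity

  ```
  VE_H|S = 1 − (1 − VE_SH) / (1 − VE_S)
  ```

  where VE_S is effectiveness against symptomatic infection, VE_SH
  against symptomatic hospitalization, and VE_H|S against hospitalization
  *among* the symptomatically infected; and the pyramid decomposition
  sCFR = r_M|H · r_H|S.
* **A structural-causal-model simulator.**  Populations with covariates,
  confounded or randomized vaccination, a variant-bearing exposure
  contact, shared frailty, misclassified measurements — and *both*
  potential-outcome vectors per individual (common random numbers across
  arms), so every causal estimand has computable ground truth.
* **Study-design emulators and estimators.**  Challenge trial, blinded
  RCT (exposure unrecorded), observational cohort, contact tracing with
  covariate-dependent selection, progression studies ascertained at a
  later event, and severity-pyramid synthesis; standardized risk-ratio VE
  estimators with large-sample intervals and bias accounting against the
  simulator's truth.
* **Packaged experiments** demonstrating the classic failure modes:
  exposure factoring out of the blinded-trial risk ratio, collider bias
  from conditioning on symptomatic infection (up to sign-flipped
  "apparent harm"), and broken cross-study exchangeability in pyramid
  synthesis.

## A worked example

Why can a conditional "effectiveness" *increase* as immunity wanes?
Because VE_H|S is a ratio of two waning quantities:

```python
>>> from param_lab.experiments import reproduce_table2
>>> print(reproduce_table2().to_string(index=False))
  example vaccination  VE_S_pct  VE_H|S_pct  VE_SH_pct
Example 1      Recent        90          70         97
Example 1  Longer ago        65          43         80
Example 2      Recent        62          63         86
Example 2  Longer ago         0          71         71
```

In Example 1 both endpoints wane at similar rates and VE_H|S falls
(70% → 43%).  In Example 2 protection against symptomatic infection
collapses (62% → 0%) while protection against hospitalization wanes
gently (86% → 71%), and the conditional measure *rises* (63% → 71%) —
a post-treatment-conditioned ratio, not a causal effect.

And the collider-bias demonstration (`examples/04_collider_bias.py`):
with immunocompromised status driving vaccination uptake as well as
symptom and hospitalization risk, a progression study ascertained at
symptoms estimates a crude VE_H|S of about **−0.55** (apparent harm)
when the potential-outcome benchmark is **+0.40**; stratifying on the
measured confounder restores ≈ 0.40.

The `examples/` directory has one short narrative script per capability;
`param-lab --help` exposes the same functionality as a command line
(`outcomes`, `algebra`, `simulate`, `design`, `estimate`, `experiment`,
`fixtures`).

## Layout

```
src/param_lab/
  outcome_space.py   event chains, precedence, feasible outcome enumeration
  param_algebra.py   VE identity, joint<->conditional tables, sCFR composition
  scm.py             scenario configs, SCM simulator, ground-truth estimands
  scenarios.py       shipped scenario library (null/effect/confounded/...)
  study_designs.py   design emulators and masking-safe study samples
  estimators.py      risk-ratio VE, progression risks, bias reports
  experiments.py     packaged end-to-end experiments + fixture generation
  cli.py             thin click CLI (`param-lab`)
```

See `docs/methods.md` for the model, its assumptions, and numerical
conventions.
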