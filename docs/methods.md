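# Methods

## The estimation problem

An individual-based transmission model needs, for each person with
baseline covariates *L = l* assigned vaccination *A = a* and exposure to
variant *e*, the probability of each feasible combination of
post-exposure events — infection (I), symptoms (S), diagnosis (D),
hospitalization (H), ICU (C), death (M).  Epidemiologic studies estimate
related but different quantities: marginal risk ratios, conditional
progression risks among the ascertained, fragments of a severity
pyramid.  This package provides (a) the exact algebra connecting those
quantities and (b) a simulation bench on which each study design is run
against known ground truth.

## Outcome space

Events form an ordered chain with a precedence relation: a pair (a, b)
means b can occur only if a did.  The relation must be acyclic and
consistent with the chain order, and the first event (infection) must be
ancestral to every other in simulated scenarios.  Feasible outcomes are
the binary vectors satisfying all pairs — between n+1 (strict linear
chain) and 2^n (no constraints) for n events.  The shipped default is
S←I, D←I, H←D, C←H, M←H: death may skip the ICU, diagnosis does not
require symptoms.  Enumeration is lexicographic with the first event as
the most significant bit, so output order is deterministic.  Timing and
duration are deliberately out of scope: outcomes are terminal
indicators, not compartmental states.

## VE algebra

All effectiveness values are proportions in (−∞, 1]; negative values
encode harm.  With VE_S = 1 − RR(S) and VE_SH = 1 − RR(S∧H) (the joint
event "symptomatic and hospitalized"), the conditional measure
VE_H|S = 1 − RR(H | S=1) satisfies the exact identity

    VE_H|S = 1 − (1 − VE_SH) / (1 − VE_S),

because Pr(H | S) = Pr(S∧H)/Pr(S).  Defining VE_SH on the joint event is
what makes the identity hold for *any* event chain; in scenarios where
hospitalization implies symptoms it coincides with VE against
hospitalization simpliciter.  VE_S = 1 is excluded (empty denominator).
The identity is monotone increasing in VE_SH and decreasing in VE_S,
which is why the conditional measure can rise while both inputs wane.
Percent formatting (nearest integer, half-up) exists only in the
reporting layer.

Joint↔conditional conversion: a progression table stores
Pr(event | full realized history of prior events).  Entries whose
history violates precedence are absent (structural zero); entries on
zero-probability histories carry an explicit `UNDEFINED` sentinel —
never a silent 0, because a model consumer must distinguish "never
reached" from "never progresses".  The two directions are exact inverses
on their valid domains (tested to 1e-12).

sCFR composition: the pyramid product r_M|H · r_H|S equals
Pr(M = 1 | S = 1) only when every death passes through hospitalization;
`scfr_compose` takes the chain and refuses the decomposition otherwise.

## The simulator

One simulated individual carries covariates (age group, sex, comorbidity
count, prior infection, immunocompromised status, calendar period),
a frailty factor, a vaccination assignment, an exposure contact with a
variant drawn from the period's mixture, and both potential-outcome
vectors.

* **Risk model.**  Each event has a baseline conditional probability
  given its prerequisites, multiplied by age-group, immunocompromised,
  prior-infection, variant, vaccination, and frailty factors, clipped to
  [0, 1] with a logged counter.  Multiplicativity mirrors the usual
  sparse-data assumption; the shipped scenarios are sized so clipping
  does not trigger (frailty scenarios may clip rarely; the counter
  reports it).
* **Common random numbers.**  One uniform per (individual, event),
  shared across the two vaccination arms, makes individual-level
  potential outcomes well defined and keeps contrast variance small.
  Exposure shares a uniform across arms the same way, so a behavioral
  vaccination→exposure multiplier produces nested exposure sets.
* **Frailty** is a single multiplicative susceptibility factor shared by
  all of an individual's events: exp(σZ − σ²/2) with Z a standard normal
  truncated at ±3 (so E ≈ 1 and risks stay in range); σ = 0 disables it.
  A useful algebraic fact, visible in the collider grids: with a purely
  multiplicative risk model and arm-constant effects, frailty (or any
  non-vaccination-linked confounder of S and H) cancels from the
  conditional risk ratio, so it induces *no* bias on its own.  The
  collider demonstrations therefore hinge on the confounder also driving
  vaccination — as in realistic prioritization of the
  immunocompromised.
* **Misclassification.**  Measured copies of immunocompromised status
  and of a binary variant call (an SGTF-style proxy requiring exactly
  two variants) are flipped by sensitivity/specificity; true fields are
  untouched.
* **Seeding.**  One root seed per scenario; every stochastic operation
  draws from a child stream with a fixed label (covariates, vaccination,
  exposure, frailty, events, misclassification, selection), so adding an
  operation never perturbs the others and populations are bit-identical
  given (config, n).

Ground truth (`true_estimands`) is computed from the potential outcomes
among the exposed: per-event risks under both arms, VE per event, VE_SH
on the joint event, and the identity-implied VE_H|S.  By construction
VE_SH = 1 − (1 − VE_S)(1 − VE_H|S) holds to machine precision on the
same risk table.

What the generator does *not* emulate — and what passing tests therefore
do not establish about real data: transmission dynamics and contact
networks (exposure is a single exogenous contact), event timing and
censoring, effect modification of vaccine multipliers across strata,
non-multiplicative (e.g. saturating) risk structure, and loss to
follow-up.

## Study designs and estimators

Study samples expose only what the design could see; counterfactual and
frailty columns are structurally excluded and their presence raises an
error, so estimators are pure functions of observable rows.  The blinded
RCT emulator additionally hides exposure and refuses scenarios with a
vaccination→exposure effect; the numerical check that "exposure factors
out of the ratio" is an experiment on the oracle view, not on trial
rows.  Contact-tracing selection rules are weight functions of measured
covariates, making non-exchangeable selection first-class.

Stratified VE standardizes within-stratum risks to the sample's stratum
distribution (a marginal, population-averaged VE); strata with no
unvaccinated events are excluded with an audited count rather than
producing infinite risk ratios.  Confidence intervals are large-sample
log-RR intervals (Wilson intervals for plain conditional risks); exact
small-sample inference is out of scope.  Even a fully adjusted VE_H|S
retains an ambiguous causal interpretation — the symptomatic sets under
the two arms differ — and the toolkit quantifies this as the gap to the
identity benchmark rather than implementing principal-stratification
estimators.

## Experiments and Monte-Carlo conventions

Replicated experiments report the replicate mean and its standard error;
deviations are flagged beyond 3 MC SE, with 20 replicates as the default
for stochastic checks.  Problem sizes shipped with the experiments and
acceptance tests — n = 150,000–200,000 per replicate — put individual
risk-ratio SEs near 0.01–0.02, small enough that the configured biases
(crude-vs-truth gaps of 0.1–1.0) are detected with wide margin while a
full run of the suite stays in the tens of seconds.  The collider grid
default covers confounder log-odds {0, 3} × frailty SD {0, 0.3}; the
strong-confounder cell is calibrated (immunocompromised prevalence 0.15,
risk multipliers 3 on S and 5 on H, log-odds 3 on vaccination) so the
crude conditional VE flips sign while the benchmark stays near +0.4.

Fixture generation (`generate_fixtures`) writes the waning profiles,
three canonical scenario YAMLs, and n = 1,000 populations,
byte-identical for a fixed seed; the test suite builds its own inputs
programmatically.

## Known limitations

Variant misclassification supports exactly two co-circulating variants
(a binary proxy); regression adjustment beyond stratification,
test-negative designs, vaccine effects on infectiousness, and
transportability across populations are out of scope.  The severity
pyramid assumes each component reports one level; overlapping designs
are refused rather than reconciled.
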