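"""Risk-ratio VE estimators, progression risks, and bias accounting.

All estimators are pure functions of the visible rows of a
:class:`~param_lab.study_designs.StudySample`; the sample's masking
invariant guarantees they cannot touch counterfactual ground truth.

Stratified VE combines within-stratum risks by standardization to the
sample's stratum distribution, giving a marginal, population-averaged VE;
per-stratum risks remain available to callers that want them.  Strata
with no events in the unvaccinated arm are excluded from standardization
(their risk ratio is undefined) and counted, keeping composite estimates
finite and the exclusion auditable.  Confidence intervals are
large-sample intervals on the log risk-ratio scale (binomial Wilson
intervals for plain conditional risks); exact small-sample inference is
out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .study_designs import StudySample

__all__ = [
    "EstimateResult",
    "EstimationError",
    "ve_risk_ratio",
    "ve_progression",
    "progression_risk",
    "bias_report",
]

logger = logging.getLogger(__name__)

_Z = stats.norm.ppf(0.975)


class EstimationError(ValueError):
    """The sample cannot support the requested estimate."""


@dataclass
class EstimateResult:
    """A named estimand with uncertainty and optional ground truth."""

    estimand: str
    estimate: float
    ci_low: float
    ci_high: float
    se: float
    strata_used: tuple[str, ...] = ()
    n_effective: int = 0
    n_excluded_strata: int = 0
    truth: float | None = None
    bias: float | None = None

    def with_truth(self, truth: float) -> "EstimateResult":
        return EstimateResult(
            **{
                **self.__dict__,
                "truth": truth,
                "bias": self.estimate - truth,
            }
        )


def _event_indicator(rows: pd.DataFrame, outcome_event: str | Sequence[str]) -> np.ndarray:
    """Indicator of one event, or of the joint occurrence of several."""
    if isinstance(outcome_event, str):
        outcome_event = (outcome_event,)
    ind = np.ones(len(rows), dtype=bool)
    for ev in outcome_event:
        if ev not in rows.columns:
            raise EstimationError(f"sample rows have no column for event {ev!r}")
        ind &= rows[ev].to_numpy(bool)
    return ind


def _estimand_name(outcome_event: str | Sequence[str], suffix: str = "") -> str:
    name = outcome_event if isinstance(outcome_event, str) else "".join(outcome_event)
    return f"VE_{name}{suffix}"


def _arm_counts(
    rows: pd.DataFrame, y: np.ndarray
) -> tuple[int, int, int, int]:
    a = rows["vaccinated"].to_numpy(int)
    n1, n0 = int((a == 1).sum()), int((a == 0).sum())
    x1, x0 = int(y[a == 1].sum()), int(y[a == 0].sum())
    return n0, x0, n1, x1


def _ve_from_risks(r1: float, r0: float, var1: float, var0: float) -> tuple[float, float, float, float]:
    """VE point estimate and CI from arm risks and their variances."""
    rr = r1 / r0
    var_log_rr = var1 / r1**2 if r1 > 0 else np.inf
    var_log_rr += var0 / r0**2
    sd = np.sqrt(var_log_rr)
    lo, hi = 1.0 - rr * np.exp(_Z * sd), 1.0 - rr * np.exp(-_Z * sd)
    se = rr * sd  # delta method on VE = 1 - RR
    return 1.0 - rr, lo, hi, se


def ve_risk_ratio(
    sample: StudySample,
    outcome_event: str | Sequence[str],
    strata: Sequence[str] = (),
) -> EstimateResult:
    """VE = 1 - risk ratio for an event (or joint event), optionally
    standardized over covariate strata.

    ``outcome_event`` may be a single event label or a sequence of labels,
    in which case the outcome is their joint occurrence (e.g. ``("S","H")``
    for symptomatic hospitalization).
    """
    rows = sample.rows
    if "vaccinated" not in rows.columns:
        raise EstimationError("sample rows carry no vaccination column")
    y = _event_indicator(rows, outcome_event)
    strata = tuple(strata)

    if not strata:
        n0, x0, n1, x1 = _arm_counts(rows, y)
        if n0 == 0 or n1 == 0:
            raise EstimationError("a vaccination arm is empty")
        if x0 == 0:
            raise EstimationError(
                "no events in the unvaccinated arm; crude risk ratio undefined"
            )
        r1, r0 = x1 / n1, x0 / n0
        est, lo, hi, se = _ve_from_risks(r1, r0, r1 * (1 - r1) / n1, r0 * (1 - r0) / n0)
        return EstimateResult(
            estimand=_estimand_name(outcome_event),
            estimate=est,
            ci_low=lo,
            ci_high=hi,
            se=se,
            n_effective=n0 + n1,
        )

    for s in strata:
        if s not in rows.columns:
            raise EstimationError(f"stratification column {s!r} not in sample rows")
    groups = rows.assign(_y=y).groupby(list(strata), observed=True)
    cells = []
    excluded = 0
    for key, g in groups:
        n0, x0, n1, x1 = _arm_counts(g, g["_y"].to_numpy(bool))
        if n0 == 0 or n1 == 0 or x0 == 0:
            excluded += 1
            continue
        cells.append((len(g), x1 / n1, x0 / n0, n1, n0))
    if not cells:
        raise EstimationError("every stratum lacked unvaccinated events or an arm")
    if excluded:
        logger.info("excluded %d strata without unvaccinated events", excluded)
    total = sum(c[0] for c in cells)
    w = np.array([c[0] / total for c in cells])
    r1s = np.array([c[1] for c in cells])
    r0s = np.array([c[2] for c in cells])
    n1s = np.array([c[3] for c in cells])
    n0s = np.array([c[4] for c in cells])
    R1, R0 = float(w @ r1s), float(w @ r0s)
    var1 = float((w**2 * r1s * (1 - r1s) / n1s).sum())
    var0 = float((w**2 * r0s * (1 - r0s) / n0s).sum())
    est, lo, hi, se = _ve_from_risks(R1, R0, var1, var0)
    return EstimateResult(
        estimand=_estimand_name(outcome_event),
        estimate=est,
        ci_low=lo,
        ci_high=hi,
        se=se,
        strata_used=strata,
        n_effective=total,
        n_excluded_strata=excluded,
    )


def ve_progression(
    sample: StudySample,
    from_event: str,
    to_event: str,
    strata: Sequence[str] = (),
) -> EstimateResult:
    """Conditional VE: 1 - risk ratio of ``to_event`` among individuals
    with ``from_event`` = 1 (e.g. VE against hospitalization among the
    symptomatically infected).

    This is the post-treatment-conditioned measure: without adjustment for
    every common cause of the ascertainment event and the outcome it need
    not equal the value implied by the marginal VEs.
    """
    rows = sample.rows
    if from_event not in rows.columns:
        raise EstimationError(f"sample rows have no column for event {from_event!r}")
    cond = rows[rows[from_event] == 1]
    if cond.empty:
        raise EstimationError(f"no individuals with {from_event} = 1 in sample")
    sub = StudySample(
        design=sample.design,
        rows=cond.reset_index(drop=True),
        chain=sample.chain,
        ascertainment_event=from_event,
        provenance=sample.provenance,
    )
    res = ve_risk_ratio(sub, to_event, strata)
    res.estimand = f"VE_{to_event}|{from_event}"
    return res


def progression_risk(
    sample: StudySample,
    from_event: str,
    to_event: str,
    strata: Sequence[str] = (),
) -> EstimateResult:
    """Conditional risk Pr(to_event = 1 | from_event = 1), arms pooled.

    Crude risks get a Wilson binomial interval; stratified risks are
    standardized to the conditional sample's stratum distribution with a
    normal-approximation interval.
    """
    rows = sample.rows
    for ev in (from_event, to_event):
        if ev not in rows.columns:
            raise EstimationError(f"sample rows have no column for event {ev!r}")
    cond = rows[rows[from_event] == 1]
    if cond.empty:
        raise EstimationError(f"no individuals with {from_event} = 1 in sample")
    name = f"r_{to_event}|{from_event}"
    strata = tuple(strata)
    if not strata:
        n = len(cond)
        x = int(cond[to_event].sum())
        r = x / n
        lo, hi = proportion_confint(x, n, alpha=0.05, method="wilson")
        se = float(np.sqrt(r * (1 - r) / n))
        return EstimateResult(name, r, float(lo), float(hi), se, (), n)
    groups = cond.groupby(list(strata), observed=True)
    total = len(cond)
    R, var = 0.0, 0.0
    for _, g in groups:
        wg = len(g) / total
        rg = float(g[to_event].mean())
        R += wg * rg
        var += wg**2 * rg * (1 - rg) / len(g)
    se = float(np.sqrt(var))
    return EstimateResult(
        name, R, R - _Z * se, R + _Z * se, se, strata, total
    )


def bias_report(
    results: Sequence[EstimateResult],
    truths: Mapping[str, float] | None = None,
    run_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Tabulate estimates against ground truth with a 3-SE bias flag.

    An estimand missing from ``truths`` is reported with an empty bias
    column, not an error.  ``run_ids`` labels duplicated estimand names
    (e.g. replications) so aggregation never hides provenance.
    """
    truths = dict(truths or {})
    rows = []
    for i, res in enumerate(results):
        truth = res.truth if res.truth is not None else truths.get(res.estimand)
        bias = res.estimate - truth if truth is not None else None
        rows.append(
            {
                "run": run_ids[i] if run_ids is not None else i,
                "estimand": res.estimand,
                "estimate": res.estimate,
                "se": res.se,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "n_effective": res.n_effective,
                "truth": truth if truth is not None else np.nan,
                "bias": bias if bias is not None else np.nan,
                "flag_3se": bool(bias is not None and abs(bias) > 3 * res.se),
            }
        )
    return pd.DataFrame(rows)
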