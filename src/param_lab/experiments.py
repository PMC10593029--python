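"""End-to-end experiments: worked examples and bias demonstrations.

Each experiment is reproducible from its arguments and a seed alone, and
returns plain DataFrames/dataclasses; ``out_dir`` arguments additionally
write CSV outputs plus a JSON manifest recording the spec, seed, and
package version.  Monte-Carlo convention throughout: replicated runs,
uncertainty reported as the standard error of the replicate mean, and a
3-SE flag for deviations.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .estimators import progression_risk, ve_progression, ve_risk_ratio
from .param_algebra import VEProfile, percent, ve_waning_table
from .scenarios import (
    collider_scenario,
    confounded_scenario,
    effect_scenario,
    frailty_misclassification_scenario,
    null_scenario,
    pyramid_scenario,
)
from .scm import ScenarioConfig, sample_population, true_estimands
from .study_designs import StudySample, progression_study, severity_pyramid

__all__ = [
    "TABLE2_PROFILES",
    "reproduce_table2",
    "rct_identity_check",
    "collider_bias_experiment",
    "pyramid_exchangeability_experiment",
    "generate_fixtures",
]

#: The four (VE_S, VE_SH) waning profiles of the worked two-example table:
#: Example 1 wanes at similar rates on both endpoints, Example 2 loses
#: protection against symptomatic infection much faster.
TABLE2_PROFILES: dict[str, list[VEProfile]] = {
    "Example 1": [
        VEProfile("Recent", 0.90, 0.97),
        VEProfile("Longer ago", 0.65, 0.80),
    ],
    "Example 2": [
        VEProfile("Recent", 0.62, 0.86),
        VEProfile("Longer ago", 0.00, 0.71),
    ],
}


def _child_seed(seed: int, *key: int) -> int:
    """A stable sub-seed below 2**31 derived from (seed, key)."""
    return int(np.random.SeedSequence(seed, spawn_key=key).generate_state(1)[0] % (2**31))


def _write_manifest(out_dir: Path, name: str, spec: dict) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / f"{name}.manifest.json", "w") as fh:
        json.dump({"experiment": name, "version": __version__, **spec}, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# Worked waning example
# ---------------------------------------------------------------------------


def reproduce_table2(out_dir: str | Path | None = None) -> pd.DataFrame:
    """The two-example waning table, at nearest-percent rounding.

    Shows that the conditional measure VE_H|S *decreases* across strata in
    Example 1 but *increases* in Example 2 even though both marginal VEs
    wane in both examples — the hazard of calling a post-treatment-
    conditioned ratio an "effectiveness".
    """
    frames = []
    for example, profiles in TABLE2_PROFILES.items():
        t = ve_waning_table(profiles)
        frames.append(
            pd.DataFrame(
                {
                    "example": example,
                    "vaccination": t["stratum_label"],
                    "VE_S_pct": t["ve_s"].map(percent),
                    "VE_H|S_pct": t["ve_h_given_s"].map(percent),
                    "VE_SH_pct": t["ve_sh"].map(percent),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    if out_dir is not None:
        out_dir = Path(out_dir)
        _write_manifest(out_dir, "table2", {"profiles": {k: [dataclasses.asdict(p) for p in v] for k, v in TABLE2_PROFILES.items()}})
        table.to_csv(out_dir / "table2.csv", index=False)
    return table


# ---------------------------------------------------------------------------
# RCT identity: exposure factors out of the ratio
# ---------------------------------------------------------------------------


@dataclass
class IdentityCheckReport:
    """Marginal vs exposure-conditional VE on the same populations."""

    outcome_event: str
    marginal: np.ndarray  # per-replicate marginal 1 - RR (trial-visible)
    conditional: np.ndarray  # per-replicate exposure-conditional 1 - RR (oracle)
    a_multiplier: float

    @property
    def difference_mean(self) -> float:
        return float(np.mean(self.marginal - self.conditional))

    @property
    def difference_se(self) -> float:
        d = self.marginal - self.conditional
        return float(np.std(d, ddof=1) / np.sqrt(len(d)))

    @property
    def consistent(self) -> bool:
        """True when the two quantities agree within 3 MC standard errors."""
        return abs(self.difference_mean) <= 3 * self.difference_se

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": np.arange(len(self.marginal)),
                "marginal_ve": self.marginal,
                "conditional_ve": self.conditional,
            }
        )


def rct_identity_check(
    cfg: ScenarioConfig,
    n: int,
    seed: int,
    replications: int = 20,
    outcome_event: str = "S",
    out_dir: str | Path | None = None,
) -> IdentityCheckReport:
    """Check numerically that exposure factors out of the trial risk ratio.

    On each replicate population (vaccination randomized): the *marginal*
    1 - RR of the outcome, computable from trial-visible rows where
    exposure is unrecorded, and the *exposure-conditional* 1 - RR among
    the exposed, computable only with the simulator's oracle view.  Under
    no direct effect of vaccination on exposure the two coincide up to
    Monte-Carlo error; a behavioral vaccination->exposure effect drives
    them apart in the configured direction.
    """
    marg, cond = [], []
    for rep in range(replications):
        c = replace(cfg, seed=_child_seed(seed, rep))
        pop = sample_population(c, n)
        df = pop.df
        y = df[outcome_event].to_numpy(bool)
        a = df["a_observed"].to_numpy(int)
        r1, r0 = y[a == 1].mean(), y[a == 0].mean()
        marg.append(1.0 - r1 / r0)
        e = df["exposed"].to_numpy(bool)
        r1e = y[e & (a == 1)].mean()
        r0e = y[e & (a == 0)].mean()
        cond.append(1.0 - r1e / r0e)
    report = IdentityCheckReport(
        outcome_event=outcome_event,
        marginal=np.array(marg),
        conditional=np.array(cond),
        a_multiplier=cfg.exposure.a_multiplier,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        _write_manifest(
            out_dir,
            "rct_identity",
            {"seed": seed, "n": n, "replications": replications, "scenario": cfg.to_dict()},
        )
        report.to_frame().to_csv(out_dir / "rct_identity.csv", index=False)
    return report


# ---------------------------------------------------------------------------
# Collider bias grid
# ---------------------------------------------------------------------------


def collider_bias_experiment(
    confounder_strengths: Sequence[float] = (0.0, 3.0),
    frailty_sds: Sequence[float] = (0.0, 0.3),
    n: int = 150_000,
    replications: int = 20,
    seed: int = 0,
    misclassification_sweep: Sequence[float] = (),
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Crude and adjusted conditional VE_H|S against the algebraic benchmark.

    For each grid cell (confounder log-odds on vaccination, frailty SD):
    replicate populations are ascertained at symptoms; the crude
    conditional VE, the VE stratified on the measured confounder, and the
    benchmark ``1 - (1-VE_SH)/(1-VE_S)`` recomputed from the same
    population's potential outcomes are recorded.  A ``sign_flip`` flag
    marks cells where the mean crude estimate is negative (apparent harm)
    while the benchmark is positive.

    ``misclassification_sweep`` optionally adds rows in which the
    confounder is measured with the given sensitivity = specificity,
    showing the adjusted gap shrink as measurement quality rises.
    """
    grid: list[dict] = []
    for strength in confounder_strengths:
        for fr in frailty_sds:
            grid.append({"confounder_log_odds": strength, "frailty_sd": fr, "measurement": 1.0})
    for q in misclassification_sweep:
        grid.append({"confounder_log_odds": max(confounder_strengths), "frailty_sd": 0.0, "measurement": q})

    rows = []
    for cell_i, cell in enumerate(grid):
        crude, adjusted, bench = [], [], []
        for rep in range(replications):
            cfg = collider_scenario(
                seed=_child_seed(seed, cell_i, rep),
                confounder_log_odds=cell["confounder_log_odds"],
                frailty_sd=cell["frailty_sd"],
                immunocompromised_sensitivity=cell["measurement"],
                immunocompromised_specificity=cell["measurement"],
            )
            pop = sample_population(cfg, n)
            study = progression_study(cfg, n, "S")
            crude.append(ve_progression(study, "S", "H").estimate)
            adjusted.append(
                ve_progression(study, "S", "H", strata=["immunocompromised"]).estimate
            )
            bench.append(true_estimands(cfg, n, pop=pop)["VE_H|S"])
        crude, adjusted, bench = map(np.asarray, (crude, adjusted, bench))
        d_crude = crude - bench
        d_adj = adjusted - bench
        r = len(crude)
        rows.append(
            {
                **cell,
                "replications": r,
                "crude_mean": crude.mean(),
                "crude_se": crude.std(ddof=1) / np.sqrt(r),
                "adjusted_mean": adjusted.mean(),
                "adjusted_se": adjusted.std(ddof=1) / np.sqrt(r),
                "benchmark_mean": bench.mean(),
                "benchmark_se": bench.std(ddof=1) / np.sqrt(r),
                "crude_dev_mean": d_crude.mean(),
                "crude_dev_se": d_crude.std(ddof=1) / np.sqrt(r),
                "adjusted_dev_mean": d_adj.mean(),
                "adjusted_dev_se": d_adj.std(ddof=1) / np.sqrt(r),
                "crude_flag_3se": bool(
                    abs(d_crude.mean()) > 3 * d_crude.std(ddof=1) / np.sqrt(r)
                ),
                "adjusted_flag_3se": bool(
                    abs(d_adj.mean()) > 3 * d_adj.std(ddof=1) / np.sqrt(r)
                ),
                "sign_flip": bool(crude.mean() < 0 < bench.mean()),
            }
        )
    out = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        _write_manifest(
            out_dir,
            "collider_bias",
            {
                "seed": seed,
                "n": n,
                "replications": replications,
                "confounder_strengths": list(confounder_strengths),
                "frailty_sds": list(frailty_sds),
                "misclassification_sweep": list(misclassification_sweep),
            },
        )
        out.to_csv(out_dir / "collider_bias.csv", index=False)
    return out


# ---------------------------------------------------------------------------
# Severity-pyramid exchangeability
# ---------------------------------------------------------------------------


@dataclass
class PyramidExchangeabilityReport:
    """Composed vs direct composite risk, matched and mismatched sources."""

    direct: float
    direct_se: float
    composed_matched: float
    composed_mismatched: float
    levels_matched: pd.DataFrame
    levels_mismatched: pd.DataFrame

    @property
    def matched_gap(self) -> float:
        return self.composed_matched - self.direct

    @property
    def mismatched_gap(self) -> float:
        return self.composed_mismatched - self.direct


def pyramid_exchangeability_experiment(
    cfg: ScenarioConfig | None = None,
    mismatched_cfg: ScenarioConfig | None = None,
    n: int = 100_000,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> PyramidExchangeabilityReport:
    """Compose sCFR = r_M|H * r_H|S from level studies and compare with the
    direct estimate of Pr(death | symptomatic) from one full-chain sample.

    The matched pyramid draws both level studies from the same scenario;
    the mismatched pyramid replaces the hospitalization-level study with
    one drawn from an age-shifted subpopulation (default: much older),
    violating cross-study exchangeability in a known direction.
    """
    cfg = cfg or pyramid_scenario(seed=_child_seed(seed, 0))
    mismatched_cfg = mismatched_cfg or replace(
        pyramid_scenario(age_probs=(0.02, 0.08, 0.30, 0.60)),
        seed=_child_seed(seed, 1),
    )

    full = progression_study(replace(cfg, seed=_child_seed(seed, 2)), n, "S")
    direct = progression_risk(full, "S", "M")

    comp_s = progression_study(replace(cfg, seed=_child_seed(seed, 3)), n, "S")
    comp_h = progression_study(replace(cfg, seed=_child_seed(seed, 4)), n, "H")
    comp_h_mis = progression_study(replace(mismatched_cfg, seed=_child_seed(seed, 5)), n, "H")

    levels = [("S", "H"), ("H", "M")]
    matched = severity_pyramid([comp_s, comp_h], cfg.chain, levels)
    mismatched = severity_pyramid([comp_s, comp_h_mis], cfg.chain, levels)

    report = PyramidExchangeabilityReport(
        direct=direct.estimate,
        direct_se=direct.se,
        composed_matched=matched.product,
        composed_mismatched=mismatched.product,
        levels_matched=matched.levels,
        levels_mismatched=mismatched.levels,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        _write_manifest(out_dir, "pyramid", {"seed": seed, "n": n})
        pd.DataFrame(
            [
                {
                    "direct_sCFR": report.direct,
                    "direct_se": report.direct_se,
                    "composed_matched": report.composed_matched,
                    "composed_mismatched": report.composed_mismatched,
                }
            ]
        ).to_csv(out_dir / "pyramid.csv", index=False)
    return report


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------


def generate_fixtures(out_dir: str | Path, seed: int = 0, n: int = 1000) -> list[Path]:
    """Write the canonical small inputs: waning profiles, three scenario
    YAMLs, and pre-simulated n=1000 populations.  Byte-identical for a
    fixed seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    profiles = pd.DataFrame(
        [
            {"example": ex, "stratum_label": p.stratum_label, "ve_s": p.ve_s, "ve_sh": p.ve_sh}
            for ex, ps in TABLE2_PROFILES.items()
            for p in ps
        ]
    )
    path = out_dir / "table2_profiles.csv"
    profiles.to_csv(path, index=False)
    written.append(path)

    scenarios = {
        "null": null_scenario(seed=_child_seed(seed, 10)),
        "confounded": confounded_scenario(seed=_child_seed(seed, 11)),
        "frailty_misclassification": frailty_misclassification_scenario(
            seed=_child_seed(seed, 12)
        ),
    }
    for name, cfg in scenarios.items():
        cfg.validate()
        ypath = out_dir / f"scenario_{name}.yaml"
        cfg.to_yaml(ypath)
        written.append(ypath)
        pop = sample_population(cfg, n)
        ppath = out_dir / f"pop_{name}.csv"
        pop.to_csv(ppath)
        written.append(ppath)

    with open(out_dir / "fixtures.manifest.json", "w") as fh:
        json.dump(
            {"seed": seed, "n": n, "version": __version__, "files": [p.name for p in written]},
            fh,
            indent=2,
        )
    return written
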