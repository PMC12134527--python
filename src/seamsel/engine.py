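"""Whole-trial simulation and operating characteristics.

One replicate runs the full design: simulate the phase-II cohort,
dichotomize at t*, select a population (Bayesian posterior rules or the
frequentist z-threshold comparator), and — unless the trial stopped for
futility — simulate the phase-III cohort in the selected population,
extend stage-1 follow-up to the final database lock, and apply the
conditional-error combination test with closed testing.  Aggregation over
replicates reproduces the design's operating characteristics: selection
frequencies, false positive rate, overall power, and hazard-ratio bias.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bayes import PosteriorSummary, build_design_matrix, fit_logistic_posterior, interim_decision_bayes
from .combination import (
    FinalOutcome,
    StageStatistics,
    closed_test_decision,
    estimate_hazard_ratio,
    logrank_z,
)
from .design import InterimDecision, MCMCConfig, TrialDesign
from .frequentist import binary_stage_stats, interim_decision_freq
from .simulate import ScenarioSpec, TrialDataset, dichotomize, simulate_cohort

__all__ = [
    "TrialResult",
    "OperatingCharacteristics",
    "interim_analysis",
    "run_single_trial",
    "run_scenario",
    "bias_summary",
    "find_sample_size",
]

_DECISIONS = (
    InterimDecision.FUTILITY,
    InterimDecision.F_ONLY,
    InterimDecision.S_ONLY,
    InterimDecision.F_AND_S,
)


@dataclasses.dataclass
class TrialResult:
    """Everything recorded about one simulated trial."""

    decision: InterimDecision
    outcome: FinalOutcome
    stats: StageStatistics
    hr_estimates: dict[str, float]
    true_hr: dict[str, float]
    seed: int
    probs: tuple[float, float, float] | None = None  # (p_TS, p_T, p_sum) if Bayesian
    converged: bool = True

    def to_record(self) -> dict:
        rec = {"seed": self.seed, "decision": self.decision.value, "converged": self.converged}
        rec.update(self.stats.to_dict())
        if self.probs is not None:
            rec.update(p_TS=self.probs[0], p_T=self.probs[1], p_sum=self.probs[2])
        rec.update(
            reject_F=self.outcome.reject_F,
            reject_S=self.outcome.reject_S,
            reject_intersection=self.outcome.reject_intersection,
        )
        for pop, hr in self.hr_estimates.items():
            rec[f"hr_hat_{pop}"] = hr
        return rec


def interim_analysis(
    binary_dataset: TrialDataset,
    design: TrialDesign,
    method: str = "bayes",
    mcmc: MCMCConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[InterimDecision, StageStatistics, PosteriorSummary | None]:
    """Selection step on a dichotomized stage-1 cohort (simulated or real)."""
    bstats = binary_stage_stats(binary_dataset, design=design)
    stats_ = StageStatistics(z1b_F=bstats.z_F, z1b_S=bstats.z_S, w1=design.w1, w2=design.w2)
    if method == "freq":
        return interim_decision_freq(bstats.z_F, bstats.z_S, design), stats_, None
    if method != "bayes":
        raise ValueError("method must be 'bayes' or 'freq'")
    X, y = build_design_matrix(binary_dataset)
    summary = fit_logistic_posterior(X, y, prior=design.prior, mcmc=mcmc, seed=seed, zeta_e=design.zeta_e)
    decision = interim_decision_bayes(summary.p_TS, summary.p_T, summary.p_sum, design)
    return decision, stats_, summary


def run_single_trial(
    scenario: ScenarioSpec,
    design: TrialDesign,
    method: str = "bayes",
    seed: int | None = None,
    mcmc: MCMCConfig | None = None,
) -> TrialResult:
    """Run one complete seamless trial under a scenario.

    The replicate seed deterministically spawns independent sub-streams for
    the stage-1 cohort, the sampler, and the stage-2 cohort, so a single
    trial is replayable from (scenario, design, method, seed).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng_ph2, rng_mcmc, rng_ph3 = (np.random.default_rng(s) for s in ss.spawn(3))
    ph2 = simulate_cohort(scenario, design, "phase2", seed=rng_ph2)
    binary = dichotomize(ph2, design.t_star)
    decision, stats_, summary = interim_analysis(binary, design, method, mcmc, rng_mcmc)
    probs = (summary.p_TS, summary.p_T, summary.p_sum) if summary is not None else None
    converged = summary.converged if summary is not None else True
    true_hr = {
        "F": scenario.true_hr("F", design.prevalence, design.t_star),
        "S": scenario.true_hr("S", design.prevalence, design.t_star),
    }
    if decision is InterimDecision.FUTILITY:
        outcome = closed_test_decision(stats_, decision, design)
        return TrialResult(decision, outcome, stats_, {}, true_hr, _seed_id(seed), probs, converged)
    # phase III in the selected population; stage-1 patients in the selected
    # group continue follow-up to the final lock
    membership = "S_only" if decision is InterimDecision.S_ONLY else "mixed"
    ph3 = simulate_cohort(
        scenario, design, "phase3", seed=rng_ph3, membership=membership, entry_start=ph2.analysis_time
    )
    lock = float(ph3.df["entry_time"].max()) + design.followup_phase3
    ph2_final = ph2.observed_at(lock)
    ph3_final = ph3.observed_at(lock)
    hr_estimates: dict[str, float] = {}
    for pop in ("F", "S"):
        analyze = (pop == "F" and decision.analyzes_F) or (pop == "S" and decision.analyzes_S)
        if not analyze:
            continue
        z1 = logrank_z(ph2_final, population=pop)
        z2 = logrank_z(ph3_final, population=pop)
        if pop == "F":
            stats_.z1_F, stats_.z2_F = z1, z2
        else:
            stats_.z1_S, stats_.z2_S = z1, z2
        pooled = TrialDataset(
            pd.concat([ph2_final.subset(pop).df, ph3_final.subset(pop).df], ignore_index=True),
            "final",
            lock,
        )
        hr_estimates[pop] = estimate_hazard_ratio(pooled, "F", method=design.hr_method)
    outcome = closed_test_decision(stats_, decision, design)
    return TrialResult(decision, outcome, stats_, hr_estimates, true_hr, _seed_id(seed), probs, converged)


def _seed_id(seed) -> int:
    return int(seed) if seed is not None and np.isscalar(seed) else -1


def _pct(k: int, n: int) -> float:
    return 100.0 * k / n


def _se_pct(k: int, n: int) -> float:
    p = k / n
    return 100.0 * math.sqrt(p * (1.0 - p) / n)


@dataclasses.dataclass
class OperatingCharacteristics:
    """Aggregates over simulated trials, one scenario and method."""

    scenario_id: int
    method: str
    n_sim: int
    decision_pct: dict[str, float]
    decision_se: dict[str, float]
    conditional_positive_pct: dict[str, float]  # rejections among that decision
    f_tot: float  # % of trials where F selected AND H0F rejected
    s_tot: float
    false_positive_rate: float  # % of trials with any rejection
    false_positive_se: float
    overall_power: float  # % rejecting >=1 target population
    preferred_pct: float  # % of trials taking the preferred interim decision
    bias_F: float
    bias_S: float
    n_nonconverged: int
    results: list[TrialResult] | None = None

    def to_frame(self) -> pd.DataFrame:
        row = {
            "Scenario": self.scenario_id,
            "Model": self.method,
            "Futility": self.decision_pct["futility"],
            "F": self.decision_pct["F"],
            "S": self.decision_pct["S"],
            "S&F": self.decision_pct["F&S"],
            "F (positive %)": self.conditional_positive_pct["F"],
            "S (positive %)": self.conditional_positive_pct["S"],
            "S&F (positive %)": self.conditional_positive_pct["F&S"],
            "Ftot": self.f_tot,
            "Stot": self.s_tot,
            "False positive rate": self.false_positive_rate,
            "Overall power": self.overall_power,
            "Bias F": self.bias_F,
            "Bias S": self.bias_S,
            "n_sim": self.n_sim,
            "n_nonconverged": self.n_nonconverged,
        }
        for k, v in self.decision_se.items():
            row[f"SE {k}"] = v
        row["SE false positive rate"] = self.false_positive_se
        return pd.DataFrame([row])


def run_scenario(
    scenario: ScenarioSpec,
    design: TrialDesign,
    method: str = "bayes",
    n_sim: int = 1000,
    root_seed: int | None = None,
    mcmc: MCMCConfig | None = None,
    keep_results: bool = False,
) -> OperatingCharacteristics:
    """Simulate ``n_sim`` independent trials and aggregate their operating
    characteristics.  Replicate seeds are spawned deterministically from
    ``root_seed``."""
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    ss = root_seed if isinstance(root_seed, np.random.SeedSequence) else np.random.SeedSequence(root_seed)
    children = ss.spawn(n_sim)
    results: list[TrialResult] = []
    for i, child in enumerate(children):
        res = run_single_trial(scenario, design, method=method, seed=child, mcmc=mcmc)
        res.seed = i
        results.append(res)
    return summarize(results, scenario, method, keep_results=keep_results)


def summarize(
    results: Sequence[TrialResult],
    scenario: ScenarioSpec,
    method: str,
    keep_results: bool = False,
) -> OperatingCharacteristics:
    n = len(results)
    dec_counts = {d.value: 0 for d in _DECISIONS}
    pos_counts = {d.value: 0 for d in _DECISIONS}
    for r in results:
        dec_counts[r.decision.value] += 1
        if r.outcome.any_rejection:
            pos_counts[r.decision.value] += 1
    cond_pos = {
        d.value: (_pct(pos_counts[d.value], dec_counts[d.value]) if dec_counts[d.value] else math.nan)
        for d in _DECISIONS
    }
    f_tot = _pct(sum(r.outcome.reject_F for r in results), n)
    s_tot = _pct(sum(r.outcome.reject_S for r in results), n)
    any_rej = sum(r.outcome.any_rejection for r in results)
    targets = set(scenario.target_populations)
    if targets:
        n_power = sum(
            (("F" in targets) and r.outcome.reject_F) or (("S" in targets) and r.outcome.reject_S)
            for r in results
        )
        overall_power = _pct(n_power, n)
    else:
        overall_power = math.nan
    preferred = scenario.preferred_selection
    preferred_pct = (
        _pct(sum(r.decision.value == preferred for r in results), n) if preferred else math.nan
    )
    bias_F, bias_S = bias_summary(results)
    return OperatingCharacteristics(
        scenario_id=scenario.scenario_id,
        method=method,
        n_sim=n,
        decision_pct={k: _pct(v, n) for k, v in dec_counts.items()},
        decision_se={k: _se_pct(v, n) for k, v in dec_counts.items()},
        conditional_positive_pct=cond_pos,
        f_tot=f_tot,
        s_tot=s_tot,
        false_positive_rate=_pct(any_rej, n),
        false_positive_se=_se_pct(any_rej, n),
        overall_power=overall_power,
        preferred_pct=preferred_pct,
        bias_F=bias_F,
        bias_S=bias_S,
        n_nonconverged=sum(not r.converged for r in results),
        results=list(results) if keep_results else None,
    )


def bias_summary(results: Iterable[TrialResult]) -> tuple[float, float]:
    """Mean (estimated HR - simulated HR) per population, over the trials in
    which that population was analyzed.  NaN when never analyzed."""
    diffs: dict[str, list[float]] = {"F": [], "S": []}
    for r in results:
        for pop, hr in r.hr_estimates.items():
            diffs[pop].append(hr - r.true_hr[pop])
    return (
        float(np.mean(diffs["F"])) if diffs["F"] else math.nan,
        float(np.mean(diffs["S"])) if diffs["S"] else math.nan,
    )


def find_sample_size(
    design_template: TrialDesign,
    null_scenario: ScenarioSpec,
    alt_scenario: ScenarioSpec,
    global_sizes: Sequence[int] = tuple(range(150, 211, 10)),
    stage1_sizes: Sequence[int] = tuple(range(30, 81, 10)),
    n_sim: int = 1000,
    root_seed: int | None = None,
    alpha_bound: float = 0.05,
    power_target: float = 0.8,
    power_slack: float = 0.02,
) -> tuple[tuple[int, int] | None, pd.DataFrame]:
    """Grid search for (n_phase2, n_phase3) with the frequentist design.

    Per-arm stage sizes are scanned over ``global_sizes`` x ``stage1_sizes``;
    each cell is simulated under the null and alternative scenarios with the
    frequentist selection at thresholds 0 and a perfect assumed binary-to-
    survival correlation (the planning convention).  Returns the smallest
    qualifying cell — false positive rate <= ``alpha_bound`` (in percent,
    alpha_bound*100) and overall power >= ``power_target - power_slack`` —
    plus the full grid report.  If no cell qualifies the first element is
    None and the report carries the flag column.
    """
    plan = design_template.replace(rho=1.0, freq_tau_F_star=0.0, freq_tau_S_star=0.0)
    ss = np.random.SeedSequence(root_seed)
    rows = []
    best: tuple[int, int] | None = None
    for total in sorted(global_sizes):
        for n2 in sorted(stage1_sizes):
            n3 = total - n2
            if n3 < 1:
                continue
            d = plan.replace(n_phase2=n2, n_phase3=n3, w1=None, w2=None)
            s_null, s_alt = ss.spawn(2)
            oc_null = run_scenario(null_scenario, d, "freq", n_sim, s_null)
            oc_alt = run_scenario(alt_scenario, d, "freq", n_sim, s_alt)
            ok = (
                oc_null.false_positive_rate <= 100.0 * alpha_bound
                and oc_alt.overall_power >= 100.0 * (power_target - power_slack)
            )
            rows.append(
                {
                    "total_per_arm": total,
                    "n_phase2": n2,
                    "n_phase3": n3,
                    "false_positive_rate": oc_null.false_positive_rate,
                    "overall_power": oc_alt.overall_power,
                    "qualifies": ok,
                }
            )
            if ok and best is None:
                best = (n2, n3)
    return best, pd.DataFrame(rows)
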