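"""Final-analysis machinery: log-rank statistics, conditional error function
combination testing, and closed testing over the full population F and the
subgroup S.

The two-stage design combines the stage-1 and stage-2 survival statistics
with inverse-normal weights, S2 = w1*Z1 + w2*Z2 (w1^2 + w2^2 = 1).  Under
the joint null, (S2_F, S2_S) is bivariate standard normal with correlation
equal to the subgroup prevalence tau, so the no-early-stopping critical
value c2 solves P(max(S2_F, S2_S) >= c2) = alpha.  Because only the binary
dichotomized statistic Z1b is observed at the interim, the final rule
conditions on s1 = w1*Z1b through the assumed binary-survival correlation
rho and thresholds the stage-2 statistic alone:

    reject H0 individually  iff  Z2 > (c2 - rho * s1) / w2.

When both populations are tested, the intersection hypothesis must also be
rejected (closed testing): the intersection p-value at Zmax = max(Z2_F,
Z2_S) must fall below the conditional threshold p_thresh.
"""

from __future__ import annotations

import dataclasses
import math
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

from .design import InterimDecision, TrialDesign
from .simulate import ScenarioSpec, TrialDataset, simulate_cohort, dichotomize, make_scenario_fixture, scenario_ids
from .frequentist import binary_stage_stats

__all__ = [
    "StageStatistics",
    "FinalOutcome",
    "logrank_z",
    "combination_statistic",
    "bivariate_normal_cdf",
    "critical_value_c2",
    "conditional_critical_value",
    "intersection_pvalue",
    "intersection_threshold",
    "closed_test_decision",
    "estimate_rho",
    "estimate_hazard_ratio",
]


# ---------------------------------------------------------------------------
# log-rank statistic


class ZeroVarianceError(ValueError):
    """Raised when a log-rank variance is zero (no usable events)."""


def logrank_z(dataset_or_time, event=None, group=None, population: str | None = None) -> float:
    """One-sided log-rank z; positive values favor the treatment arm.

    Accepts either ``(dataset, population=...)`` with a
    :class:`~seamsel.simulate.TrialDataset`, or raw arrays
    ``(time, event, group)`` with group 1 = treatment.
    """
    if isinstance(dataset_or_time, TrialDataset):
        ds = dataset_or_time.subset(population or "F")
        time = ds.df["obs_time"].to_numpy(dtype=float)
        event = ds.df["event"].to_numpy(dtype=np.int64)
        group = ds.df["arm"].to_numpy(dtype=np.int64)
        label = population or "F"
    else:
        time = np.asarray(dataset_or_time, dtype=float)
        event = np.asarray(event, dtype=np.int64)
        group = np.asarray(group, dtype=np.int64)
        label = population or "?"
    if time.size == 0 or event.sum() == 0:
        raise ZeroVarianceError(f"no events in population {label}")
    treated = group == 1
    ut = np.unique(time[event == 1])
    st_all = np.sort(time)
    st1 = np.sort(time[treated])
    n_at_risk = time.size - np.searchsorted(st_all, ut, side="left")
    n1_at_risk = st1.size - np.searchsorted(st1, ut, side="left")
    et_all = np.sort(time[event == 1])
    et1 = np.sort(time[(event == 1) & treated])
    d = np.searchsorted(et_all, ut, side="right") - np.searchsorted(et_all, ut, side="left")
    d1 = np.searchsorted(et1, ut, side="right") - np.searchsorted(et1, ut, side="left")
    frac = n1_at_risk / n_at_risk
    expected = d * frac
    with np.errstate(invalid="ignore", divide="ignore"):
        var = np.where(
            n_at_risk > 1,
            d * frac * (1.0 - frac) * (n_at_risk - d) / (n_at_risk - 1.0),
            0.0,
        )
    v = var.sum()
    if v <= 0.0:
        raise ZeroVarianceError(f"log-rank variance is zero in population {label}")
    # fewer treated deaths than expected -> protective -> positive z
    return float((expected - d1).sum() / math.sqrt(v))


# ---------------------------------------------------------------------------
# combination test numerics


def combination_statistic(z_stage1: float, z_stage2: float, w1: float, w2: float) -> float:
    """Inverse-normal combination S2 = w1*Z1 + w2*Z2 (requires w1^2+w2^2=1)."""
    if abs(w1 * w1 + w2 * w2 - 1.0) > 1e-12:
        raise ValueError("combination weights must satisfy w1^2 + w2^2 = 1")
    return w1 * z_stage1 + w2 * z_stage2


def bivariate_normal_cdf(x: float, y: float, corr: float) -> float:
    """P(X <= x, Y <= y) for standard bivariate normal with correlation corr."""
    if not -1.0 <= corr <= 1.0:
        raise ValueError("correlation must be in [-1, 1]")
    if corr >= 1.0 - 1e-12:
        return float(stats.norm.cdf(min(x, y)))
    if corr <= -1.0 + 1e-12:
        return float(max(0.0, stats.norm.cdf(x) + stats.norm.cdf(y) - 1.0))
    return float(stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, corr], [corr, 1.0]]).cdf([x, y]))


@lru_cache(maxsize=256)
def critical_value_c2(tau_corr: float, alpha: float) -> float:
    """Critical value with no early efficacy stopping.

    Solves P(max(Z_F, Z_S) >= c2) = alpha for a standard bivariate normal
    pair with correlation ``tau_corr``.  Endpoints: Phi^{-1}(1-alpha) at
    tau_corr=1 (degenerate single test) and Phi^{-1}(sqrt(1-alpha)) at
    tau_corr=0 (independence).
    """
    if not 0.0 <= tau_corr <= 1.0:
        raise ValueError("tau_corr must be in [0, 1]")
    if not 0.0 < alpha < 0.5:
        raise ValueError("alpha must be in (0, 0.5)")
    lo = float(stats.norm.ppf(1.0 - alpha))
    hi = float(stats.norm.ppf(math.sqrt(1.0 - alpha)))
    if tau_corr >= 1.0 - 1e-12:
        return lo
    if tau_corr <= 1e-12:
        return hi
    f = lambda c: bivariate_normal_cdf(c, c, tau_corr) - (1.0 - alpha)
    return float(optimize.brentq(f, lo - 1e-9, hi + 1e-9, xtol=1e-10))


def conditional_critical_value(c2: float, s1: float, rho: float, w2: float) -> float:
    """Stage-2 threshold given the weighted stage-1 binary statistic s1.

    Derived from the conditional error P(S2 >= c2 | s1, H0) with the stage-1
    survival statistic replaced by its conditional projection rho * Z1b:
    reject iff Z2 > (c2 - rho * s1) / w2.
    """
    if w2 <= 0:
        raise ValueError("w2 must be positive")
    return (c2 - rho * s1) / w2


def intersection_pvalue(z_max: float, tau_corr: float) -> float:
    """p-value of the intersection null at Zmax = max(Z2_F, Z2_S).

    Equals 1 - P(Z_F <= z_max, Z_S <= z_max) under the bivariate standard
    normal with correlation ``tau_corr``; decreasing in z_max.
    """
    if not 0.0 <= tau_corr <= 1.0:
        raise ValueError("tau_corr must be in [0, 1]")
    return 1.0 - bivariate_normal_cdf(z_max, z_max, tau_corr)


def intersection_threshold(
    c2: float, s1_F: float, s1_S: float, rho: float, w2: float, tau_corr: float
) -> float:
    """Conditional critical p-value for the intersection test.

    p_thresh = 1 - P(Z2_F < (c2 - rho*s1_F)/w2, Z2_S < (c2 - rho*s1_S)/w2)
    under the bivariate standard normal with correlation ``tau_corr``.
    """
    a = conditional_critical_value(c2, s1_F, rho, w2)
    b = conditional_critical_value(c2, s1_S, rho, w2)
    return 1.0 - bivariate_normal_cdf(a, b, tau_corr)


# ---------------------------------------------------------------------------
# per-trial statistics and closed testing


@dataclasses.dataclass
class StageStatistics:
    """Every statistic of one trial's two stages (NaN where not computed)."""

    z1b_F: float = math.nan
    z1b_S: float = math.nan
    z1_F: float = math.nan
    z1_S: float = math.nan
    z2_F: float = math.nan
    z2_S: float = math.nan
    w1: float = math.nan
    w2: float = math.nan
    c2: float = math.nan
    p_intersection: float = math.nan
    p_thresh: float = math.nan

    @property
    def s1_F(self) -> float:
        return self.w1 * self.z1b_F

    @property
    def s1_S(self) -> float:
        return self.w1 * self.z1b_S

    @property
    def s2_F(self) -> float:
        return self.w1 * self.z1_F + self.w2 * self.z2_F

    @property
    def s2_S(self) -> float:
        return self.w1 * self.z1_S + self.w2 * self.z2_S

    @property
    def z_max(self) -> float:
        return max(self.z2_F, self.z2_S)

    def to_dict(self) -> dict[str, float]:
        d = dataclasses.asdict(self)
        d.update(s1_F=self.s1_F, s1_S=self.s1_S, s2_F=self.s2_F, s2_S=self.s2_S)
        return d


@dataclasses.dataclass(frozen=True)
class FinalOutcome:
    """Rejection decisions of the final analysis."""

    tested_F: bool
    tested_S: bool
    reject_F: bool
    reject_S: bool
    reject_intersection: bool
    threshold_F: float = math.nan
    threshold_S: float = math.nan

    @property
    def any_rejection(self) -> bool:
        return self.reject_F or self.reject_S


def closed_test_decision(
    stats_: StageStatistics, decision: InterimDecision, design: TrialDesign
) -> FinalOutcome:
    """Apply the conditional-error rule (and closed testing if both
    populations were selected) to one trial's statistics."""
    if decision is InterimDecision.FUTILITY:
        return FinalOutcome(False, False, False, False, False)
    tau_corr = design.subgroup_test_corr
    c2 = critical_value_c2(tau_corr, design.alpha)
    stats_.c2 = c2
    thr_F = conditional_critical_value(c2, stats_.s1_F, design.rho, design.w2)
    thr_S = conditional_critical_value(c2, stats_.s1_S, design.rho, design.w2)
    if decision is InterimDecision.F_ONLY:
        if math.isnan(stats_.z2_F):
            raise ValueError("missing stage-2 statistic for F")
        return FinalOutcome(True, False, stats_.z2_F > thr_F, False, False, threshold_F=thr_F)
    if decision is InterimDecision.S_ONLY:
        if math.isnan(stats_.z2_S):
            raise ValueError("missing stage-2 statistic for S")
        return FinalOutcome(False, True, False, stats_.z2_S > thr_S, False, threshold_S=thr_S)
    # both populations: closed testing
    if math.isnan(stats_.z2_F) or math.isnan(stats_.z2_S):
        raise ValueError("missing stage-2 statistics for the F&S analysis")
    p_int = intersection_pvalue(stats_.z_max, tau_corr)
    p_thr = intersection_threshold(c2, stats_.s1_F, stats_.s1_S, design.rho, design.w2, tau_corr)
    stats_.p_intersection = p_int
    stats_.p_thresh = p_thr
    reject_int = p_int < p_thr
    return FinalOutcome(
        True,
        True,
        reject_int and stats_.z2_F > thr_F,
        reject_int and stats_.z2_S > thr_S,
        reject_int,
        threshold_F=thr_F,
        threshold_S=thr_S,
    )


# ---------------------------------------------------------------------------
# planning-stage estimation


def estimate_rho(
    design: TrialDesign,
    scenarios: list[ScenarioSpec] | None = None,
    n_sim: int = 500,
    seed: int | None = None,
    population: str = "both",
) -> float:
    """Simulated correlation between the interim binary z and the log-rank z.

    For each replicate, one phase-II cohort is simulated; the two-proportion
    z at ``t_star`` and the log-rank z on the same patients at full
    follow-up are paired, and their Pearson correlation is computed per
    scenario (and per population, 'F', 'S' or the mean of 'both'), then
    averaged over scenarios.
    """
    if n_sim < 2:
        raise ValueError("n_sim must be >= 2")
    if scenarios is None:
        scenarios = [make_scenario_fixture(i, design.prevalence) for i in scenario_ids()]
    if population not in ("F", "S", "both"):
        raise ValueError("population must be 'F', 'S' or 'both'")
    pops = ["F", "S"] if population == "both" else [population]
    rng = np.random.default_rng(seed)
    per_scenario = []
    for scen in scenarios:
        pairs = {p: ([], []) for p in pops}
        for _ in range(n_sim):
            cohort = simulate_cohort(scen, design, "phase2", seed=rng)
            binary = dichotomize(cohort, design.t_star)
            bstats = binary_stage_stats(binary, design=design)
            # full follow-up: every event observed
            full = cohort.observed_at(cohort.df["entry_time"].max() + cohort.df["event_time"].max() + 1.0)
            for p in pops:
                zb = bstats.z_F if p == "F" else bstats.z_S
                pairs[p][0].append(zb)
                pairs[p][1].append(logrank_z(full, population=p))
        corrs = []
        for p in pops:
            zb, zs = np.asarray(pairs[p][0]), np.asarray(pairs[p][1])
            if zb.std() == 0.0 or zs.std() == 0.0:
                raise ValueError("degenerate statistic variance in rho estimation")
            corrs.append(float(np.corrcoef(zb, zs)[0, 1]))
        per_scenario.append(float(np.mean(corrs)))
    return float(np.mean(per_scenario))


def estimate_hazard_ratio(dataset: TrialDataset, population: str = "F", method: str = "exponential") -> float:
    """Treatment-vs-control hazard ratio estimate on one population.

    ``method='exponential'`` uses the constant-hazard MLE rate ratio
    (events / person-time per arm), adequate under the exponential
    simulation model; ``method='cox'`` fits a proportional-hazards partial
    likelihood (lifelines).
    """
    ds = dataset.subset(population)
    df = ds.df
    d1 = int(df.loc[df["arm"] == 1, "event"].sum())
    d0 = int(df.loc[df["arm"] == 0, "event"].sum())
    if d1 == 0 or d0 == 0:
        raise ZeroVarianceError(f"no events in one arm of population {population}")
    if method == "exponential":
        t1 = float(df.loc[df["arm"] == 1, "obs_time"].sum())
        t0 = float(df.loc[df["arm"] == 0, "obs_time"].sum())
        return (d1 / t1) / (d0 / t0)
    if method == "cox":
        from lifelines import CoxPHFitter

        cph = CoxPHFitter()
        cph.fit(df[["obs_time", "event", "arm"]], duration_col="obs_time", event_col="event")
        return float(np.exp(cph.params_["arm"]))
    raise ValueError("method must be 'exponential' or 'cox'")
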