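"""Frequentist interim comparator: two-proportion z-tests and threshold rules.

Selection at the interim mimics the Bayesian rules but thresholds the
one-sided z statistics of the survival-rate comparison in the full
population (z_F) and in the subgroup (z_S) against fixed cutoffs
(tau_F*, tau_S*): both above -> F&S, only z_S above -> S, only z_F above
-> F, neither -> futility.  A statistic exactly at its threshold does not
count as exceeding it.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from .design import InterimDecision, TrialDesign
from .simulate import TrialDataset

__all__ = ["BinaryStageStats", "binary_z_statistic", "binary_stage_stats", "interim_decision_freq"]

log = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class BinaryStageStats:
    """Stage-1 binary z statistics and the evaluable counts behind them."""

    z_F: float
    z_S: float
    counts: dict[str, tuple[int, int]]  # {"F_treat": (alive, evaluable), ...}


def binary_z_statistic(
    alive_treat: int,
    n_treat: int,
    alive_ctrl: int,
    n_ctrl: int,
    pooled: bool = True,
) -> float:
    """One-sided z for H1: treatment survival rate > control survival rate.

    Normal-approximation two-proportion statistic with pooled variance by
    default (``pooled=False`` uses the unpooled Wald variance).  Degenerate
    tables (pooled rate 0 or 1) carry no evidence either way and return 0.
    """
    if n_treat < 1 or n_ctrl < 1:
        raise ValueError("both arms need at least one evaluable patient")
    if not (0 <= alive_treat <= n_treat and 0 <= alive_ctrl <= n_ctrl):
        raise ValueError("alive counts must lie in [0, n]")
    pt, pc = alive_treat / n_treat, alive_ctrl / n_ctrl
    if pooled:
        p = (alive_treat + alive_ctrl) / (n_treat + n_ctrl)
        var = p * (1.0 - p) * (1.0 / n_treat + 1.0 / n_ctrl)
    else:
        var = pt * (1.0 - pt) / n_treat + pc * (1.0 - pc) / n_ctrl
    if var <= 0.0:
        log.info("degenerate binary table (all alive or all dead); z set to 0")
        return 0.0
    return (pt - pc) / math.sqrt(var)


def binary_stage_stats(dataset: TrialDataset, pooled: bool | None = None, design: TrialDesign | None = None) -> BinaryStageStats:
    """Compute z_F and z_S from a dichotomized stage-1 cohort."""
    df = dataset.df
    if "binary_status" not in df.columns:
        raise ValueError("dataset must be dichotomized first")
    if pooled is None:
        pooled = design.pooled_variance if design is not None else True
    counts: dict[str, tuple[int, int]] = {}
    zs: dict[str, float] = {}
    for pop, mask in (("F", np.ones(len(df), dtype=bool)), ("S", df["in_S"].to_numpy() == 1)):
        sub = df[mask]
        cells = {}
        for arm, name in ((1, "treat"), (0, "ctrl")):
            s = sub.loc[sub["arm"] == arm, "binary_status"].dropna()
            cells[name] = (int(s.sum()), int(len(s)))
            counts[f"{pop}_{name}"] = cells[name]
        zs[pop] = binary_z_statistic(*cells["treat"], *cells["ctrl"], pooled=pooled)
    return BinaryStageStats(z_F=zs["F"], z_S=zs["S"], counts=counts)


def interim_decision_freq(z_F: float, z_S: float, design: TrialDesign) -> InterimDecision:
    """Threshold-based population selection on the stage-1 binary z scale."""
    if not (math.isfinite(design.freq_tau_F_star) and math.isfinite(design.freq_tau_S_star)):
        raise ValueError("frequentist selection thresholds must be finite")
    above_S = z_S > design.freq_tau_S_star
    above_F = z_F > design.freq_tau_F_star
    if above_S and above_F:
        return InterimDecision.F_AND_S
    if above_S:
        return InterimDecision.S_ONLY
    if above_F:
        return InterimDecision.F_ONLY
    return InterimDecision.FUTILITY
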