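"""Trial design configuration: fixed constants, priors, decision labels.

A seamless phase II/III trial enrolls ``n_phase2`` patients per arm for an
interim (binary, survival-at-``t_star``) analysis and, if the trial
continues, ``n_phase3`` further patients per arm for the confirmatory
time-to-event analysis.  The interim selects the full population F, the
pre-identified biomarker subgroup S, both, or stops for futility.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from typing import Any, Mapping

__all__ = [
    "InterimDecision",
    "PriorSpec",
    "MCMCConfig",
    "TrialDesign",
    "design_from_dict",
]


class InterimDecision(enum.Enum):
    """Outcome of the interim analysis: which population enters phase III."""

    FUTILITY = "futility"
    F_ONLY = "F"
    S_ONLY = "S"
    F_AND_S = "F&S"

    @property
    def analyzes_F(self) -> bool:
        return self in (InterimDecision.F_ONLY, InterimDecision.F_AND_S)

    @property
    def analyzes_S(self) -> bool:
        return self in (InterimDecision.S_ONLY, InterimDecision.F_AND_S)


_PRIOR_FAMILIES = ("peaked_horseshoe", "flatter_horseshoe", "normal")


@dataclasses.dataclass(frozen=True)
class PriorSpec:
    """Prior on the logistic-regression coefficients (theta_S, theta_T, theta_TS).

    Horseshoe: theta_k | lambda_k, tau ~ N(0, tau^2 lambda_k^2) with local
    scale lambda_k ~ half-Cauchy(0, 1) and global scale tau ~ half-t with
    ``global_df`` degrees of freedom and scale ``global_scale`` (1 for the
    "peaked" variant, 10 for the "flatter" one).  The global scale is shared
    across the three coefficients by default (the textbook horseshoe,
    pooling evidence about overall sparsity);
    ``global_shrinkage="per_coefficient"`` gives each coefficient an
    independent global scale instead.

    Normal: theta_k ~ N(0, ``normal_variance``) independently.

    The intercept theta_0 always gets a weakly informative
    N(0, ``intercept_variance``) prior.
    """

    family: str = "peaked_horseshoe"
    global_scale: float = 1.0
    global_df: float = 1.0
    normal_variance: float = 2.0
    intercept_variance: float = 4.0
    global_shrinkage: str = "shared"  # or "per_coefficient"

    def __post_init__(self) -> None:
        if self.family not in _PRIOR_FAMILIES:
            raise ValueError(f"unknown prior family {self.family!r}; choose from {_PRIOR_FAMILIES}")
        for name in ("global_scale", "global_df", "normal_variance", "intercept_variance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.global_shrinkage not in ("per_coefficient", "shared"):
            raise ValueError("global_shrinkage must be 'per_coefficient' or 'shared'")

    @classmethod
    def peaked_horseshoe(cls, **kw: Any) -> "PriorSpec":
        return cls(family="peaked_horseshoe", global_scale=1.0, **kw)

    @classmethod
    def flatter_horseshoe(cls, **kw: Any) -> "PriorSpec":
        return cls(family="flatter_horseshoe", global_scale=10.0, **kw)

    @classmethod
    def normal(cls, variance: float = 2.0, **kw: Any) -> "PriorSpec":
        return cls(family="normal", normal_variance=variance, **kw)


@dataclasses.dataclass(frozen=True)
class MCMCConfig:
    """Posterior sampling settings.

    ``chains * draws`` is the number of pooled posterior draws retained for
    exceedance probabilities.  The ensemble sampler runs ``warmup`` discarded
    steps followed by at least ``min_steps`` retained steps (more if needed to
    reach the requested draw count), thinning evenly down to the target.
    """

    chains: int = 2
    draws: int = 500
    warmup: int = 400
    min_steps: int = 1200
    rhat_warn: float = 1.1

    def __post_init__(self) -> None:
        if self.chains < 1 or self.draws < 1 or self.warmup < 0 or self.min_steps < 1:
            raise ValueError("invalid MCMC settings")

    @property
    def n_draws(self) -> int:
        return self.chains * self.draws


@dataclasses.dataclass(frozen=True)
class TrialDesign:
    """All fixed constants of the seamless design.

    Sample sizes are PER ARM: ``n_phase2`` patients/arm at stage 1 and
    ``n_phase3`` patients/arm at stage 2, so the default (50, 140) gives a
    per-arm total of 190.  ``prevalence`` is the probability of subgroup
    membership.  ``t_star`` is the dichotomization time (months) of the
    interim binary endpoint.  ``tau_S``, ``tau_F``, ``tau_1`` are the
    posterior-probability selection thresholds, ``zeta_e`` the effect
    threshold on the log-odds scale.  ``rho`` is the assumed correlation
    between the stage-1 binary and stage-1 survival test statistics used by
    the conditional error function.  ``w1``, ``w2`` are the inverse-normal
    combination weights (w1^2 + w2^2 = 1); they default to
    sqrt(n_phase2 / (n_phase2 + n_phase3)) and its complement.
    """

    n_phase2: int = 50
    n_phase3: int = 140
    prevalence: float = 0.7
    t_star: float = 12.0
    tau_S: float = 0.5
    tau_F: float = 0.7
    tau_1: float = 0.0
    zeta_e: float = 0.0
    alpha: float = 0.025
    rho: float = 0.8
    w1: float | None = None
    w2: float | None = None
    prior: PriorSpec = dataclasses.field(default_factory=PriorSpec)
    freq_tau_S_star: float = 0.0
    freq_tau_F_star: float = 0.0
    ltfu_rate: float = 0.0
    followup_phase3: float = 12.0
    accrual_rate: float = 10.0  # patients/month, both arms combined
    subgroup_corr: str = "tau"  # corr(Z_F, Z_S): "tau" or "sqrt_tau"
    pooled_variance: bool = True  # binary z-test variance pooling
    hr_method: str = "exponential"  # HR estimator: "exponential" or "cox"

    def __post_init__(self) -> None:
        if self.n_phase2 < 1 or self.n_phase3 < 1:
            raise ValueError("per-arm sample sizes must be >= 1")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if not 0.0 < self.alpha < 0.5:
            raise ValueError("alpha must be in (0, 0.5)")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        if self.t_star < 0:
            raise ValueError("t_star must be >= 0")
        for name in ("tau_S", "tau_F", "tau_1"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.ltfu_rate < 0:
            raise ValueError("ltfu_rate must be >= 0")
        if self.accrual_rate <= 0 or self.followup_phase3 < 0:
            raise ValueError("accrual_rate must be > 0 and followup_phase3 >= 0")
        if self.subgroup_corr not in ("tau", "sqrt_tau"):
            raise ValueError("subgroup_corr must be 'tau' or 'sqrt_tau'")
        if self.hr_method not in ("exponential", "cox"):
            raise ValueError("hr_method must be 'exponential' or 'cox'")
        # derive combination weights if not supplied
        if self.w1 is None and self.w2 is None:
            w1 = math.sqrt(self.n_phase2 / (self.n_phase2 + self.n_phase3))
            object.__setattr__(self, "w1", w1)
            object.__setattr__(self, "w2", math.sqrt(1.0 - w1 * w1))
        elif self.w1 is not None and self.w2 is None:
            if not 0.0 < self.w1 < 1.0:
                raise ValueError("w1 must be in (0, 1)")
            object.__setattr__(self, "w2", math.sqrt(1.0 - self.w1**2))
        elif self.w1 is None:
            raise ValueError("give w1 (w2 is derived) or both weights")
        if abs(self.w1**2 + self.w2**2 - 1.0) > 1e-12:
            raise ValueError("combination weights must satisfy w1^2 + w2^2 = 1")

    @property
    def subgroup_test_corr(self) -> float:
        """Correlation between the F and S test statistics in the joint null."""
        if self.subgroup_corr == "tau":
            return self.prevalence
        return math.sqrt(self.prevalence)

    def replace(self, **kw: Any) -> "TrialDesign":
        return dataclasses.replace(self, **kw)


def design_from_dict(cfg: Mapping[str, Any]) -> TrialDesign:
    """Build a :class:`TrialDesign` from a (YAML/JSON-loaded) mapping.

    A ``prior`` sub-mapping is converted to :class:`PriorSpec`; a plain string
    selects one of the three named families with its default scales.
    """
    cfg = dict(cfg)
    prior = cfg.pop("prior", None)
    if prior is None:
        spec = PriorSpec()
    elif isinstance(prior, str):
        spec = {
            "peaked_horseshoe": PriorSpec.peaked_horseshoe,
            "flatter_horseshoe": PriorSpec.flatter_horseshoe,
            "normal": PriorSpec.normal,
        }[prior]()
    elif isinstance(prior, PriorSpec):
        spec = prior
    else:
        spec = PriorSpec(**prior)
    return TrialDesign(prior=spec, **cfg)
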