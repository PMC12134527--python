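"""Cohort simulation: exponential survival with a biomarker subgroup.

Event times are exponential (constant hazard).  The control hazard is
``ln 2 / control_median``; treated patients inside the subgroup S have their
hazard multiplied by ``hr_S`` and treated patients in the complement SC by
``hr_SC``.  Randomization is 1:1 and subgroup membership is Bernoulli with
the design prevalence.  Accrual is uniform at the design accrual rate;
censoring is administrative (follow-up frozen at an analysis time), plus an
optional loss-to-follow-up exponential hazard.

The interim endpoint is the survival indicator at ``t_star``: patients still
under observation at ``t_star`` count as alive (status 1), patients who died
before ``t_star`` count as dead (status 0), and patients censored before
``t_star`` are excluded from the binary comparison.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import math
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd
import yaml

from .design import TrialDesign

__all__ = [
    "ScenarioSpec",
    "TrialDataset",
    "PatientRecord",
    "hr_complement",
    "make_scenario_fixture",
    "scenario_ids",
    "simulate_cohort",
    "dichotomize",
    "read_cohort_csv",
    "write_cohort_csv",
]

LN2 = math.log(2.0)


def _survival(hr: float, control_median: float, t: float) -> float:
    """Exponential survival probability at time t under hazard ratio hr."""
    return math.exp(-hr * LN2 / control_median * t)


def hr_complement(
    hr_F: float,
    hr_S: float,
    prevalence: float,
    control_median: float = 7.0,
    t_ref: float = 12.0,
) -> float:
    """Hazard ratio for the complement SC implied by a marginal target hr_F.

    Solves for hr_SC so that the large-sample marginal survival of the
    treated full population at ``t_ref`` matches the survival implied by
    ``hr_F``:  tau * S0^hr_S + (1 - tau) * S0^hr_SC = S0^hr_F.

    When the marginal target is too harmful for any non-negative complement
    survival to satisfy the equation (possible when hr_F > 1 with a benign
    subgroup), falls back to prevalence-weighted hazard averaging:
    hr_SC = (hr_F - tau * hr_S) / (1 - tau).
    """
    if min(hr_F, hr_S, control_median, prevalence) <= 0 or prevalence >= 1:
        raise ValueError("hazard ratios, control_median > 0 and prevalence in (0,1) required")
    s0 = _survival(1.0, control_median, t_ref)
    s_sc = (_survival(hr_F, control_median, t_ref) - prevalence * _survival(hr_S, control_median, t_ref)) / (
        1.0 - prevalence
    )
    if s_sc <= 0.0:
        return (hr_F - prevalence * hr_S) / (1.0 - prevalence)
    return math.log(s_sc) / math.log(s0)


@dataclasses.dataclass(frozen=True)
class ScenarioSpec:
    """One simulation scenario: hazards in subgroup and complement.

    ``target_hr_F`` is the marginal full-population hazard-ratio target that
    ``hr_SC`` was derived from (informational); ``target_rates`` holds the
    closed-form 1-year survival rates implied by the hazards, for validation.
    ``acceptable_selections`` lists the interim decisions considered correct
    (first entry = preferred); ``target_populations`` the populations whose
    rejection counts as a correct positive.
    """

    scenario_id: int
    control_median: float
    hr_S: float
    hr_SC: float
    target_hr_F: float | None = None
    target_rates: dict[str, float] | None = None
    acceptable_selections: tuple[str, ...] = ()
    target_populations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.control_median <= 0 or self.hr_S <= 0 or self.hr_SC <= 0:
            raise ValueError("control_median and hazard ratios must be > 0")

    @property
    def preferred_selection(self) -> str | None:
        return self.acceptable_selections[0] if self.acceptable_selections else None

    def hazard(self, arm: int, in_S: bool) -> float:
        """Event hazard (per month) for a patient cell."""
        lam = LN2 / self.control_median
        if arm == 0:
            return lam
        return lam * (self.hr_S if in_S else self.hr_SC)

    def true_hr(self, population: str, prevalence: float, t_ref: float = 12.0) -> float:
        """Simulated hazard ratio of a population ('F' or 'S').

        For F this is the marginal target when one was set, otherwise the
        survival-matched marginal hazard ratio at ``t_ref``.
        """
        if population == "S":
            return self.hr_S
        if population != "F":
            raise ValueError("population must be 'F' or 'S'")
        if self.target_hr_F is not None:
            return self.target_hr_F
        s_t = prevalence * _survival(self.hr_S, self.control_median, t_ref) + (1 - prevalence) * _survival(
            self.hr_SC, self.control_median, t_ref
        )
        return math.log(s_t) / math.log(_survival(1.0, self.control_median, t_ref))


def _load_scenario_table() -> dict:
    text = importlib.resources.files("seamsel").joinpath("data/scenarios.yaml").read_text()
    return yaml.safe_load(text)


_SCENARIO_TABLE = _load_scenario_table()


def scenario_ids() -> list[int]:
    return [row["id"] for row in _SCENARIO_TABLE["scenarios"]]


def make_scenario_fixture(scenario_id: int, prevalence: float = 0.7) -> ScenarioSpec:
    """Return a packaged scenario, deriving hr_SC for the given prevalence."""
    for row in _SCENARIO_TABLE["scenarios"]:
        if row["id"] == scenario_id:
            break
    else:
        raise ValueError(f"unknown scenario id {scenario_id!r}; have {scenario_ids()}")
    cm = float(_SCENARIO_TABLE["control_median"])
    t_ref = float(_SCENARIO_TABLE["t_ref"])
    hr_F, hr_S = float(row["hr_F"]), float(row["hr_S"])
    hr_SC = hr_complement(hr_F, hr_S, prevalence, cm, t_ref)
    rates = {
        "control": _survival(1.0, cm, t_ref),
        "treatment_S": _survival(hr_S, cm, t_ref),
        "treatment_SC": _survival(hr_SC, cm, t_ref),
    }
    rates["treatment_F"] = prevalence * rates["treatment_S"] + (1 - prevalence) * rates["treatment_SC"]
    return ScenarioSpec(
        scenario_id=scenario_id,
        control_median=cm,
        hr_S=hr_S,
        hr_SC=hr_SC,
        target_hr_F=hr_F,
        target_rates=rates,
        acceptable_selections=tuple(row["acceptable_selections"]),
        target_populations=tuple(row["target_populations"]),
    )


class PatientRecord(NamedTuple):
    """Row view of one patient (see :class:`TrialDataset`)."""

    id: int
    arm: int
    in_S: int
    event_time: float
    censor_time: float
    obs_time: float
    event: int
    binary_status: float  # 1.0 alive at t*, 0.0 dead before t*, nan excluded


_LATENT_COLS = ["id", "arm", "in_S", "entry_time", "event_time", "ltfu_time"]


@dataclasses.dataclass
class TrialDataset:
    """A simulated (or imported) cohort.

    ``df`` has one row per patient with latent columns (``entry_time``,
    ``event_time``, ``ltfu_time``) when simulated, plus observed columns
    (``censor_time``, ``obs_time``, ``event`` and, after
    :func:`dichotomize`, ``binary_status``) frozen at ``analysis_time``
    (months since trial start).
    """

    df: pd.DataFrame
    stage: str
    analysis_time: float
    t_star: float | None = None  # set once dichotomized

    @property
    def n(self) -> int:
        return len(self.df)

    def subset(self, population: str) -> "TrialDataset":
        """Restrict to a population: 'F' (everyone) or 'S' (subgroup)."""
        if population == "F":
            return self
        if population != "S":
            raise ValueError("population must be 'F' or 'S'")
        return TrialDataset(
            self.df[self.df["in_S"] == 1].reset_index(drop=True),
            self.stage,
            self.analysis_time,
            self.t_star,
        )

    def observed_at(self, analysis_time: float) -> "TrialDataset":
        """Re-freeze follow-up at a later analysis time (simulated data only)."""
        if not set(_LATENT_COLS) <= set(self.df.columns) or self.df["event_time"].isna().any():
            raise ValueError("cannot extend follow-up: latent event times unavailable")
        if analysis_time < self.analysis_time:
            raise ValueError("analysis time cannot move backwards")
        df = self.df[_LATENT_COLS].copy()
        _observe(df, analysis_time)
        return TrialDataset(df, self.stage, analysis_time)

    def records(self) -> Iterator[PatientRecord]:
        b = self.df.get("binary_status", pd.Series(np.nan, index=self.df.index))
        for row, bs in zip(self.df.itertuples(index=False), b):
            yield PatientRecord(
                int(row.id), int(row.arm), int(row.in_S),
                float(row.event_time) if "event_time" in self.df else math.nan,
                float(row.censor_time), float(row.obs_time), int(row.event), float(bs),
            )


def _observe(df: pd.DataFrame, analysis_time: float) -> None:
    """Fill censor_time/obs_time/event from latent times, in place."""
    admin = analysis_time - df["entry_time"].to_numpy()
    if (admin < 0).any():
        raise ValueError("analysis time precedes some entry times")
    censor = np.minimum(admin, df["ltfu_time"].to_numpy())
    event_time = df["event_time"].to_numpy()
    obs = np.minimum(event_time, censor)
    df["censor_time"] = censor
    df["obs_time"] = obs
    df["event"] = (event_time <= censor).astype(np.int64)


def simulate_cohort(
    scenario: ScenarioSpec,
    design: TrialDesign,
    stage: str,
    n_per_arm: int | None = None,
    seed: int | np.random.Generator | None = None,
    membership: str = "mixed",
    entry_start: float = 0.0,
    analysis_time: float | None = None,
) -> TrialDataset:
    """Simulate one two-arm cohort under a scenario.

    ``membership`` is ``"mixed"`` (Bernoulli(prevalence) subgroup draws) or
    ``"S_only"`` (an enrichment cohort, every patient in S).  Entry times are
    uniform over the accrual window implied by the design accrual rate,
    starting at ``entry_start``.  The default analysis time is the moment the
    last patient completes ``t_star`` months (phase 2 interim) or the design
    minimum follow-up (phase 3); follow-up can be extended later with
    :meth:`TrialDataset.observed_at`.
    """
    if stage not in ("phase2", "phase3"):
        raise ValueError("stage must be 'phase2' or 'phase3'")
    if n_per_arm is None:
        n_per_arm = design.n_phase2 if stage == "phase2" else design.n_phase3
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be >= 1")
    if membership not in ("mixed", "S_only"):
        raise ValueError("membership must be 'mixed' or 'S_only'")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_arm
    arm = np.repeat([0, 1], n_per_arm)
    if membership == "S_only":
        in_s = np.ones(n, dtype=np.int64)
    else:
        in_s = (rng.random(n) < design.prevalence).astype(np.int64)
    lam0 = LN2 / scenario.control_median
    hr = np.where(arm == 0, 1.0, np.where(in_s == 1, scenario.hr_S, scenario.hr_SC))
    event_time = rng.exponential(1.0 / (lam0 * hr))
    accrual_window = n / design.accrual_rate
    entry = entry_start + rng.random(n) * accrual_window
    if design.ltfu_rate > 0:
        ltfu = rng.exponential(1.0 / design.ltfu_rate, size=n)
    else:
        ltfu = np.full(n, np.inf)
    if analysis_time is None:
        horizon = design.t_star if stage == "phase2" else design.followup_phase3
        analysis_time = float(entry.max()) + horizon
    df = pd.DataFrame(
        {
            "id": np.arange(n, dtype=np.int64),
            "arm": arm,
            "in_S": in_s,
            "entry_time": entry,
            "event_time": event_time,
            "ltfu_time": ltfu,
        }
    )
    _observe(df, analysis_time)
    return TrialDataset(df, stage, float(analysis_time))


def dichotomize(dataset: TrialDataset, t_star: float) -> TrialDataset:
    """Fill the binary survival status at ``t_star``.

    status 1: still under observation at ``t_star`` (alive, whether or not an
    event or censoring happened later); status 0: died before ``t_star``;
    excluded (NaN): censored alive before ``t_star``.  Idempotent.
    """
    if t_star < 0:
        raise ValueError("t_star must be >= 0")
    df = dataset.df.copy()
    obs = df["obs_time"].to_numpy(dtype=float)
    event = df["event"].to_numpy() == 1
    status = np.where(obs >= t_star, 1.0, np.where(event, 0.0, np.nan))
    df["binary_status"] = status
    return TrialDataset(df, dataset.stage, dataset.analysis_time, t_star=t_star)


_CSV_COLS = ["id", "arm", "in_S", "obs_time", "event"]


def write_cohort_csv(dataset: TrialDataset, path) -> None:
    """Emit the observed patient-level view (id, arm, in_S, obs_time, event)."""
    out = dataset.df[_CSV_COLS].copy()
    if "binary_status" in dataset.df:
        out["binary_status"] = dataset.df["binary_status"]
    out.to_csv(path, index=False)


def read_cohort_csv(path, stage: str = "phase2", analysis_time: float = math.nan) -> TrialDataset:
    """Read a patient-level CSV (columns id, arm, in_S, obs_time, event)."""
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"patient CSV is missing columns {missing}")
    if not df["arm"].isin([0, 1]).all() or not df["in_S"].isin([0, 1]).all():
        raise ValueError("arm and in_S must be 0/1 indicators")
    if (df["obs_time"] <= 0).any():
        raise ValueError("obs_time must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event must be a 0/1 indicator")
    out = df[_CSV_COLS].copy()
    out["censor_time"] = np.where(out["event"] == 1, np.inf, out["obs_time"])
    return TrialDataset(out, stage, analysis_time)
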