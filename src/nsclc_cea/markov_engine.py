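"""Three-state Markov cohort model on 3-week cycles.

States: progression-free survival (PFS), progressive disease (PD), Death.
Every patient starts in PFS.  Per-cycle transition probabilities come from
fitted parametric survival curves: the death probability is derived from the
overall-survival curve and applied identically from PFS and PD (one OS curve
exists per arm); the progression probability is the residual PFS exit
probability, floored at zero.

Accrual: drug acquisition cost follows the on-treatment fraction of the PFS
state (the PFS occupancy scaled down by the ratio of median time on
treatment to median PFS, zero beyond the treatment cap); adverse-event
management costs and disutilities are one-off at model entry; routine
follow-up applies to everyone alive; post-progression patients either
receive subsequent therapy (within a per-patient cycle cap) or best
supportive care; palliative care is charged once per incident death.  Costs
and health outcomes are discounted at an annual rate compounded per cycle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .survival_models import SurvivalFit

__all__ = [
    "ModelConfig",
    "AdverseEvent",
    "Strategy",
    "HealthInputs",
    "TransitionSchedule",
    "MarkovTrace",
    "CostBreakdown",
    "HealthOutcome",
    "EconOutcome",
    "build_transition_schedule",
    "run_trace",
    "on_treatment_fraction",
    "accrue_costs",
    "accrue_health",
    "evaluate_strategy",
]

WEEKS_PER_YEAR = 365.25 / 7.0


@dataclass(frozen=True)
class ModelConfig:
    """Model-level settings and care costs shared by all strategies."""

    cycle_length_weeks: float = 3.0
    discount_rate: float = 0.05  # annual
    max_cycles: int = 520  # 30-year cap on the lifetime horizon
    stop_threshold: float = 1e-4  # stop once the alive fraction falls below
    wtp_threshold: float = 31500.0  # USD per QALY
    weeks_per_year: float = WEEKS_PER_YEAR
    half_cycle_correction: bool = False
    followup_cost_per_cycle: float = 85.71
    supportive_cost_per_cycle: float = 338.00
    palliative_cost_per_event: float = 2464.50
    followup_in_pd: bool = True  # routine follow-up also while progressed

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ValueError("discount rate must be non-negative")
        if self.max_cycles < 1:
            raise ValueError("horizon must be at least one cycle")

    @property
    def cycle_years(self) -> float:
        return self.cycle_length_weeks / self.weeks_per_year

    def discount_factors(self, n: int) -> np.ndarray:
        k = np.arange(n)
        return (1.0 + self.discount_rate) ** (-k * self.cycle_years)


@dataclass(frozen=True)
class AdverseEvent:
    """A grade 3-4 adverse event with its frequency, cost and disutility."""

    name: str
    risk: float
    management_cost: float
    disutility: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.risk <= 1.0:
            raise ValueError("adverse-event risk must lie in [0, 1]")
        if self.management_cost < 0 or self.disutility < 0:
            raise ValueError("adverse-event cost and disutility must be non-negative")


@dataclass(frozen=True)
class Strategy:
    """A treatment strategy's drug schedule, toxicity and downstream care."""

    name: str
    induction_cost_per_cycle: float
    maintenance_cost_per_cycle: float
    induction_cycles: int = 4
    max_treatment_cycles: Optional[int] = None  # None: treat until progression
    tot_ratio: float = 1.0  # median time on treatment / median PFS
    adverse_events: tuple[AdverseEvent, ...] = ()
    subsequent_fraction: float = 0.0
    subsequent_cost_per_cycle: float = 0.0
    max_subsequent_cycles: int = 6

    def __post_init__(self) -> None:
        if min(self.induction_cost_per_cycle, self.maintenance_cost_per_cycle, self.subsequent_cost_per_cycle) < 0:
            raise ValueError("costs must be non-negative")
        if not 0.0 <= self.subsequent_fraction <= 1.0:
            raise ValueError("subsequent-therapy fraction must lie in [0, 1]")

    @property
    def ae_cost(self) -> float:
        return sum(ae.risk * ae.management_cost for ae in self.adverse_events)

    @property
    def ae_disutility(self) -> float:
        return sum(ae.risk * ae.disutility for ae in self.adverse_events)


@dataclass(frozen=True)
class HealthInputs:
    """Health-state utilities (stable disease / progressed)."""

    utility_pfs: float = 0.81
    utility_pd: float = 0.58

    def __post_init__(self) -> None:
        if not (0.0 <= self.utility_pfs <= 1.0 and 0.0 <= self.utility_pd <= 1.0):
            raise ValueError("utilities must lie in [0, 1]")


@dataclass(frozen=True)
class TransitionSchedule:
    """Per-cycle exit probabilities feeding the cohort recursion."""

    p_death: np.ndarray
    p_progress: np.ndarray

    def __post_init__(self) -> None:
        pd_, pp = np.asarray(self.p_death, float), np.asarray(self.p_progress, float)
        object.__setattr__(self, "p_death", pd_)
        object.__setattr__(self, "p_progress", pp)
        if pd_.shape != pp.shape:
            raise ValueError("p_death and p_progress must have equal length")


@dataclass(frozen=True)
class MarkovTrace:
    """Cycle-indexed occupancy of (PFS, PD, Death) plus incident streams.

    Row ``k`` is the state occupied during cycle ``k``; ``incident_deaths[k]``
    and ``incident_progressions[k]`` are arrivals at the start of cycle ``k``
    (zero at ``k = 0``).  ``p_death`` keeps the death probabilities actually
    applied, so post-progression cohorts can be aged for therapy caps.
    """

    occupancy: np.ndarray  # (n_cycles, 3)
    incident_deaths: np.ndarray
    incident_progressions: np.ndarray
    p_death: np.ndarray  # length n_cycles - 1

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0]

    @property
    def alive(self) -> np.ndarray:
        return self.occupancy[:, 0] + self.occupancy[:, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(self.n_cycles),
                "pfs": self.occupancy[:, 0],
                "pd": self.occupancy[:, 1],
                "death": self.occupancy[:, 2],
                "incident_deaths": self.incident_deaths,
                "incident_progressions": self.incident_progressions,
            }
        )


def build_transition_schedule(pfs_fit: SurvivalFit, os_fit: SurvivalFit, cfg: ModelConfig) -> TransitionSchedule:
    """Per-cycle death and progression probabilities from fitted curves.

    ``p_death(k) = 1 - S_os((k+1)D) / S_os(kD)`` applied from both alive
    states; ``p_progress`` is the extra PFS exit probability beyond death,
    floored at zero (with a warning if the PFS curve sits above the OS curve
    by more than numerical tolerance).
    """
    delta = cfg.cycle_length_weeks
    k = np.arange(cfg.max_cycles, dtype=float)
    s_os0 = np.asarray(os_fit.survival(k * delta), float)
    s_os1 = np.asarray(os_fit.survival((k + 1) * delta), float)
    s_pfs0 = np.asarray(pfs_fit.survival(k * delta), float)
    s_pfs1 = np.asarray(pfs_fit.survival((k + 1) * delta), float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_death = np.where(s_os0 > 0, 1.0 - s_os1 / s_os0, 1.0)
        p_exit_pfs = np.where(s_pfs0 > 0, 1.0 - s_pfs1 / s_pfs0, 1.0)
    p_death = np.clip(p_death, 0.0, 1.0)
    p_exit_pfs = np.clip(p_exit_pfs, 0.0, 1.0)
    residual = p_exit_pfs - p_death
    if np.any(residual < -1e-6):
        warnings.warn(
            "PFS curve lies above the OS curve over part of the horizon; progression probability floored at 0",
            stacklevel=2,
        )
    p_progress = np.maximum(residual, 0.0)
    # joint exit probability cannot exceed 1
    p_progress = np.minimum(p_progress, 1.0 - p_death)
    return TransitionSchedule(p_death, p_progress)


def run_trace(schedule: TransitionSchedule, cfg: ModelConfig) -> MarkovTrace:
    """Run the cohort recursion until the alive fraction is negligible."""
    p_death, p_progress = schedule.p_death, schedule.p_progress
    if p_death.size < 1:
        raise ValueError("schedule must cover at least one cycle")
    if np.any((p_death < 0) | (p_death > 1)) or np.any((p_progress < 0) | (p_progress > 1)):
        raise ValueError("transition probabilities must lie in [0, 1]")
    if np.any(p_death + p_progress > 1.0 + 1e-9):
        raise ValueError("joint exit probability exceeds 1")

    occ = [np.array([1.0, 0.0, 0.0])]
    inc_d = [0.0]
    inc_p = [0.0]
    applied_pd = []
    n_avail = min(p_death.size, cfg.max_cycles)
    for k in range(n_avail):
        pfs, pd_, dead = occ[-1]
        alive = pfs + pd_
        if alive < cfg.stop_threshold:
            break
        pdk, ppk = float(p_death[k]), float(p_progress[k])
        deaths = alive * pdk
        progressions = pfs * ppk
        pfs1 = pfs * (1.0 - pdk - ppk)
        pd1 = pd_ * (1.0 - pdk) + progressions
        dead1 = 1.0 - pfs1 - pd1
        occ.append(np.array([pfs1, pd1, dead1]))
        inc_d.append(deaths)
        inc_p.append(progressions)
        applied_pd.append(pdk)
    return MarkovTrace(
        occupancy=np.vstack(occ),
        incident_deaths=np.array(inc_d),
        incident_progressions=np.array(inc_p),
        p_death=np.array(applied_pd),
    )


def on_treatment_fraction(
    pfs_occupancy: np.ndarray,
    tot_ratio: float,
    max_treatment_cycles: Optional[int] = None,
) -> np.ndarray:
    """Fraction of the cohort on first-line drug in each cycle.

    The PFS occupancy is scaled by the time-on-treatment ratio (treatment
    stops earlier than progression on average) and set to zero beyond the
    treatment cap.
    """
    if tot_ratio <= 0:
        raise ValueError("time-on-treatment ratio must be positive")
    if tot_ratio > 1.0:
        warnings.warn("time-on-treatment ratio above 1 clamped to 1", stacklevel=2)
        tot_ratio = 1.0
    frac = tot_ratio * np.asarray(pfs_occupancy, float)
    if max_treatment_cycles is not None:
        k = np.arange(frac.size)
        frac = np.where(k < max_treatment_cycles, frac, 0.0)
    return frac


def _accrual_occupancy(trace: MarkovTrace, cfg: ModelConfig) -> np.ndarray:
    """State occupancy used for accrual; midpoint-averaged under half-cycle correction."""
    occ = trace.occupancy
    if not cfg.half_cycle_correction:
        return occ
    nxt = np.vstack([occ[1:], occ[-1:]])
    return 0.5 * (occ + nxt)


def _eligible_pd(trace: MarkovTrace, cap: int) -> np.ndarray:
    """PD occupancy still within ``cap`` cycles since progression.

    Cohorts progressing at cycle j decay by the death hazard; summing the
    survivors of the last ``cap`` progression cohorts gives the fraction
    still eligible for subsequent therapy.
    """
    n = trace.n_cycles
    surv = np.concatenate([[1.0], np.cumprod(1.0 - trace.p_death)])  # alive-decay from cycle 0
    eligible = np.zeros(n)
    inc_p = trace.incident_progressions
    for k in range(n):
        j_lo = max(0, k - cap + 1)
        js = np.arange(j_lo, k + 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(surv[js] > 0, surv[k] / surv[js], 0.0)
        eligible[k] = float((inc_p[js] * ratios).sum())
    return np.minimum(eligible, trace.occupancy[:, 1] + 1e-12)


@dataclass(frozen=True)
class CostBreakdown:
    """Discounted and undiscounted cost totals by component."""

    components: dict[str, float]
    components_undiscounted: dict[str, float]

    @property
    def total(self) -> float:
        return sum(self.components.values())

    @property
    def total_undiscounted(self) -> float:
        return sum(self.components_undiscounted.values())


def accrue_costs(trace: MarkovTrace, strat: Strategy, cfg: ModelConfig) -> CostBreakdown:
    """Accumulate discounted cost components over the trace."""
    if np.any(trace.occupancy < -1e-12):
        raise ValueError("negative state occupancy")
    n = trace.n_cycles
    k = np.arange(n)
    disc = cfg.discount_factors(n)
    occ = _accrual_occupancy(trace, cfg)
    pfs, pd_ = occ[:, 0], occ[:, 1]
    alive = pfs + pd_

    on_frac = on_treatment_fraction(pfs, strat.tot_ratio, strat.max_treatment_cycles)
    per_cycle_drug = np.where(k < strat.induction_cycles, strat.induction_cost_per_cycle, strat.maintenance_cost_per_cycle)
    drug = on_frac * per_cycle_drug
    followup = cfg.followup_cost_per_cycle * (alive if cfg.followup_in_pd else pfs)
    eligible = _eligible_pd(trace, strat.max_subsequent_cycles)
    subsequent = strat.subsequent_fraction * strat.subsequent_cost_per_cycle * eligible
    supportive = cfg.supportive_cost_per_cycle * (1.0 - strat.subsequent_fraction) * pd_
    palliative = cfg.palliative_cost_per_event * trace.incident_deaths
    ae = strat.ae_cost  # one-off at model entry (cycle 0, discount factor 1)

    streams = {
        "drug": drug,
        "adverse_events": None,
        "followup": followup,
        "subsequent_therapy": subsequent,
        "supportive_care": supportive,
        "palliative_care": palliative,
    }
    components = {}
    components_undisc = {}
    for name, arr in streams.items():
        if name == "adverse_events":
            components[name] = ae
            components_undisc[name] = ae
        else:
            components[name] = float((arr * disc).sum())
            components_undisc[name] = float(arr.sum())
    return CostBreakdown(components, components_undisc)


@dataclass(frozen=True)
class HealthOutcome:
    ly: float
    qaly: float
    ly_undiscounted: float
    qaly_undiscounted: float


def accrue_health(
    trace: MarkovTrace,
    health: HealthInputs,
    adverse_events: Sequence[AdverseEvent],
    cfg: ModelConfig,
) -> HealthOutcome:
    """Discounted life-years and QALYs, with a one-off adverse-event disutility."""
    n = trace.n_cycles
    disc = cfg.discount_factors(n)
    occ = _accrual_occupancy(trace, cfg)
    pfs, pd_ = occ[:, 0], occ[:, 1]
    alive = pfs + pd_
    cyc = cfg.cycle_years
    q_weights = pfs * health.utility_pfs + pd_ * health.utility_pd
    ae_dis = sum(ae.risk * ae.disutility for ae in adverse_events) * cyc  # one cycle's duration

    ly = float((alive * cyc * disc).sum())
    qaly = float((q_weights * cyc * disc).sum()) - ae_dis
    ly_u = float((alive * cyc).sum())
    qaly_u = float((q_weights * cyc).sum()) - ae_dis
    return HealthOutcome(ly, qaly, ly_u, qaly_u)


@dataclass(frozen=True)
class EconOutcome:
    """Discounted cost, life-years and QALYs for one strategy."""

    strategy: str
    cost: float
    ly: float
    qaly: float
    cost_undiscounted: float
    ly_undiscounted: float
    qaly_undiscounted: float
    cost_components: dict[str, float] = field(default_factory=dict)


def evaluate_strategy(
    strat: Strategy,
    pfs_fit: SurvivalFit,
    os_fit: SurvivalFit,
    health: HealthInputs,
    cfg: ModelConfig,
) -> EconOutcome:
    """Schedule -> trace -> cost and health accrual for one strategy."""
    schedule = build_transition_schedule(pfs_fit, os_fit, cfg)
    trace = run_trace(schedule, cfg)
    costs = accrue_costs(trace, strat, cfg)
    hlth = accrue_health(trace, health, strat.adverse_events, cfg)
    return EconOutcome(
        strategy=strat.name,
        cost=costs.total,
        ly=hlth.ly,
        qaly=hlth.qaly,
        cost_undiscounted=costs.total_undiscounted,
        ly_undiscounted=hlth.ly_undiscounted,
        qaly_undiscounted=hlth.qaly_undiscounted,
        cost_components=dict(costs.components),
    )
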