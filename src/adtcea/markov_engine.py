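"""Cohort state-transition engine: traces, accrual, and strategy evaluation.

The model tracks a cohort through four states (stable on ADT, stable off ADT,
metastatic, dead) over annual cycles.  Within a cycle, competing risks are
composed multiplicatively with other-cause death applied first: from a stable
state the cohort dies of other causes with probability ``p_other``, develops
metastases with probability ``p_met * (1 - p_other)``, and otherwise stays;
from the metastatic state it dies with probability
``1 - (1 - p_other) * (1 - p_excess)`` (other-cause or cancer) and otherwise
stays.  Survivors of the on-ADT state move to the off-ADT state after one
cycle, implementing a one-year ADT utility decrement.

Accrual follows the usual cohort conventions: per-cycle rewards (utilities,
metastatic care cost) are applied to the trapezoidal average of adjacent state
occupancies when the half-cycle correction is on, discounted by
``(1 + r)^-t``; one-time transition costs (upfront test/drug cost at cycle 0,
end-of-life cost at the cycle of death) are not half-cycle corrected.
Deaths exiting the metastatic state count as cancer deaths, so end-of-life
costs split proportionally to each strategy's cancer-specific mortality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from adtcea.model_spec import (
    Arm,
    EconomicInputs,
    HealthState,
    ModelSpec,
    MortalityInputs,
    N_STATES,
    Strategy,
)

__all__ = [
    "Trace",
    "StrategyResult",
    "build_transition_schedule",
    "run_cohort_trace",
    "accrue_costs_qalys",
    "evaluate_strategy",
    "strategy_trace",
]

ON = HealthState.STABLE_ON_ADT
OFF = HealthState.STABLE_OFF_ADT
MET = HealthState.METASTATIC
DEAD = HealthState.DEAD


@dataclass
class Trace:
    """State occupancy by cycle plus the new-death decomposition.

    ``occupancy`` has shape (T+1, 4); row t is the cohort distribution at the
    start of cycle t (row 0 is the initial distribution).  ``new_deaths_cancer``
    and ``new_deaths_other`` have length T+1; entry t is the fraction of the
    cohort dying during the step from t-1 to t, split by source state
    (metastatic = cancer death, stable = other-cause death); entry 0 is 0.
    """

    occupancy: np.ndarray
    new_deaths_cancer: np.ndarray
    new_deaths_other: np.ndarray

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per (cycle, state) with the death series."""
        T = self.horizon
        rows = []
        for t in range(T + 1):
            for s in HealthState:
                rows.append(
                    {
                        "cycle": t,
                        "state": s.name,
                        "occupancy": self.occupancy[t, s],
                        "new_deaths_cancer": self.new_deaths_cancer[t],
                        "new_deaths_other": self.new_deaths_other[t],
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class StrategyResult:
    """Expected discounted cost and QALYs per patient, plus 15-year mortality."""

    strategy_name: str
    cost: float
    qaly: float
    p_cancer_death_15y: float
    p_death_15y: float


def build_transition_schedule(
    arm: Arm, mortality: MortalityInputs, horizon: int
) -> np.ndarray:
    """Per-cycle transition matrices for one arm, shape (horizon, 4, 4).

    Matrix t governs the step from cycle t to t+1.  Rows are row-stochastic;
    DEAD is absorbing; the on-ADT row routes its staying mass to the off-ADT
    state so the ADT state is occupied for at most one cycle.

    Raises ValueError naming the cycle and row if any composed entry falls
    outside [0, 1] (possible only with invalid inputs).
    """
    p_met = np.asarray(arm.p_metastasis, dtype=float)
    p_other = np.asarray(mortality.p_death_other, dtype=float)
    p_excess = np.asarray(mortality.p_death_metastatic_excess, dtype=float)
    if len(p_met) < horizon or len(p_other) < horizon or len(p_excess) < horizon:
        raise ValueError(
            f"arm {arm.id!r}: probability schedules shorter than horizon {horizon}"
        )
    p_met = p_met[:horizon]
    p_other = p_other[:horizon]
    p_excess = p_excess[:horizon]
    to_met = p_met * (1.0 - p_other)
    stay_stable = 1.0 - to_met - p_other
    met_to_dead = 1.0 - (1.0 - p_other) * (1.0 - p_excess)
    mats = np.zeros((horizon, N_STATES, N_STATES))
    # stable on ADT: survivors not progressing move off ADT
    mats[:, ON, OFF] = stay_stable
    mats[:, ON, MET] = to_met
    mats[:, ON, DEAD] = p_other
    mats[:, OFF, OFF] = stay_stable
    mats[:, OFF, MET] = to_met
    mats[:, OFF, DEAD] = p_other
    mats[:, MET, MET] = 1.0 - met_to_dead
    mats[:, MET, DEAD] = met_to_dead
    mats[:, DEAD, DEAD] = 1.0
    if mats.min() < -1e-15 or mats.max() > 1 + 1e-15:
        t, row, _ = np.argwhere((mats < -1e-15) | (mats > 1 + 1e-15))[0]
        raise ValueError(
            f"arm {arm.id!r}: transition entry outside [0, 1] at cycle {t}, "
            f"row {HealthState(row).name}"
        )
    return mats


def run_cohort_trace(schedule: np.ndarray, init: np.ndarray) -> Trace:
    """Propagate an initial distribution through a matrix schedule.

    ``init`` must be a distribution over the four states (sums to 1).  The
    new-death series records, at each step, the probability mass entering
    DEAD from the metastatic state (cancer) and from the stable states
    (other-cause).
    """
    schedule = np.asarray(schedule, dtype=float)
    init = np.asarray(init, dtype=float)
    if init.shape != (N_STATES,) or abs(init.sum() - 1.0) > 1e-9 or np.any(init < 0):
        raise ValueError("init must be a probability distribution over the 4 states")
    T = schedule.shape[0]
    occ = np.zeros((T + 1, N_STATES))
    ndc = np.zeros(T + 1)
    ndo = np.zeros(T + 1)
    occ[0] = init
    for t in range(T):
        M = schedule[t]
        occ[t + 1] = occ[t] @ M
        ndc[t + 1] = occ[t, MET] * M[MET, DEAD]
        ndo[t + 1] = occ[t, ON] * M[ON, DEAD] + occ[t, OFF] * M[OFF, DEAD]
    return Trace(occupancy=occ, new_deaths_cancer=ndc, new_deaths_other=ndo)


def accrue_costs_qalys(
    trace: Trace,
    arm: Arm,
    econ: EconomicInputs,
    half_cycle_correction: bool = True,
    discount_rate: float | None = None,
    cycle_length: float = 1.0,
) -> tuple[float, float]:
    """Discounted cost and QALYs for one arm given its cohort trace.

    State rewards (utilities; metastatic care cost) accrue each cycle on the
    trapezoidal occupancy average when ``half_cycle_correction`` is on, on the
    end-of-cycle occupancy otherwise, discounted at ``(1+r)^-t``.  The upfront
    cost applies undiscounted at cycle 0; end-of-life costs apply at the cycle
    of death, split by cause.
    """
    r = econ.discount_rate if discount_rate is None else discount_rate
    u = np.array([econ.utility_on_adt, econ.utility_off_adt, econ.utility_metastatic, 0.0])
    c_state = np.array([0.0, 0.0, econ.cost_metastatic, 0.0])
    if np.any(u < 0) or np.any(c_state < 0) or econ.cost_eol_cancer < 0 or econ.cost_eol_noncancer < 0:
        raise ValueError("rewards (utilities, costs) must be non-negative")
    occ = trace.occupancy
    T = trace.horizon
    disc = (1.0 + r) ** (-np.arange(1, T + 1) * cycle_length)
    occ_eff = 0.5 * (occ[:-1] + occ[1:]) if half_cycle_correction else occ[1:]
    qaly = float(disc @ (occ_eff @ u)) * cycle_length
    cost = float(arm.upfront_cost)
    cost += float(disc @ (occ_eff @ c_state)) * cycle_length
    cost += float(
        disc
        @ (
            trace.new_deaths_cancer[1:] * econ.cost_eol_cancer
            + trace.new_deaths_other[1:] * econ.cost_eol_noncancer
        )
    )
    return cost, qaly


def _arm_init(arm: Arm) -> np.ndarray:
    init = np.zeros(N_STATES)
    init[ON if arm.receives_adt else OFF] = 1.0
    return init


def evaluate_strategy(strategy: Strategy, spec: ModelSpec) -> StrategyResult:
    """Component-weighted expected cost, QALYs and 15-year mortality.

    ADT-bearing arms enter the model in the stable-on-ADT state, others in
    the stable-off-ADT state.
    """
    cost = qaly = p_cancer = p_death = 0.0
    for comp in strategy.components:
        schedule = build_transition_schedule(comp.arm, spec.mortality, spec.horizon)
        trace = run_cohort_trace(schedule, _arm_init(comp.arm))
        c, q = accrue_costs_qalys(
            trace,
            comp.arm,
            spec.econ,
            half_cycle_correction=spec.half_cycle_correction,
            cycle_length=spec.cycle_length,
        )
        w = comp.weight
        cost += w * c
        qaly += w * q
        p_cancer += w * float(trace.new_deaths_cancer.sum())
        p_death += w * float(
            trace.new_deaths_cancer.sum() + trace.new_deaths_other.sum()
        )
    return StrategyResult(
        strategy_name=strategy.name,
        cost=cost,
        qaly=qaly,
        p_cancer_death_15y=p_cancer,
        p_death_15y=p_death,
    )


def strategy_trace(strategy: Strategy, spec: ModelSpec) -> Trace:
    """Component-weighted cohort trace for a whole strategy (for reporting)."""
    occ = None
    ndc = ndo = None
    for comp in strategy.components:
        schedule = build_transition_schedule(comp.arm, spec.mortality, spec.horizon)
        tr = run_cohort_trace(schedule, _arm_init(comp.arm))
        if occ is None:
            occ = comp.weight * tr.occupancy
            ndc = comp.weight * tr.new_deaths_cancer
            ndo = comp.weight * tr.new_deaths_other
        else:
            occ += comp.weight * tr.occupancy
            ndc += comp.weight * tr.new_deaths_cancer
            ndo += comp.weight * tr.new_deaths_other
    return Trace(occupancy=occ, new_deaths_cancer=ndc, new_deaths_other=ndo)
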