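"""Markov cohort trace and per-arm accrual of life-years, QALYs and costs.

The cohort starts 100% in the configured state (NYHA II at age 68).  Each
yearly cycle the occupancy vector is pushed through that cycle's transition
table; accruals follow a cycle-start convention: everyone alive at the start
of a cycle earns that cycle's full life-year, utility-weighted QALY,
background cost and drug/monitoring costs (so a death during a cycle still
accrues that cycle's person-time).  Hospitalization and death event costs
are accrued in the cycle the transition occurs.  Costs and effects are
discounted geometrically from the second cycle onward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .effects import ArmLabel, build_arm_tables
from .errors import ModelError, ValidationError
from .params import (
    CV_DEATH_IDX,
    HOSP_IDX,
    LIVING_STATES,
    NONCV_DEATH_IDX,
    DiscountSpec,
    ModelConfig,
    NYHAState,
    TransitionTable,
)

__all__ = ["CohortTrace", "ArmResults", "CycleAccrual", "discount_factor",
           "run_cohort", "run_arms"]

CONSERVATION_TOL = 1e-9


def discount_factor(cycle: int, spec: DiscountSpec) -> float:
    """1.0 before ``start_cycle``; (1+rate)^−(cycle − start_cycle + 1) after.

    With the defaults (rate 5%, start_cycle 2) the first model year is
    undiscounted and year 2 is discounted one period.
    """
    if cycle < 1:
        raise ValidationError(f"cycle index must be >= 1, got {cycle}")
    if cycle < spec.start_cycle:
        return 1.0
    return (1.0 + spec.rate) ** (-(cycle - spec.start_cycle + 1))


@dataclass
class CycleAccrual:
    """Undiscounted per-cycle accrual decomposition."""

    ly: float = 0.0
    qaly: float = 0.0
    background_cost: float = 0.0
    drug_cost: float = 0.0
    monitor_cost: float = 0.0
    hosp_cost: float = 0.0
    death_cost: float = 0.0

    @property
    def total_cost(self) -> float:
        return (self.background_cost + self.drug_cost + self.monitor_cost
                + self.hosp_cost + self.death_cost)


@dataclass
class CohortTrace:
    """Occupancy and event history of a cohort run.

    ``occupancy`` has one row per cycle start (cycle 1..horizon) plus a
    final end-of-horizon row, with columns in NYHA order I..IV then DEAD.
    """

    occupancy: np.ndarray  # (horizon + 1, 5)
    cv_deaths: np.ndarray  # per-cycle incident fractions
    noncv_deaths: np.ndarray
    hospitalizations: np.ndarray  # per-cycle hospitalization-transition mass

    def to_frame(self) -> pd.DataFrame:
        cols = [s.value for s in LIVING_STATES] + ["DEAD"]
        df = pd.DataFrame(self.occupancy, columns=cols)
        df.insert(0, "cycle_start", np.arange(1, len(df) + 1))
        events = pd.DataFrame({
            "cv_deaths": np.append(self.cv_deaths, np.nan),
            "noncv_deaths": np.append(self.noncv_deaths, np.nan),
            "hospitalizations": np.append(self.hospitalizations, np.nan),
        })
        return pd.concat([df, events], axis=1)


@dataclass
class ArmResults:
    """Per-person accumulators for one arm (cohort of size 1)."""

    arm: ArmLabel
    ly_disc: float
    ly_undisc: float
    qaly_disc: float
    qaly_undisc: float
    cost_disc: float
    cost_undisc: float
    hospitalizations_per_1000: float
    deaths_per_1000: float
    cv_deaths_per_1000: float
    noncv_deaths_per_1000: float
    trace: CohortTrace
    cycle_accruals: list[CycleAccrual] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "arm": self.arm.value,
            "ly_disc": self.ly_disc,
            "ly_undisc": self.ly_undisc,
            "qaly_disc": self.qaly_disc,
            "qaly_undisc": self.qaly_undisc,
            "cost_disc": self.cost_disc,
            "cost_undisc": self.cost_undisc,
            "hospitalizations_per_1000": self.hospitalizations_per_1000,
            "deaths_per_1000": self.deaths_per_1000,
            "cv_deaths_per_1000": self.cv_deaths_per_1000,
            "noncv_deaths_per_1000": self.noncv_deaths_per_1000,
        }


def _state_index(state: NYHAState) -> int:
    return LIVING_STATES.index(state)


def run_cohort(arm_tables: list[TransitionTable], config: ModelConfig,
               arm: ArmLabel) -> ArmResults:
    """Propagate the cohort through per-cycle tables and accrue outcomes."""
    if len(arm_tables) != config.horizon:
        raise ValidationError(
            f"need {config.horizon} per-cycle tables, got {len(arm_tables)}")

    costs = config.costs
    utilities = config.utilities.utility
    mix = config.mix.spiro_fraction

    occ = np.zeros(5)  # I, II, III, IV, DEAD
    occ[_state_index(config.start_state)] = 1.0

    occupancy = [occ.copy()]
    cv_deaths, noncv_deaths, hosps = [], [], []
    accruals: list[CycleAccrual] = []

    ly_d = ly_u = qaly_d = qaly_u = cost_d = cost_u = 0.0

    for cycle in range(1, config.horizon + 1):
        table = arm_tables[cycle - 1]
        df = discount_factor(cycle, config.discount)
        acc = CycleAccrual()

        living_start = occ[:4].copy()

        # transition the cohort
        new_living = np.zeros(4)
        cyc_cv = cyc_noncv = cyc_hosp = 0.0
        for i, state in enumerate(LIVING_STATES):
            o = living_start[i]
            if o == 0.0:
                continue
            p = table.rows[state].probs
            dest = o * p
            new_living += dest[:8].reshape(4, 2).sum(axis=1)
            cyc_hosp += dest[HOSP_IDX].sum()
            cyc_cv += dest[CV_DEATH_IDX]
            cyc_noncv += dest[NONCV_DEATH_IDX]

        # state-occupancy accruals (cycle-start convention by default)
        accruing = living_start if config.accrual == "cycle-start" else new_living
        for i, state in enumerate(LIVING_STATES):
            o = accruing[i]
            if o == 0.0:
                continue
            acc.ly += o
            acc.qaly += o * utilities[state]
            acc.background_cost += o * costs.background_annual[state]
            if arm is ArmLabel.EG:
                acc.drug_cost += o * costs.eplerenone_annual
                acc.monitor_cost += o * costs.epl_monitor(cycle)
            elif arm is ArmLabel.UCG:
                f = mix[state]
                acc.drug_cost += o * f * costs.spiro_annual
                acc.monitor_cost += o * f * costs.spiro_monitor_annual

        # event accruals in the cycle the transition occurs
        acc.hosp_cost += (cyc_hosp * costs.hosp_events_per_cycle_cap
                          * costs.hf_hosp_event)
        acc.death_cost += (cyc_cv * costs.cv_death_unit
                           + cyc_noncv * costs.noncv_death_unit)

        if not math.isfinite(acc.total_cost) or not math.isfinite(acc.ly):
            raise ModelError(f"non-finite accrual at cycle {cycle}")

        ly_u += acc.ly
        qaly_u += acc.qaly
        cost_u += acc.total_cost
        ly_d += df * acc.ly
        qaly_d += df * acc.qaly
        cost_d += df * acc.total_cost

        occ = np.empty(5)
        occ[:4] = new_living
        occ[4] = occupancy[-1][4] + cyc_cv + cyc_noncv

        if abs(occ.sum() - 1.0) > CONSERVATION_TOL:
            raise ModelError(
                f"probability mass not conserved at cycle {cycle}: {occ.sum()}")

        occupancy.append(occ.copy())
        cv_deaths.append(cyc_cv)
        noncv_deaths.append(cyc_noncv)
        hosps.append(cyc_hosp)
        accruals.append(acc)

    trace = CohortTrace(
        occupancy=np.array(occupancy),
        cv_deaths=np.array(cv_deaths),
        noncv_deaths=np.array(noncv_deaths),
        hospitalizations=np.array(hosps),
    )
    return ArmResults(
        arm=arm,
        ly_disc=ly_d, ly_undisc=ly_u,
        qaly_disc=qaly_d, qaly_undisc=qaly_u,
        cost_disc=cost_d, cost_undisc=cost_u,
        hospitalizations_per_1000=float(np.sum(hosps)) * 1000.0,
        deaths_per_1000=float(np.sum(cv_deaths) + np.sum(noncv_deaths)) * 1000.0,
        cv_deaths_per_1000=float(np.sum(cv_deaths)) * 1000.0,
        noncv_deaths_per_1000=float(np.sum(noncv_deaths)) * 1000.0,
        trace=trace,
        cycle_accruals=accruals,
    )


def run_arms(config: ModelConfig,
             include_placebo: bool = False) -> dict[ArmLabel, ArmResults]:
    """Run the eplerenone and usual-care arms (plus the placebo reference
    on request) under one configuration."""
    arms = [ArmLabel.EG, ArmLabel.UCG]
    if include_placebo:
        arms.append(ArmLabel.PLACEBO)
    out = {}
    for arm in arms:
        tables = build_arm_tables(config, arm)
        out[arm] = run_cohort(tables, config, arm)
    return out
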