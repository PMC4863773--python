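"""Patient-level microsimulation and transition-table re-estimation.

The microsimulator draws individual NYHA trajectories with per-cycle
multinomial transitions from exactly the same per-cycle tables the cohort
engine uses, so cohort-trace occupancies are the exact expectations of the
simulated state frequencies — it is the package's independent oracle.  The
companion estimators recover transition tables from event logs by
maximum-likelihood multinomial counting, closing a
simulate → estimate → re-model parameter-recovery loop.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import run_arms
from .effects import ArmLabel
from .errors import ValidationError
from .outcomes import icer
from .params import (
    LIVING_STATES,
    OUTCOME_COLUMNS,
    ModelConfig,
    NYHAState,
    TransitionRow,
    TransitionTable,
)

__all__ = ["PatientEventLog", "simulate_patients", "estimate_transition_table",
           "parameter_recovery_suite", "occupancy_from_log"]

#: outcome index -> destination living-state index (0-3) or -1 for death
_DEST = np.array([0, 0, 1, 1, 2, 2, 3, 3, -1, -1])
_HOSP_FLAG = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 0], dtype=bool)
_STATE_LABELS = [s.value for s in LIVING_STATES] + ["DEAD"]


@dataclass
class PatientEventLog:
    """Flat per-patient per-cycle event table.

    Columns: patient_id, cycle, from_state, to_state, hospitalized,
    death_cause ('' for survivors, 'cv' or 'noncv' otherwise).  Trajectories
    stop at death; cycle indices are contiguous from 1.
    """

    events: pd.DataFrame
    n_patients: int
    seed: int

    def to_csv(self, path) -> None:
        self.events.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_patients: int | None = None,
                 seed: int = -1) -> "PatientEventLog":
        df = pd.read_csv(path, keep_default_na=False)
        if n_patients is None:
            n_patients = int(df["patient_id"].nunique())
        return cls(events=df, n_patients=n_patients, seed=seed)


def simulate_patients(arm_tables: list[TransitionTable], n: int, seed: int,
                      start_state: NYHAState = NYHAState.II) -> PatientEventLog:
    """Simulate ``n`` patients through the per-cycle tables.

    Each living patient draws one of the 10 outcomes of their current row
    each cycle; draws are vectorized per (cycle, class) group and fully
    reproducible given the seed.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    state = np.full(n, LIVING_STATES.index(start_state), dtype=np.int64)
    alive = np.ones(n, dtype=bool)

    recs = {"patient_id": [], "cycle": [], "from_state": [], "to_state": [],
            "hospitalized": [], "death_cause": []}
    ids = np.arange(1, n + 1)

    for cycle, table in enumerate(arm_tables, start=1):
        if not alive.any():
            break
        state_at_cycle_start = state.copy()
        for si, s in enumerate(LIVING_STATES):
            mask = alive & (state_at_cycle_start == si)
            m = int(mask.sum())
            if m == 0:
                continue
            probs = table.rows[s].probs
            outcome = rng.choice(10, size=m, p=probs / probs.sum())
            dest = _DEST[outcome]
            died = dest < 0
            cause = np.where(outcome == 8, "cv",
                             np.where(outcome == 9, "noncv", ""))
            to_label = np.where(died, "DEAD",
                                np.array(_STATE_LABELS)[np.clip(dest, 0, 3)])
            recs["patient_id"].append(ids[mask])
            recs["cycle"].append(np.full(m, cycle))
            recs["from_state"].append(np.full(m, s.value, dtype=object))
            recs["to_state"].append(to_label)
            recs["hospitalized"].append(_HOSP_FLAG[outcome])
            recs["death_cause"].append(cause)
            # update states
            idx = np.flatnonzero(mask)
            state[idx[~died]] = dest[~died]
            alive[idx[died]] = False

    df = pd.DataFrame({k: np.concatenate(v) if v else np.array([])
                       for k, v in recs.items()})
    df = df.sort_values(["cycle", "patient_id"], ignore_index=True)
    return PatientEventLog(events=df, n_patients=n, seed=int(seed))


def occupancy_from_log(log: PatientEventLog, horizon: int) -> np.ndarray:
    """Start-of-cycle state frequencies (cycles 1..horizon+1, states
    I..IV, DEAD) implied by an event log; comparable to a cohort trace."""
    occ = np.zeros((horizon + 1, 5))
    df = log.events
    n = log.n_patients
    for c in range(1, horizon + 1):
        sub = df[df["cycle"] == c]
        counts = sub["from_state"].value_counts()
        for si, s in enumerate(LIVING_STATES):
            occ[c - 1, si] = counts.get(s.value, 0) / n
        occ[c - 1, 4] = 1.0 - occ[c - 1, :4].sum()
    last = df[df["cycle"] == horizon]
    counts = last["to_state"].value_counts()
    # end-of-horizon row: survivors' destinations + everyone already dead
    for si, s in enumerate(LIVING_STATES):
        occ[horizon, si] = counts.get(s.value, 0) / n
    occ[horizon, 4] = 1.0 - occ[horizon, :4].sum()
    return occ


def transition_counts(log: PatientEventLog, cycles: list[int] | None = None
                      ) -> dict[NYHAState, np.ndarray]:
    """Raw (from_class × outcome) transition counts over the at-risk
    person-cycles in ``cycles`` (all cycles when None); one length-10 count
    vector per living class."""
    df = log.events
    if cycles is not None:
        df = df[df["cycle"].isin(cycles)]
    out: dict[NYHAState, np.ndarray] = {}
    for s in LIVING_STATES:
        sub = df[df["from_state"] == s.value]
        counts = np.zeros(10)
        died = sub["death_cause"] != ""
        counts[8] = (sub["death_cause"] == "cv").sum()
        counts[9] = (sub["death_cause"] == "noncv").sum()
        surv = sub[~died]
        for di, d in enumerate(LIVING_STATES):
            to_d = surv[surv["to_state"] == d.value]
            hosp = to_d["hospitalized"].astype(bool)
            counts[2 * di] = (~hosp).sum()
            counts[2 * di + 1] = hosp.sum()
        out[s] = counts
    return out


def estimate_transition_table(log: PatientEventLog,
                              cycles: list[int] | None = None
                              ) -> tuple[TransitionTable | None, list[NYHAState]]:
    """Maximum-likelihood multinomial transition estimates from a log.

    Counts (from_class, outcome) transitions over the at-risk person-cycles
    in ``cycles`` (all cycles when None).  Returns the estimated table and
    the list of living classes never observed at risk (their rows are
    flagged missing, not invented; the table is None if any row is missing).
    """
    counts = transition_counts(log, cycles)
    rows: dict[NYHAState, TransitionRow] = {}
    missing: list[NYHAState] = []
    for s in LIVING_STATES:
        total = counts[s].sum()
        if total == 0:
            missing.append(s)
            continue
        rows[s] = TransitionRow(s, counts[s] / total)
    if missing:
        return None, missing
    return TransitionTable(rows, provenance="estimated"), []


def parameter_recovery_suite(config: ModelConfig, n: int, seed: int) -> dict:
    """Simulate placebo-arm event data, re-estimate the transition table,
    rebuild the model on the estimate, and report recovery error.

    Patients are simulated from the raw (constant, untrended) placebo table
    so the weighted-average estimator targets exactly the table the config
    carries; the rebuilt config then reruns the full pipeline (age trend,
    treatment effects, costing) as usual.  Reported: relative errors of
    per-arm life-years, QALYs, costs and of the ICER per QALY versus the
    truth-config outputs.
    """
    flat_tables = [config.placebo_table] * config.horizon
    log = simulate_patients(flat_tables, n=n, seed=seed,
                            start_state=config.start_state)
    est_table, missing = estimate_transition_table(log)
    if est_table is None:
        raise ValidationError(
            f"rows never observed at risk: {[s.value for s in missing]}; "
            f"increase n")

    truth_arms = run_arms(config)
    truth_icer = icer(truth_arms[ArmLabel.UCG], truth_arms[ArmLabel.EG])

    est_config = replace(config, placebo_table=est_table)
    est_arms = run_arms(est_config)
    est_icer = icer(est_arms[ArmLabel.UCG], est_arms[ArmLabel.EG])

    def rel(a, b):
        return abs(a - b) / abs(b) if b != 0 else float("nan")

    report = {
        "n_patients": n,
        "seed": int(seed),
        "icer_per_qaly_truth": truth_icer.icer_per_qaly,
        "icer_per_qaly_estimated": est_icer.icer_per_qaly,
        "icer_per_qaly_rel_error": rel(est_icer.icer_per_qaly,
                                       truth_icer.icer_per_qaly),
        "max_table_abs_error": float(max(
            np.max(np.abs(est_table.rows[s].probs
                          - config.placebo_table.rows[s].probs))
            for s in LIVING_STATES)),
    }
    for arm in (ArmLabel.EG, ArmLabel.UCG):
        for field_name in ("ly_disc", "qaly_disc", "cost_disc"):
            t = getattr(truth_arms[arm], field_name)
            e = getattr(est_arms[arm], field_name)
            report[f"{arm.value.lower()}_{field_name}_rel_error"] = rel(e, t)
    return report
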