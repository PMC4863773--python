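"""Transition-row algebra: treatment effects, usual-care mixture, age trend.

The eplerenone effect is applied by direct multiplication of hazard ratios
onto per-cycle probabilities (the modelling convention adopted here, not a
rate-to-probability conversion): hospitalization entries are scaled by the
heart-failure-hospitalization HR with the freed mass returned to the
same-destination no-hospitalization entry, and cardiovascular death is
scaled by its HR with the freed death mass redistributed proportionally
across the eight living entries.  The usual-care arm is an entry-wise convex
mixture of the placebo row and the treated row, weighted by the per-class
spironolactone usage fraction (spironolactone users are assigned
eplerenone's efficacy).
"""

from __future__ import annotations

from dataclasses import replace
from enum import Enum

import numpy as np

from .errors import InfeasibleProbabilityError, ValidationError
from .params import (
    CV_DEATH_IDX,
    HOSP_IDX,
    LIVING_IDX,
    LIVING_STATES,
    NOH_IDX,
    NONCV_DEATH_IDX,
    OUTCOME_COLUMNS,
    AgeTrend,
    HazardRatioSet,
    ModelConfig,
    TransitionRow,
    TransitionTable,
)

__all__ = [
    "ArmLabel",
    "apply_hazard_ratios",
    "blend_usual_care",
    "apply_age_trend",
    "build_arm_tables",
]

_TRANSFORM_SUM_TOL = 1e-12


class ArmLabel(Enum):
    """Model arms: eplerenone (EG), usual care (UCG), and an internal
    placebo reference arm."""

    EG = "EG"
    UCG = "UCG"
    PLACEBO = "PLACEBO"


def _check_range(probs: np.ndarray) -> None:
    bad = (probs < -1e-15) | (probs > 1 + 1e-15)
    if bad.any():
        i = int(np.argmax(bad))
        raise InfeasibleProbabilityError(OUTCOME_COLUMNS[i], float(probs[i]))


def apply_hazard_ratios(row: TransitionRow, hrs: HazardRatioSet,
                        mode: str = "cv-only") -> TransitionRow:
    """Transform a placebo row into a treated (eplerenone-efficacy) row.

    mode "cv-only": only cardiovascular death is scaled (by ``hr_cv_death``);
    non-cardiovascular death is untouched.  mode "all-cause-split": total
    death mass is scaled by ``hr_all_cause_death`` with the CV/non-CV shares
    preserved.  Either way the freed death mass is spread proportionally
    over the eight living entries, so the row still sums to 1.
    """
    if mode not in ("cv-only", "all-cause-split"):
        raise ValidationError(f"unknown hazard-ratio mode {mode!r}")
    death_hr = hrs.hr_cv_death if mode == "cv-only" else hrs.hr_all_cause_death
    if hrs.hr_hf_hosp == 1.0 and death_hr == 1.0:
        return row  # identity transform, bit-exact
    p = row.probs.copy()

    # hospitalization effect: scale the 4 hosp entries, return freed mass to
    # the same-destination no-hospitalization entries (class split preserved)
    freed_hosp = p[HOSP_IDX] * (1.0 - hrs.hr_hf_hosp)
    p[HOSP_IDX] *= hrs.hr_hf_hosp
    p[NOH_IDX] += freed_hosp

    # death effect
    if mode == "cv-only":
        new_cv = p[CV_DEATH_IDX] * hrs.hr_cv_death
        freed_death = p[CV_DEATH_IDX] - new_cv
        p[CV_DEATH_IDX] = new_cv
    elif mode == "all-cause-split":
        total = p[CV_DEATH_IDX] + p[NONCV_DEATH_IDX]
        new_total = total * hrs.hr_all_cause_death
        freed_death = total - new_total
        if total > 0:
            share_cv = p[CV_DEATH_IDX] / total
            p[CV_DEATH_IDX] = new_total * share_cv
            p[NONCV_DEATH_IDX] = new_total * (1.0 - share_cv)
    else:
        raise ValidationError(f"unknown hazard-ratio mode {mode!r}")

    living_sum = p[LIVING_IDX].sum()
    if freed_death != 0.0:
        if living_sum > 0:
            p[LIVING_IDX] *= (living_sum + freed_death) / living_sum
        else:
            # degenerate all-death row: freed mass stays in the origin class
            p[2 * LIVING_STATES.index(row.from_class)] += freed_death

    _check_range(p)
    assert abs(p.sum() - 1.0) < 1e-9
    p /= p.sum()  # kill accumulated rounding; keeps sum within 1e-12
    return replace(row, probs=p)


def blend_usual_care(placebo: TransitionRow, treated: TransitionRow,
                     spiro_fraction: float) -> TransitionRow:
    """Entry-wise convex combination: fraction × treated + (1 − f) × placebo."""
    if placebo.from_class is not treated.from_class:
        raise ValidationError("blend requires rows from the same class")
    if not 0.0 <= spiro_fraction <= 1.0:
        raise ValidationError(
            f"spiro_fraction {spiro_fraction} outside [0, 1]")
    p = spiro_fraction * treated.probs + (1.0 - spiro_fraction) * placebo.probs
    return replace(placebo, probs=p)


def apply_age_trend(row: TransitionRow, age: float, trend: AgeTrend) -> TransitionRow:
    """Scale both death risks by trend(age)/trend(baseline), rescaling the
    living entries proportionally so the row sums to 1.  Total death mass is
    capped at 1."""
    m = trend.relative(age)
    p = row.probs.copy()
    d_old = p[CV_DEATH_IDX] + p[NONCV_DEATH_IDX]
    if d_old == 0.0 or m == 1.0:
        return row
    d_new = min(d_old * m, 1.0)
    scale_death = d_new / d_old
    p[CV_DEATH_IDX] *= scale_death
    p[NONCV_DEATH_IDX] *= scale_death
    if d_old < 1.0:
        p[LIVING_IDX] *= (1.0 - d_new) / (1.0 - d_old)
    _check_range(p)
    p /= p.sum()
    return replace(row, probs=p)


def _treated_row(placebo_row: TransitionRow, config: ModelConfig,
                 cycle: int) -> TransitionRow:
    hrs = config.hrs
    if (config.hr_unity_from_cycle is not None
            and cycle >= config.hr_unity_from_cycle):
        return placebo_row
    return apply_hazard_ratios(placebo_row, hrs, mode=config.death_hr_mode)


def build_arm_tables(config: ModelConfig, arm: ArmLabel) -> list[TransitionTable]:
    """Per-cycle transition tables for an arm over the model horizon.

    For each cycle the configured placebo table (per-year table for cycles
    1–4 when supplied, weighted average otherwise) has the age trend applied
    at the cohort's age that cycle, then the treatment effect: the full
    hazard-ratio transform for the eplerenone arm, the spironolactone-usage
    mixture for usual care, nothing for the placebo reference.  With
    ``age_trend_order = "after-treatment"`` the two steps swap.
    """
    tables = []
    for cycle in range(1, config.horizon + 1):
        if (config.per_year_tables is not None
                and cycle <= len(config.per_year_tables)):
            base = config.per_year_tables[cycle - 1]
        else:
            base = config.placebo_table
        age = config.baseline_age + cycle - 1
        rows = {}
        for state in LIVING_STATES:
            placebo_row = base.rows[state]

            def _aged(r: TransitionRow) -> TransitionRow:
                return apply_age_trend(r, age, config.age_trend)

            if config.age_trend_order == "before-treatment":
                placebo_row = _aged(placebo_row)
                if arm is ArmLabel.EG:
                    out = _treated_row(placebo_row, config, cycle)
                elif arm is ArmLabel.UCG:
                    treated = _treated_row(placebo_row, config, cycle)
                    out = blend_usual_care(placebo_row, treated,
                                           config.mix.spiro_fraction[state])
                else:
                    out = placebo_row
            else:
                if arm is ArmLabel.EG:
                    out = _aged(_treated_row(placebo_row, config, cycle))
                elif arm is ArmLabel.UCG:
                    treated = _treated_row(placebo_row, config, cycle)
                    out = _aged(blend_usual_care(
                        placebo_row, treated, config.mix.spiro_fraction[state]))
                else:
                    out = _aged(placebo_row)
            rows[state] = out.validate(1e-9)
        tables.append(TransitionTable(rows=rows, provenance=base.provenance))
    return tables
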