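"""Domain types and configuration I/O for the heart-failure Markov model.

The model tracks a cohort of chronic-heart-failure patients across five
health states — alive in NYHA functional class I, II, III or IV, and dead —
in yearly cycles.  From each living class a patient faces ten mutually
exclusive per-cycle outcomes: move to one of the four living classes either
without or with a heart-failure hospitalization (8 outcomes), die of a
cardiovascular cause, or die of a non-cardiovascular cause.  Deaths within a
cycle are mutually exclusive with the non-fatal hospitalization outcomes.

This module defines the parameter types for those dynamics (transition
rows/tables, hazard ratios, the spironolactone usage mixture of the usual-care
arm, state utilities, 2014-AUD unit costs, discounting, an age trend on
mortality) together with YAML/CSV readers, validators, and the shipped
base-case parameter pack.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, NormalizationError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "NYHAState",
    "LIVING_STATES",
    "OUTCOME_COLUMNS",
    "TransitionRow",
    "TransitionTable",
    "HazardRatioSet",
    "TreatmentMix",
    "UtilitySet",
    "CostSet",
    "DiscountSpec",
    "AgeTrend",
    "ModelConfig",
    "load_config",
    "base_case_parameters",
    "validate_transition_table",
]


class NYHAState(Enum):
    """The five model health states; ``DEAD`` is absorbing."""

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    DEAD = "DEAD"

    @property
    def is_living(self) -> bool:
        return self is not NYHAState.DEAD


LIVING_STATES: tuple[NYHAState, ...] = (
    NYHAState.I,
    NYHAState.II,
    NYHAState.III,
    NYHAState.IV,
)

#: Fixed ordering of the 10 per-cycle outcomes from any living state.
OUTCOME_COLUMNS: tuple[str, ...] = (
    "toI_noh",
    "toI_h",
    "toII_noh",
    "toII_h",
    "toIII_noh",
    "toIII_h",
    "toIV_noh",
    "toIV_h",
    "cv_death",
    "noncv_death",
)

#: Indices of the 8 living-destination entries / the hospitalization entries.
LIVING_IDX = np.arange(8)
HOSP_IDX = np.array([1, 3, 5, 7])
NOH_IDX = np.array([0, 2, 4, 6])
CV_DEATH_IDX = 8
NONCV_DEATH_IDX = 9

#: sum tolerance used throughout for validated rows
ROW_SUM_TOL = 1e-9
#: |sum - 1| up to this is treated as printed rounding and renormalized
RENORM_BAND = 5e-3


@dataclass(frozen=True)
class TransitionRow:
    """The 10 per-cycle outcome probabilities from one living NYHA class.

    ``probs`` follows :data:`OUTCOME_COLUMNS`: destination class I..IV each
    split into (no hospitalization, hospitalization), then cardiovascular
    death, then non-cardiovascular death.
    """

    from_class: NYHAState
    probs: np.ndarray  # shape (10,)

    def __post_init__(self):
        if not self.from_class.is_living:
            raise ValidationError("transition rows exist only for living states")
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (10,):
            raise ValidationError(
                f"row {self.from_class.value}: expected 10 entries, got {p.shape}"
            )
        object.__setattr__(self, "probs", p)

    # -- named accessors -------------------------------------------------
    def p_dest(self, dest: NYHAState, hospitalized: bool) -> float:
        i = LIVING_STATES.index(dest) * 2 + (1 if hospitalized else 0)
        return float(self.probs[i])

    @property
    def p_cv_death(self) -> float:
        return float(self.probs[CV_DEATH_IDX])

    @property
    def p_noncv_death(self) -> float:
        return float(self.probs[NONCV_DEATH_IDX])

    @property
    def p_death(self) -> float:
        return self.p_cv_death + self.p_noncv_death

    @property
    def p_hosp(self) -> float:
        """Probability of a (non-fatal) heart-failure hospitalization."""
        return float(self.probs[HOSP_IDX].sum())

    def validate(self, tol: float = ROW_SUM_TOL) -> "TransitionRow":
        p = self.probs
        if np.any(p < -tol) or np.any(p > 1 + tol):
            bad = int(np.argmax((p < -tol) | (p > 1 + tol)))
            raise ValidationError(
                f"row {self.from_class.value}: entry {OUTCOME_COLUMNS[bad]} = "
                f"{p[bad]:.10g} outside [0, 1]"
            )
        s = float(p.sum())
        if abs(s - 1.0) > tol:
            raise NormalizationError(self.from_class.value, s, tol)
        return self

    def renormalized(self) -> "TransitionRow":
        return replace(self, probs=self.probs / self.probs.sum())

    def as_dict(self) -> dict[str, float]:
        return dict(zip(OUTCOME_COLUMNS, map(float, self.probs)))


@dataclass(frozen=True)
class TransitionTable:
    """Per-cycle transition rows for all four living classes.

    ``provenance`` distinguishes the base-case weighted-average table from
    per-year tables used in the early-cycle scenario.
    """

    rows: Mapping[NYHAState, TransitionRow]
    provenance: str = "weighted-average"

    def __post_init__(self):
        missing = [s.value for s in LIVING_STATES if s not in self.rows]
        if missing:
            raise ValidationError(f"transition table missing rows: {missing}")
        object.__setattr__(self, "rows", dict(self.rows))

    def row(self, state: NYHAState) -> TransitionRow:
        return self.rows[state]

    def validate(self, tol: float = ROW_SUM_TOL) -> "TransitionTable":
        for r in self.rows.values():
            r.validate(tol)
        return self

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for s in LIVING_STATES:
            rec = {"from_class": s.value}
            rec.update(self.rows[s].as_dict())
            recs.append(rec)
        return pd.DataFrame(recs)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "weighted-average",
                   renormalize: bool = True) -> "TransitionTable":
        rows = {}
        for _, rec in df.iterrows():
            s = NYHAState(str(rec["from_class"]))
            probs = np.array([float(rec[c]) for c in OUTCOME_COLUMNS])
            row = TransitionRow(s, probs)
            total = float(probs.sum())
            if abs(total - 1.0) > ROW_SUM_TOL:
                if renormalize and abs(total - 1.0) <= RENORM_BAND:
                    logger.warning(
                        "renormalizing row %s (sum %.6f) — printed rounding",
                        s.value, total,
                    )
                    row = row.renormalized()
                else:
                    raise NormalizationError(s.value, total, ROW_SUM_TOL)
            rows[s] = row.validate()
        return cls(rows=rows, provenance=provenance)

    @classmethod
    def from_csv(cls, path, provenance: str = "weighted-average") -> "TransitionTable":
        return cls.from_frame(pd.read_csv(path), provenance=provenance)


def validate_transition_table(table: TransitionTable,
                              tol: float = ROW_SUM_TOL) -> TransitionTable:
    """Check every row sums to 1 within ``tol`` with entries in [0, 1]."""
    return table.validate(tol)


@dataclass(frozen=True)
class HazardRatioSet:
    """Eplerenone-vs-placebo hazard ratios with 95% confidence intervals.

    Applied multiplicatively to per-cycle probabilities: heart-failure
    hospitalization entries, cardiovascular death, and (optionally) total
    death with cause shares preserved.
    """

    hr_hf_hosp: float = 0.58
    hr_hf_hosp_ci: tuple[float, float] = (0.47, 0.70)
    hr_cv_death: float = 0.76
    hr_cv_death_ci: tuple[float, float] = (0.61, 0.94)
    hr_all_cause_death: float = 0.76
    hr_all_cause_death_ci: tuple[float, float] = (0.62, 0.93)

    def __post_init__(self):
        for name in ("hr_hf_hosp", "hr_cv_death", "hr_all_cause_death"):
            point = getattr(self, name)
            lo, hi = getattr(self, name + "_ci")
            if point < 0:
                raise ValidationError(f"{name} must be >= 0, got {point}")
            if not (lo <= point <= hi):
                raise ValidationError(
                    f"{name}: CI ({lo}, {hi}) does not bracket point {point}"
                )


@dataclass(frozen=True)
class TreatmentMix:
    """Fraction of the usual-care arm on spironolactone, per NYHA class.

    Spironolactone users are assigned eplerenone's efficacy; the complement
    of each fraction behaves as placebo.
    """

    spiro_fraction: Mapping[NYHAState, float] = field(
        default_factory=lambda: {
            NYHAState.I: 0.0,
            NYHAState.II: 0.437,
            NYHAState.III: 0.937,
            NYHAState.IV: 0.937,
        }
    )

    def __post_init__(self):
        frac = dict(self.spiro_fraction)
        for s in LIVING_STATES:
            if s not in frac:
                raise ConfigError(f"mixture: missing spiro fraction for class {s.value}")
            if not 0.0 <= frac[s] <= 1.0:
                raise ValidationError(
                    f"spiro fraction for {s.value} = {frac[s]} outside [0, 1]"
                )
        object.__setattr__(self, "spiro_fraction", frac)


@dataclass(frozen=True)
class UtilitySet:
    """Health-state utility weights (EQ-5D derived), per living class."""

    utility: Mapping[NYHAState, float] = field(
        default_factory=lambda: {
            NYHAState.I: 0.815,
            NYHAState.II: 0.720,
            NYHAState.III: 0.590,
            NYHAState.IV: 0.508,
        }
    )

    def __post_init__(self):
        u = dict(self.utility)
        for s in LIVING_STATES:
            if s not in u:
                raise ConfigError(f"utilities: missing class {s.value}")
            if not 0.0 <= u[s] <= 1.0:
                raise ValidationError(f"utility for {s.value} = {u[s]} outside [0, 1]")
        object.__setattr__(self, "utility", u)


@dataclass(frozen=True)
class CostSet:
    """2014-AUD unit costs.

    ``death_event_unit`` is derived as ``death_in_hospital_fraction ×
    cvd_death_admission`` (half of deaths are assumed to occur in hospital,
    so each death is costed at half an admission) and applies to both death
    causes; ``cv_death_unit_override`` lets a scenario cost cardiovascular
    deaths at the full admission instead.  ``hosp_events_per_cycle_cap`` is
    the number of hospitalization events costed per hospitalization
    transition (base case: one).
    """

    background_annual: Mapping[NYHAState, float] = field(
        default_factory=lambda: {
            NYHAState.I: 151.0,
            NYHAState.II: 175.0,
            NYHAState.III: 226.0,
            NYHAState.IV: 242.0,
        }
    )
    hf_hosp_event: float = 7136.0
    cvd_death_admission: float = 3642.0
    death_in_hospital_fraction: float = 0.5
    eplerenone_annual: float = 1374.0
    epl_monitor_first_cycle: float = 35.60
    epl_monitor_annual: float = 71.20
    spiro_annual: float = 45.29
    spiro_monitor_annual: float = 71.20
    hosp_events_per_cycle_cap: int = 1
    cv_death_unit_override: float | None = None
    #: if True cycle 1 accrues first-cycle + annual monitoring (ambiguous
    #: year-one reading; default keeps cycle 1 = first-cycle cost only)
    first_cycle_includes_annual_monitoring: bool = False

    def __post_init__(self):
        bg = dict(self.background_annual)
        for s in LIVING_STATES:
            if s not in bg:
                raise ConfigError(f"costs: missing background cost for {s.value}")
        object.__setattr__(self, "background_annual", bg)
        for name in ("hf_hosp_event", "cvd_death_admission", "eplerenone_annual",
                     "epl_monitor_first_cycle", "epl_monitor_annual",
                     "spiro_annual", "spiro_monitor_annual"):
            if getattr(self, name) < 0:
                raise ValidationError(f"cost {name} must be >= 0")
        if not 0.0 <= self.death_in_hospital_fraction <= 1.0:
            raise ValidationError("death_in_hospital_fraction outside [0, 1]")
        if self.hosp_events_per_cycle_cap < 0:
            raise ValidationError("hosp_events_per_cycle_cap must be >= 0")

    @property
    def death_event_unit(self) -> float:
        return self.death_in_hospital_fraction * self.cvd_death_admission

    @property
    def cv_death_unit(self) -> float:
        if self.cv_death_unit_override is not None:
            return self.cv_death_unit_override
        return self.death_event_unit

    @property
    def noncv_death_unit(self) -> float:
        return self.death_event_unit

    def epl_monitor(self, cycle: int) -> float:
        if cycle == 1:
            first = self.epl_monitor_first_cycle
            if self.first_cycle_includes_annual_monitoring:
                first += self.epl_monitor_annual
            return first
        return self.epl_monitor_annual


@dataclass(frozen=True)
class DiscountSpec:
    """Geometric discounting applied from ``start_cycle`` onward.

    With the default ``start_cycle = 2`` the first model year is undiscounted
    ("after the first cycle") and cycle *c* receives
    ``(1 + rate) ** -(c - start_cycle + 1)``.
    """

    rate: float = 0.05
    start_cycle: int = 2

    def __post_init__(self):
        if self.rate < 0:
            raise ValidationError(f"discount rate must be >= 0, got {self.rate}")
        if self.start_cycle < 1:
            raise ValidationError("discount start_cycle must be >= 1")


class AgeTrend:
    """Relative mortality multiplier per integer year of age.

    Scales both cardiovascular and non-cardiovascular per-cycle death risks
    as the cohort ages from the baseline age (68 years at cycle 1), so that
    trial-derived risks pick up the background age gradient of all-cause
    mortality.  The shipped default is a stand-in: a smooth exponential
    increase per year of age (national life-table mortality grows roughly
    exponentially through old age), normalized to 1.0 at the baseline age.
    An explicit per-age table can be supplied instead.
    """

    def __init__(self, multipliers: Mapping[int, float], baseline_age: int = 68,
                 standin: bool = False):
        ages = sorted(multipliers)
        if not ages:
            raise ConfigError("age_trend: empty multiplier table")
        mult = {int(a): float(multipliers[a]) for a in ages}
        if baseline_age not in mult:
            raise ConfigError(f"age_trend: no multiplier at baseline age {baseline_age}")
        if abs(mult[baseline_age] - 1.0) > 1e-9:
            raise ValidationError(
                f"age_trend multiplier at baseline age must be 1.0, "
                f"got {mult[baseline_age]}"
            )
        if any(m <= 0 for m in mult.values()):
            raise ValidationError("age_trend multipliers must be > 0")
        self._mult = mult
        self._ages = ages
        self.baseline_age = int(baseline_age)
        self.standin = bool(standin)

    @classmethod
    def exponential(cls, annual_growth: float = 0.09, baseline_age: int = 68,
                    max_age: int = 110) -> "AgeTrend":
        """Stand-in trend: multiplier(a) = exp(growth × (a − baseline))."""
        table = {
            a: math.exp(annual_growth * (a - baseline_age))
            for a in range(baseline_age, max_age + 1)
        }
        return cls(table, baseline_age=baseline_age, standin=True)

    @classmethod
    def flat(cls, baseline_age: int = 68, max_age: int = 110) -> "AgeTrend":
        return cls({a: 1.0 for a in range(baseline_age, max_age + 1)},
                   baseline_age=baseline_age)

    def multiplier(self, age: float) -> float:
        """Multiplier at ``age``; linear interpolation between table ages,
        log-linear extension beyond the last tabulated age (never an error
        below 110)."""
        lo_age, hi_age = self._ages[0], self._ages[-1]
        if age <= lo_age:
            return self._mult[lo_age]
        if age >= hi_age:
            if len(self._ages) >= 2:
                a0, a1 = self._ages[-2], self._ages[-1]
                slope = (math.log(self._mult[a1]) - math.log(self._mult[a0])) / (a1 - a0)
                return self._mult[hi_age] * math.exp(slope * (age - hi_age))
            return self._mult[hi_age]
        return float(np.interp(age, self._ages, [self._mult[a] for a in self._ages]))

    def relative(self, age: float) -> float:
        """trend(age) / trend(baseline_age)."""
        return self.multiplier(age) / self.multiplier(self.baseline_age)

    def to_dict(self) -> dict:
        return {
            "kind": "table",
            "baseline_age": self.baseline_age,
            "standin": self.standin,
            "multipliers": {int(a): float(m) for a, m in self._mult.items()},
        }

    def __eq__(self, other):
        return (isinstance(other, AgeTrend)
                and self.baseline_age == other.baseline_age
                and self._mult == other._mult)


@dataclass(frozen=True)
class ModelConfig:
    """Complete parameter pack for a model run.

    ``per_year_tables`` optionally carries per-year placebo tables for cycles
    1–4 (scenario use); ``hr_unity_from_cycle`` reverts the treatment-effect
    hazard ratios to 1 from that cycle onward (waning-effect scenario).
    ``death_hr_mode`` selects whether the cardiovascular-death hazard ratio
    alone is applied ("cv-only", default) or total death is scaled by the
    all-cause hazard ratio with cause shares preserved ("all-cause-split").
    """

    placebo_table: TransitionTable = field(default_factory=lambda: None)  # type: ignore
    hrs: HazardRatioSet = field(default_factory=HazardRatioSet)
    mix: TreatmentMix = field(default_factory=TreatmentMix)
    utilities: UtilitySet = field(default_factory=UtilitySet)
    costs: CostSet = field(default_factory=CostSet)
    discount: DiscountSpec = field(default_factory=DiscountSpec)
    age_trend: AgeTrend = field(default_factory=AgeTrend.exponential)
    horizon: int = 10
    start_state: NYHAState = NYHAState.II
    cohort_size: int = 1000
    baseline_age: int = 68
    per_year_tables: Sequence[TransitionTable] | None = None
    hr_unity_from_cycle: int | None = None
    death_hr_mode: str = "cv-only"
    age_trend_order: str = "before-treatment"
    accrual: str = "cycle-start"

    def __post_init__(self):
        if self.placebo_table is None:
            raise ConfigError("placebo transition table is required")
        if self.horizon < 1:
            raise ConfigError(f"horizon must be >= 1, got {self.horizon}")
        if not self.start_state.is_living:
            raise ConfigError("start_state must be a living NYHA class")
        if self.death_hr_mode not in ("cv-only", "all-cause-split"):
            raise ConfigError(f"unknown death_hr_mode {self.death_hr_mode!r}")
        if self.age_trend_order not in ("before-treatment", "after-treatment"):
            raise ConfigError(f"unknown age_trend_order {self.age_trend_order!r}")
        if self.accrual not in ("cycle-start", "cycle-end"):
            raise ConfigError(f"unknown accrual convention {self.accrual!r}")
        self.placebo_table.validate()
        if self.per_year_tables is not None:
            for t in self.per_year_tables:
                t.validate()
            object.__setattr__(self, "per_year_tables", tuple(self.per_year_tables))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "model": {
                "horizon": self.horizon,
                "start_state": self.start_state.value,
                "cohort_size": self.cohort_size,
                "baseline_age": self.baseline_age,
                "death_hr_mode": self.death_hr_mode,
                "age_trend_order": self.age_trend_order,
                "accrual": self.accrual,
                "hr_unity_from_cycle": self.hr_unity_from_cycle,
            },
            "transition_table": {
                "provenance": self.placebo_table.provenance,
                "rows": {
                    s.value: self.placebo_table.rows[s].as_dict()
                    for s in LIVING_STATES
                },
            },
            "hazard_ratios": {
                "hf_hosp": {"point": self.hrs.hr_hf_hosp,
                            "lo": self.hrs.hr_hf_hosp_ci[0],
                            "hi": self.hrs.hr_hf_hosp_ci[1]},
                "cv_death": {"point": self.hrs.hr_cv_death,
                             "lo": self.hrs.hr_cv_death_ci[0],
                             "hi": self.hrs.hr_cv_death_ci[1]},
                "all_cause_death": {"point": self.hrs.hr_all_cause_death,
                                    "lo": self.hrs.hr_all_cause_death_ci[0],
                                    "hi": self.hrs.hr_all_cause_death_ci[1]},
            },
            "mixture": {s.value: self.mix.spiro_fraction[s] for s in LIVING_STATES},
            "utilities": {s.value: self.utilities.utility[s] for s in LIVING_STATES},
            "costs": {
                "background_annual": {
                    s.value: self.costs.background_annual[s] for s in LIVING_STATES
                },
                "hf_hosp_event": self.costs.hf_hosp_event,
                "cvd_death_admission": self.costs.cvd_death_admission,
                "death_in_hospital_fraction": self.costs.death_in_hospital_fraction,
                "eplerenone_annual": self.costs.eplerenone_annual,
                "epl_monitor_first_cycle": self.costs.epl_monitor_first_cycle,
                "epl_monitor_annual": self.costs.epl_monitor_annual,
                "spiro_annual": self.costs.spiro_annual,
                "spiro_monitor_annual": self.costs.spiro_monitor_annual,
                "hosp_events_per_cycle_cap": self.costs.hosp_events_per_cycle_cap,
                "cv_death_unit_override": self.costs.cv_death_unit_override,
                "first_cycle_includes_annual_monitoring":
                    self.costs.first_cycle_includes_annual_monitoring,
            },
            "discount": {"rate": self.discount.rate,
                         "start_cycle": self.discount.start_cycle},
            "age_trend": self.age_trend.to_dict(),
        }
        if self.per_year_tables is not None:
            d["per_year_tables"] = [
                {
                    "provenance": t.provenance,
                    "rows": {s.value: t.rows[s].as_dict() for s in LIVING_STATES},
                }
                for t in self.per_year_tables
            ]
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _require(section: Mapping, key: str, where: str):
    if key not in section:
        raise ConfigError(f"missing field {key!r} in section [{where}]")
    return section[key]


def _table_from_mapping(spec: Mapping, base_dir: Path | None,
                        default_provenance: str = "weighted-average") -> TransitionTable:
    provenance = spec.get("provenance", default_provenance)
    if "csv" in spec:
        csv_path = Path(spec["csv"])
        if not csv_path.is_absolute() and base_dir is not None:
            csv_path = base_dir / csv_path
        return TransitionTable.from_csv(csv_path, provenance=provenance)
    if "rows" in spec:
        recs = []
        for label, row in spec["rows"].items():
            rec = {"from_class": label}
            rec.update(row)
            recs.append(rec)
        return TransitionTable.from_frame(pd.DataFrame(recs), provenance=provenance)
    raise ConfigError("transition_table needs either 'csv' or inline 'rows'")


def _age_trend_from_mapping(spec: Mapping) -> AgeTrend:
    kind = spec.get("kind", "table")
    if kind == "exponential-standin":
        return AgeTrend.exponential(
            annual_growth=float(_require(spec, "annual_growth", "age_trend")),
            baseline_age=int(spec.get("baseline_age", 68)),
            max_age=int(spec.get("max_age", 110)),
        )
    if kind == "flat":
        return AgeTrend.flat(baseline_age=int(spec.get("baseline_age", 68)))
    if kind == "table":
        mult = _require(spec, "multipliers", "age_trend")
        return AgeTrend({int(a): float(m) for a, m in mult.items()},
                        baseline_age=int(spec.get("baseline_age", 68)),
                        standin=bool(spec.get("standin", False)))
    raise ConfigError(f"unknown age_trend kind {kind!r}")


def config_from_dict(d: Mapping, base_dir: Path | None = None) -> ModelConfig:
    """Build a validated :class:`ModelConfig` from a parsed config mapping."""
    for section in ("model", "transition_table", "hazard_ratios", "mixture",
                    "utilities", "costs", "discount", "age_trend"):
        if section not in d:
            raise ConfigError(f"missing section [{section}]")

    model = d["model"]
    table = _table_from_mapping(d["transition_table"], base_dir)

    hrs_raw = d["hazard_ratios"]

    def _hr(name):
        h = _require(hrs_raw, name, "hazard_ratios")
        return float(h["point"]), (float(h["lo"]), float(h["hi"]))

    hf, hf_ci = _hr("hf_hosp")
    cv, cv_ci = _hr("cv_death")
    ac, ac_ci = _hr("all_cause_death")
    hrs = HazardRatioSet(hr_hf_hosp=hf, hr_hf_hosp_ci=hf_ci,
                         hr_cv_death=cv, hr_cv_death_ci=cv_ci,
                         hr_all_cause_death=ac, hr_all_cause_death_ci=ac_ci)

    mix = TreatmentMix({NYHAState(k): float(v) for k, v in d["mixture"].items()})
    utilities = UtilitySet({NYHAState(k): float(v) for k, v in d["utilities"].items()})

    c = d["costs"]
    costs = CostSet(
        background_annual={
            NYHAState(k): float(v)
            for k, v in _require(c, "background_annual", "costs").items()
        },
        hf_hosp_event=float(_require(c, "hf_hosp_event", "costs")),
        cvd_death_admission=float(_require(c, "cvd_death_admission", "costs")),
        death_in_hospital_fraction=float(
            _require(c, "death_in_hospital_fraction", "costs")),
        eplerenone_annual=float(_require(c, "eplerenone_annual", "costs")),
        epl_monitor_first_cycle=float(_require(c, "epl_monitor_first_cycle", "costs")),
        epl_monitor_annual=float(_require(c, "epl_monitor_annual", "costs")),
        spiro_annual=float(_require(c, "spiro_annual", "costs")),
        spiro_monitor_annual=float(_require(c, "spiro_monitor_annual", "costs")),
        hosp_events_per_cycle_cap=int(c.get("hosp_events_per_cycle_cap", 1)),
        cv_death_unit_override=(
            None if c.get("cv_death_unit_override") is None
            else float(c["cv_death_unit_override"])),
        first_cycle_includes_annual_monitoring=bool(
            c.get("first_cycle_includes_annual_monitoring", False)),
    )
    if "death_event_unit" in c:
        stated = float(c["death_event_unit"])
        if abs(stated - costs.death_event_unit) > 1e-6:
            raise ConfigError(
                f"death_event_unit {stated} inconsistent with "
                f"death_in_hospital_fraction × cvd_death_admission = "
                f"{costs.death_event_unit}"
            )

    disc = d["discount"]
    discount = DiscountSpec(rate=float(_require(disc, "rate", "discount")),
                            start_cycle=int(disc.get("start_cycle", 2)))

    age_trend = _age_trend_from_mapping(d["age_trend"])

    per_year = None
    if "per_year_tables" in d and d["per_year_tables"]:
        per_year = [
            _table_from_mapping(t, base_dir, default_provenance="per-year")
            for t in d["per_year_tables"]
        ]

    return ModelConfig(
        placebo_table=table,
        hrs=hrs,
        mix=mix,
        utilities=utilities,
        costs=costs,
        discount=discount,
        age_trend=age_trend,
        horizon=int(_require(model, "horizon", "model")),
        start_state=NYHAState(model.get("start_state", "II")),
        cohort_size=int(model.get("cohort_size", 1000)),
        baseline_age=int(model.get("baseline_age", 68)),
        per_year_tables=per_year,
        hr_unity_from_cycle=(
            None if model.get("hr_unity_from_cycle") is None
            else int(model["hr_unity_from_cycle"])),
        death_hr_mode=model.get("death_hr_mode", "cv-only"),
        age_trend_order=model.get("age_trend_order", "before-treatment"),
        accrual=model.get("accrual", "cycle-start"),
    )


def load_config(path) -> ModelConfig:
    """Load and fully validate a YAML model configuration.

    Transition tables may be inline (``rows:``) or referenced as CSV
    relative to the config file.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: not a mapping at top level")
    return config_from_dict(raw, base_dir=path.parent)


def base_case_parameters() -> ModelConfig:
    """The shipped base-case parameter pack.

    All scalar inputs (hazard ratios, spironolactone mixture, utilities,
    unit costs, discounting, horizon, baseline age) are the published
    base-case values.  The placebo transition table and the age trend are
    synthetic stand-ins: the source trial's per-class transition table and
    the national age-trend table are not reproduced here, so plausible
    values consistent with the trial's printed aggregate event rates are
    shipped instead (see the data files' headers).
    """
    ref = resources.files("chf_cea").joinpath("data/base_case.yaml")
    with resources.as_file(ref) as p:
        return load_config(p)
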