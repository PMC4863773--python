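"""Pre-registered scenario analyses: named transforms of the base case.

Each scenario alters only its declared parameters and reruns the full
pipeline.  The registry covers a lower discount rate, truncated 2- and
4-year horizons, treatment-effect waning (all hazard ratios reverting to 1
from year 2), double hospitalization costing per cycle, costing every
cardiovascular death at a full admission, and (when per-year placebo tables
are supplied) year-specific transition probabilities for the first 4 cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

from .cohort import ArmResults, run_arms
from .effects import ArmLabel
from .errors import ConfigError, UnknownScenarioError
from .outcomes import ICERResult, icer
from .params import ModelConfig

__all__ = ["Scenario", "SCENARIOS", "list_scenarios", "run_scenario"]


@dataclass(frozen=True)
class Scenario:
    name: str
    description: str
    transform: Callable[[ModelConfig], ModelConfig]


def _discount_3pct(c: ModelConfig) -> ModelConfig:
    return replace(c, discount=replace(c.discount, rate=0.03))


def _horizon(n: int) -> Callable[[ModelConfig], ModelConfig]:
    def f(c: ModelConfig) -> ModelConfig:
        return replace(c, horizon=n)
    return f


def _hr_one_after_year2(c: ModelConfig) -> ModelConfig:
    return replace(c, hr_unity_from_cycle=2)


def _double_hospitalization(c: ModelConfig) -> ModelConfig:
    return replace(c, costs=replace(c.costs, hosp_events_per_cycle_cap=2))


def _all_deaths_in_hospital(c: ModelConfig) -> ModelConfig:
    return replace(c, costs=replace(
        c.costs, cv_death_unit_override=c.costs.cvd_death_admission))


def _yearly_tp_first4(c: ModelConfig) -> ModelConfig:
    if c.per_year_tables is None or len(c.per_year_tables) == 0:
        raise ConfigError(
            "scenario 'yearly_tp_first4' needs per-year placebo tables "
            "(config section per_year_tables), which this pack does not ship")
    return c  # build_arm_tables consumes per_year_tables when present


SCENARIOS: dict[str, Scenario] = {
    s.name: s for s in [
        Scenario("discount_3pct",
                 "3.0% annual discount rate after the first cycle",
                 _discount_3pct),
        Scenario("horizon_2y", "2-year time horizon", _horizon(2)),
        Scenario("horizon_4y", "4-year time horizon", _horizon(4)),
        Scenario("hr_one_after_year2",
                 "all treatment hazard ratios revert to 1.0 from year 2",
                 _hr_one_after_year2),
        Scenario("double_hospitalization",
                 "2 hospitalization events costed per hospitalization cycle",
                 _double_hospitalization),
        Scenario("all_deaths_in_hospital",
                 "every cardiovascular death costed at a full admission",
                 _all_deaths_in_hospital),
        Scenario("yearly_tp_first4",
                 "per-year placebo transition tables for cycles 1-4, "
                 "weighted average thereafter",
                 _yearly_tp_first4),
    ]
}


def list_scenarios() -> list[str]:
    return sorted(SCENARIOS)


def run_scenario(name: str, config: ModelConfig
                 ) -> tuple[ICERResult, dict[ArmLabel, ArmResults]]:
    """Apply the named transform and rerun both arms; returns the ICER
    result and the per-arm results."""
    if name not in SCENARIOS:
        raise UnknownScenarioError(
            f"unknown scenario {name!r}; registered: {', '.join(list_scenarios())}")
    cfg = SCENARIOS[name].transform(config)
    arms = run_arms(cfg)
    return icer(arms[ArmLabel.UCG], arms[ArmLabel.EG]), arms
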