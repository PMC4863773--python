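import numpy as np
import pytest

from chf_cea import (
    AgeTrend,
    ModelConfig,
    NYHAState,
    TransitionRow,
    TransitionTable,
    base_case_parameters,
)
from chf_cea.params import LIVING_STATES, OUTCOME_COLUMNS


def make_row(from_class: NYHAState, **entries) -> TransitionRow:
    """Build a row from named outcome entries (unnamed entries are 0)."""
    p = np.zeros(10)
    for name, v in entries.items():
        p[OUTCOME_COLUMNS.index(name)] = v
    return TransitionRow(from_class, p)


def uniform_table(**entries) -> TransitionTable:
    """Table with the same outcome probabilities from every living class."""
    return TransitionTable(
        {s: make_row(s, **entries) for s in LIVING_STATES})


@pytest.fixture(scope="session")
def base_config() -> ModelConfig:
    return base_case_parameters()


@pytest.fixture
def simple_table() -> TransitionTable:
    """Small hand-checkable dynamics: stay, progress, or die."""
    return uniform_table(toII_noh=0.55, toII_h=0.20, toIII_noh=0.10,
                         toIII_h=0.05, cv_death=0.06, noncv_death=0.04)


@pytest.fixture
def flat_trend_config(simple_table) -> ModelConfig:
    """Config with no age trend, for hand-arithmetic checks."""
    return ModelConfig(placebo_table=simple_table, age_trend=AgeTrend.flat())
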