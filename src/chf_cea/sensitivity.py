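"""Deterministic and probabilistic sensitivity analysis.

One-way DSA reruns the full model at the low and high value of one
parameter at a time (95% confidence limits where published — the three
hazard ratios — otherwise ±50% of the base value) and orders parameters by
the width of the resulting ICER range (tornado ordering).

PSA assigns each uncertain parameter a distribution by family — utilities
beta (method-of-moments from the base value and SE = range/3.92), costs
uniform over the range, transition probabilities triangular with mode at
the base value — and Monte-Carlo samples all of them jointly, rerunning
both arms per iteration.  Treatment drug and monitoring costs are held
fixed.  Sampled transition rows are renormalized entry-wise to sum to 1,
and the NYHA IV row stays tied to the NYHA III row (the structural
assumption of the base case).  Outputs: incremental cost/effect scatter,
cost-effectiveness acceptability curve (CEAC), percentile ICER intervals
restricted to the positive-effect quadrant, and net-monetary-benefit
intervals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import run_arms
from .effects import ArmLabel
from .errors import ConfigError, ModelError
from .outcomes import icer
from .params import (
    LIVING_STATES,
    OUTCOME_COLUMNS,
    CostSet,
    ModelConfig,
    NYHAState,
    TransitionRow,
    TransitionTable,
    UtilitySet,
)

logger = logging.getLogger(__name__)

__all__ = ["DSASpec", "PSADistribution", "PSAResult", "default_dsa_specs",
           "run_dsa", "build_psa_distributions", "run_psa",
           "get_param", "set_param"]


# ---------------------------------------------------------------------------
# parameter paths
# ---------------------------------------------------------------------------

def get_param(config: ModelConfig, path: str) -> float:
    """Read a scalar model parameter by dotted path.

    Supported roots: ``hrs.<name>``, ``utilities.<class>``, ``mix.<class>``,
    ``discount.rate``, ``costs.<field>``, ``costs.background_annual.<class>``,
    ``transition.<class>.<outcome>``.
    """
    parts = path.split(".")
    root = parts[0]
    if root == "hrs":
        return float(getattr(config.hrs, parts[1]))
    if root == "utilities":
        return float(config.utilities.utility[NYHAState(parts[1])])
    if root == "mix":
        return float(config.mix.spiro_fraction[NYHAState(parts[1])])
    if root == "discount" and parts[1] == "rate":
        return float(config.discount.rate)
    if root == "costs":
        if parts[1] == "background_annual":
            return float(config.costs.background_annual[NYHAState(parts[2])])
        return float(getattr(config.costs, parts[1]))
    if root == "transition":
        row = config.placebo_table.rows[NYHAState(parts[1])]
        return float(row.probs[OUTCOME_COLUMNS.index(parts[2])])
    raise ConfigError(f"unknown parameter path {path!r}")


def set_param(config: ModelConfig, path: str, value: float) -> ModelConfig:
    """Return a new config with one scalar parameter replaced.

    Setting a ``transition.*`` entry renormalizes that row afterwards so it
    remains a probability row (and mirrors it to NYHA IV when the target is
    the NYHA III row and IV is tied to III in the base table).
    """
    parts = path.split(".")
    root = parts[0]
    if root == "hrs":
        return replace(config, hrs=replace(config.hrs, **{parts[1]: value}))
    if root == "utilities":
        u = dict(config.utilities.utility)
        u[NYHAState(parts[1])] = value
        return replace(config, utilities=UtilitySet(u))
    if root == "mix":
        f = dict(config.mix.spiro_fraction)
        f[NYHAState(parts[1])] = value
        return replace(config, mix=replace(config.mix, spiro_fraction=f))
    if root == "discount" and parts[1] == "rate":
        return replace(config, discount=replace(config.discount, rate=value))
    if root == "costs":
        if parts[1] == "background_annual":
            bg = dict(config.costs.background_annual)
            bg[NYHAState(parts[2])] = value
            return replace(config, costs=replace(config.costs,
                                                 background_annual=bg))
        return replace(config, costs=replace(config.costs, **{parts[1]: value}))
    if root == "transition":
        state = NYHAState(parts[1])
        col = OUTCOME_COLUMNS.index(parts[2])
        rows = dict(config.placebo_table.rows)
        iv_tied = np.allclose(rows[NYHAState.III].probs, rows[NYHAState.IV].probs)
        p = rows[state].probs.copy()
        p[col] = value
        row = TransitionRow(state, p / p.sum())
        rows[state] = row
        if state is NYHAState.III and iv_tied:
            rows[NYHAState.IV] = TransitionRow(NYHAState.IV, row.probs.copy())
        table = TransitionTable(rows, provenance=config.placebo_table.provenance)
        return replace(config, placebo_table=table)
    raise ConfigError(f"unknown parameter path {path!r}")


# ---------------------------------------------------------------------------
# deterministic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DSASpec:
    """One-way variation of a single parameter."""

    path: str
    low: float
    high: float
    label: str = ""

    def __post_init__(self):
        if self.low > self.high:
            raise ConfigError(f"DSA {self.path}: low {self.low} > high {self.high}")
        if not self.label:
            object.__setattr__(self, "label", self.path)


def default_dsa_specs(config: ModelConfig) -> list[DSASpec]:
    """95% confidence limits for the hazard ratios; ±50% of base for
    utilities (capped at 1), unit costs and spironolactone fractions."""
    specs = [
        DSASpec("hrs.hr_hf_hosp", *config.hrs.hr_hf_hosp_ci,
                label="HR heart-failure hospitalization (95% CI)"),
        DSASpec("hrs.hr_cv_death", *config.hrs.hr_cv_death_ci,
                label="HR cardiovascular death (95% CI)"),
        DSASpec("hrs.hr_all_cause_death", *config.hrs.hr_all_cause_death_ci,
                label="HR all-cause death (95% CI)"),
        DSASpec("discount.rate", 0.0, 0.075, label="discount rate 0-7.5%"),
    ]
    for s in LIVING_STATES:
        u = config.utilities.utility[s]
        specs.append(DSASpec(f"utilities.{s.value}", 0.5 * u, min(1.5 * u, 1.0),
                             label=f"utility NYHA {s.value} (±50%)"))
    for path, label in [("costs.hf_hosp_event", "hospitalization cost (±50%)"),
                        ("costs.cvd_death_admission", "CVD death admission cost (±50%)")]:
        b = get_param(config, path)
        specs.append(DSASpec(path, 0.5 * b, 1.5 * b, label=label))
    for s in LIVING_STATES:
        b = config.costs.background_annual[s]
        specs.append(DSASpec(f"costs.background_annual.{s.value}",
                             0.5 * b, 1.5 * b,
                             label=f"background cost NYHA {s.value} (±50%)"))
    for s in (NYHAState.II, NYHAState.III):
        f = config.mix.spiro_fraction[s]
        if f > 0:
            specs.append(DSASpec(f"mix.{s.value}", 0.5 * f, min(1.5 * f, 1.0),
                                 label=f"spironolactone fraction NYHA {s.value} (±50%)"))
    return specs


def _icer_pair(config: ModelConfig) -> tuple[float, float]:
    arms = run_arms(config)
    r = icer(arms[ArmLabel.UCG], arms[ArmLabel.EG])
    return r.icer_per_yols, r.icer_per_qaly


def run_dsa(config: ModelConfig,
            specs: Sequence[DSASpec] | None = None) -> pd.DataFrame:
    """One-way DSA table, tornado-ordered by ICER-per-QALY range width.

    An infeasible bound (perturbation breaks a probability constraint) is
    recorded as NaN for that bound and the run continues.
    """
    if specs is None:
        specs = default_dsa_specs(config)
    base_yols, base_qaly = _icer_pair(config)
    records = []
    for spec in specs:
        rec = {"parameter": spec.label, "path": spec.path,
               "low_value": spec.low, "high_value": spec.high,
               "base_icer_yols": base_yols, "base_icer_qaly": base_qaly}
        for bound, value in (("low", spec.low), ("high", spec.high)):
            try:
                y, q = _icer_pair(set_param(config, spec.path, value))
            except ModelError as exc:
                logger.warning("DSA %s %s bound infeasible: %s",
                               spec.path, bound, exc)
                y = q = math.nan
            rec[f"icer_yols_{bound}"] = y
            rec[f"icer_qaly_{bound}"] = q
        rec["range_qaly"] = abs(rec["icer_qaly_high"] - rec["icer_qaly_low"])
        records.append(rec)
    df = pd.DataFrame(records)
    return df.sort_values("range_qaly", ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSADistribution:
    """Sampling distribution of one parameter.

    family: beta (args a, b), uniform (args lo, hi) or triangular
    (args lo, mode, hi).  A zero-width range collapses to a point mass at
    the base value whatever the family.
    """

    path: str
    family: str
    base: float
    args: Mapping[str, float] = field(default_factory=dict)

    def sample(self, rng: np.random.Generator) -> float:
        a = self.args
        if self.family == "point":
            return self.base
        if self.family == "beta":
            return float(rng.beta(a["a"], a["b"]))
        if self.family == "uniform":
            if a["hi"] == a["lo"]:
                return self.base
            return float(rng.uniform(a["lo"], a["hi"]))
        if self.family == "triangular":
            if a["hi"] == a["lo"]:
                return self.base
            return float(rng.triangular(a["lo"], a["mode"], a["hi"]))
        raise ConfigError(f"unknown distribution family {self.family!r}")


def _beta_from_moments(path: str, mean: float, se: float) -> PSADistribution:
    if se == 0.0 or mean in (0.0, 1.0):
        return PSADistribution(path, "point", mean)
    var = se * se
    k = mean * (1.0 - mean) / var - 1.0
    if k <= 0:
        logger.warning("beta moment-matching infeasible for %s "
                       "(mean %.4g, se %.4g); falling back to uniform",
                       path, mean, se)
        lo = max(mean - 1.96 * se, 0.0)
        hi = min(mean + 1.96 * se, 1.0)
        return PSADistribution(path, "uniform", mean, {"lo": lo, "hi": hi})
    return PSADistribution(path, "beta", mean,
                           {"a": mean * k, "b": (1.0 - mean) * k})


def build_psa_distributions(config: ModelConfig,
                            rel_width: float = 0.5) -> list[PSADistribution]:
    """Distributions for every PSA-varied parameter.

    ``rel_width`` is the half-width of the variation range relative to the
    base value (default ±50%); 0 makes every distribution degenerate at
    the base value.  Probabilities and utilities are capped at 1.
    Eplerenone/spironolactone drug and monitoring costs are fixed and get
    no distribution.
    """
    dists: list[PSADistribution] = []
    for s in LIVING_STATES:
        u = config.utilities.utility[s]
        lo, hi = (1 - rel_width) * u, min((1 + rel_width) * u, 1.0)
        dists.append(_beta_from_moments(f"utilities.{s.value}", u,
                                        (hi - lo) / (2 * 1.96)))
    cost_paths = (["costs.hf_hosp_event", "costs.cvd_death_admission"]
                  + [f"costs.background_annual.{s.value}" for s in LIVING_STATES])
    for path in cost_paths:
        b = get_param(config, path)
        dists.append(PSADistribution(path, "uniform", b,
                                     {"lo": (1 - rel_width) * b,
                                      "hi": (1 + rel_width) * b}))
    # transition rows I-III; IV remains tied to III via set-time mirroring
    for s in (NYHAState.I, NYHAState.II, NYHAState.III):
        for col in OUTCOME_COLUMNS:
            p = get_param(config, f"transition.{s.value}.{col}")
            if p == 0.0:
                continue
            dists.append(PSADistribution(
                f"transition.{s.value}.{col}", "triangular", p,
                {"lo": (1 - rel_width) * p, "mode": p,
                 "hi": min((1 + rel_width) * p, 1.0)}))
    return dists


def _sampled_config(config: ModelConfig, dists: Sequence[PSADistribution],
                    rng: np.random.Generator) -> ModelConfig:
    """Sample every distribution and assemble one coherent config."""
    utilities = dict(config.utilities.utility)
    cost_kwargs: dict[str, float] = {}
    bg = dict(config.costs.background_annual)
    trans: dict[NYHAState, np.ndarray] = {
        s: config.placebo_table.rows[s].probs.copy()
        for s in LIVING_STATES
    }
    changed: set[NYHAState] = set()
    iv_tied = np.allclose(trans[NYHAState.III], trans[NYHAState.IV])

    for d in dists:
        v = d.sample(rng)
        parts = d.path.split(".")
        if parts[0] == "utilities":
            utilities[NYHAState(parts[1])] = min(max(v, 0.0), 1.0)
        elif parts[0] == "costs" and parts[1] == "background_annual":
            bg[NYHAState(parts[2])] = max(v, 0.0)
        elif parts[0] == "costs":
            cost_kwargs[parts[1]] = max(v, 0.0)
        elif parts[0] == "transition":
            s = NYHAState(parts[1])
            col = OUTCOME_COLUMNS.index(parts[2])
            if v != trans[s][col]:
                trans[s][col] = v
                changed.add(s)
        else:
            raise ConfigError(f"unsupported PSA path {d.path!r}")

    rows = {}
    for s in LIVING_STATES:
        p = trans[s]
        # renormalize only genuinely perturbed rows; a degenerate draw must
        # reproduce the base row bit-for-bit
        rows[s] = TransitionRow(s, p / p.sum() if s in changed else p)
    if iv_tied:
        rows[NYHAState.IV] = TransitionRow(NYHAState.IV,
                                           rows[NYHAState.III].probs.copy())
    table = TransitionTable(rows, provenance=config.placebo_table.provenance)
    costs = replace(config.costs, background_annual=bg, **cost_kwargs)
    return replace(config, placebo_table=table, costs=costs,
                   utilities=UtilitySet(utilities))


@dataclass
class PSAResult:
    """Monte-Carlo PSA output.

    Per-iteration incremental (cost, life-years, QALYs) of eplerenone vs
    usual care, the CEAC over a threshold grid, the fraction cost-effective
    at the headline willingness-to-pay threshold, and percentile intervals.
    ICER percentile intervals are taken over iterations in the
    positive-effect quadrant; ``quadrants`` reports the composition.
    """

    delta_cost: np.ndarray
    delta_ly: np.ndarray
    delta_qaly: np.ndarray
    ceac: dict[float, float]
    threshold: float
    pct_ce_at_threshold: float
    icer_ci_yols: tuple[float, float]
    icer_ci_qaly: tuple[float, float]
    nmb_ci: tuple[float, float]
    quadrants: dict[str, int]
    n_iter: int
    n_failed: int
    seed: int

    def scatter_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iteration": np.arange(1, len(self.delta_cost) + 1),
            "delta_cost": self.delta_cost,
            "delta_ly": self.delta_ly,
            "delta_qaly": self.delta_qaly,
        })

    def ceac_frame(self) -> pd.DataFrame:
        thresholds = sorted(self.ceac)
        return pd.DataFrame({"threshold": thresholds,
                             "fraction_cost_effective":
                                 [self.ceac[t] for t in thresholds]})

    def summary(self) -> dict:
        return {
            "n_iter": self.n_iter,
            "n_failed": self.n_failed,
            "seed": self.seed,
            "threshold": self.threshold,
            "pct_ce_at_threshold": self.pct_ce_at_threshold,
            "mean_delta_cost": float(np.mean(self.delta_cost)),
            "mean_delta_ly": float(np.mean(self.delta_ly)),
            "mean_delta_qaly": float(np.mean(self.delta_qaly)),
            "icer_ci_yols": list(self.icer_ci_yols),
            "icer_ci_qaly": list(self.icer_ci_qaly),
            "nmb_ci": list(self.nmb_ci),
            "quadrants": self.quadrants,
        }


def _pct_interval(values: np.ndarray) -> tuple[float, float]:
    if len(values) == 0:
        return (math.nan, math.nan)
    return (float(np.percentile(values, 2.5)),
            float(np.percentile(values, 97.5)))


def run_psa(config: ModelConfig, n_iter: int = 10_000, seed: int = 0,
            thresholds: Sequence[float] | None = None,
            threshold: float = 50_000.0,
            dists: Sequence[PSADistribution] | None = None) -> PSAResult:
    """Monte-Carlo probabilistic sensitivity analysis.

    One seeded generator drives the run; each iteration draws from its own
    counter-derived substream, so results are reproducible and independent
    of execution order.
    """
    if n_iter < 1:
        raise ConfigError("n_iter must be >= 1")
    if dists is None:
        dists = build_psa_distributions(config)
    if thresholds is None:
        thresholds = np.arange(0.0, 100_000.1, 2_500.0)

    dc = np.empty(n_iter)
    dly = np.empty(n_iter)
    dq = np.empty(n_iter)
    n_failed = 0
    kept = 0
    for i in range(n_iter):
        rng = np.random.Generator(np.random.PCG64(
            np.random.SeedSequence([int(seed), i])))
        try:
            cfg = _sampled_config(config, dists, rng)
            arms = run_arms(cfg)
            r = icer(arms[ArmLabel.UCG], arms[ArmLabel.EG])
        except ModelError:
            n_failed += 1
            continue
        dc[kept], dly[kept], dq[kept] = r.delta_cost, r.delta_ly, r.delta_qaly
        kept += 1
    dc, dly, dq = dc[:kept], dly[:kept], dq[:kept]

    ceac = {}
    for lam in thresholds:
        ceac[float(lam)] = float(np.mean(lam * dq - dc >= 0)) if kept else math.nan
    pct_ce = float(np.mean(threshold * dq - dc >= 0)) if kept else math.nan

    pos_q = dq > 0
    pos_ly = dly > 0
    quadrants = {
        "pos_effect_pos_cost": int(np.sum(pos_q & (dc > 0))),
        "pos_effect_neg_cost": int(np.sum(pos_q & (dc <= 0))),
        "neg_effect_pos_cost": int(np.sum(~pos_q & (dc > 0))),
        "neg_effect_neg_cost": int(np.sum(~pos_q & (dc <= 0))),
    }
    nmb = threshold * dq - dc
    return PSAResult(
        delta_cost=dc, delta_ly=dly, delta_qaly=dq,
        ceac=ceac, threshold=float(threshold), pct_ce_at_threshold=pct_ce,
        icer_ci_yols=_pct_interval(dc[pos_ly] / dly[pos_ly]),
        icer_ci_qaly=_pct_interval(dc[pos_q] / dq[pos_q]),
        nmb_ci=_pct_interval(nmb),
        quadrants=quadrants,
        n_iter=n_iter, n_failed=n_failed, seed=int(seed),
    )
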