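"""Incremental economics: ICERs, events averted, number needed to treat.

ICERs are computed from full-precision discounted deltas (never from
display-rounded intermediates): incremental cost divided by incremental
life-years (cost per year of life saved) and by incremental QALYs.
Dominance is classified by the sign quadrant of (ΔC, ΔE).  NNT is the
reciprocal of the per-person cumulative risk difference over the horizon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .cohort import ArmResults

__all__ = ["ICERResult", "EventDiff", "icer", "event_diff"]


@dataclass(frozen=True)
class ICERResult:
    """Incremental cost-effectiveness of intervention vs reference."""

    delta_cost: float
    delta_ly: float
    delta_qaly: float
    icer_per_yols: float  # nan when delta_ly == 0
    icer_per_qaly: float  # nan when delta_qaly == 0
    dominance: str  # none | intervention-dominant | intervention-dominated

    def as_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_ly": self.delta_ly,
            "delta_qaly": self.delta_qaly,
            "icer_per_yols": self.icer_per_yols,
            "icer_per_qaly": self.icer_per_qaly,
            "dominance": self.dominance,
        }


@dataclass(frozen=True)
class EventDiff:
    """Events averted by the intervention, per 1000 starting patients,
    with raw and display-rounded NNTs."""

    hospitalizations_averted_per_1000: float
    deaths_averted_per_1000: float
    nnt_hosp: float  # nan when no hospitalizations averted
    nnt_death: float
    nnt_hosp_display: float
    nnt_death_display: float

    def as_dict(self) -> dict:
        return {
            "hospitalizations_averted_per_1000":
                self.hospitalizations_averted_per_1000,
            "deaths_averted_per_1000": self.deaths_averted_per_1000,
            "nnt_hosp": self.nnt_hosp,
            "nnt_death": self.nnt_death,
            "nnt_hosp_display": self.nnt_hosp_display,
            "nnt_death_display": self.nnt_death_display,
        }


def _classify_dominance(delta_cost: float, delta_ly: float,
                        delta_qaly: float) -> str:
    eff_pos = delta_ly > 0 or delta_qaly > 0
    eff_neg = delta_ly < 0 or delta_qaly < 0
    if delta_cost < 0 and eff_pos and not eff_neg:
        return "intervention-dominant"
    if delta_cost > 0 and eff_neg and not eff_pos:
        return "intervention-dominated"
    return "none"


def icer(reference: ArmResults, intervention: ArmResults) -> ICERResult:
    """Incremental cost-effectiveness ratios on discounted outcomes.

    A zero effect delta yields a NaN ratio (flagged undefined), never an
    exception.
    """
    dc = intervention.cost_disc - reference.cost_disc
    dly = intervention.ly_disc - reference.ly_disc
    dq = intervention.qaly_disc - reference.qaly_disc
    return ICERResult(
        delta_cost=dc,
        delta_ly=dly,
        delta_qaly=dq,
        icer_per_yols=dc / dly if dly != 0 else math.nan,
        icer_per_qaly=dc / dq if dq != 0 else math.nan,
        dominance=_classify_dominance(dc, dly, dq),
    )


def event_diff(reference: ArmResults, intervention: ArmResults) -> EventDiff:
    """Hospitalizations and deaths averted per 1000 over the horizon, and
    the NNT (1000 / averted-per-1000); NNT is NaN when no events averted."""
    hosp_av = (reference.hospitalizations_per_1000
               - intervention.hospitalizations_per_1000)
    death_av = reference.deaths_per_1000 - intervention.deaths_per_1000
    nnt_h = 1000.0 / hosp_av if hosp_av > 0 else math.nan
    nnt_d = 1000.0 / death_av if death_av > 0 else math.nan
    return EventDiff(
        hospitalizations_averted_per_1000=hosp_av,
        deaths_averted_per_1000=death_av,
        nnt_hosp=nnt_h,
        nnt_death=nnt_d,
        nnt_hosp_display=round(nnt_h, 1) if not math.isnan(nnt_h) else math.nan,
        nnt_death_display=round(nnt_d, 1) if not math.isnan(nnt_d) else math.nan,
    )
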