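"""Structured result serialization: run reports, CSV exports, display rounding.

Reports are JSON (diff-able regression fixtures) with anything tabular or
plottable — cohort traces, PSA scatter, CEAC — exported as CSV.  Display
rounding (whole AUD for ICERs, one decimal for life-years/QALYs/NNT) happens
only at this layer; every internal quantity is full precision.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from .cohort import ArmResults
from .effects import ArmLabel
from .outcomes import EventDiff, ICERResult
from .params import ModelConfig

__all__ = ["RunReport", "config_hash", "display_round"]

PACKAGE_VERSION = "0.1.0"


def config_hash(config: ModelConfig) -> str:
    """Deterministic SHA-256 of the canonicalized config mapping."""
    canon = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def _clean(obj):
    """Make a structure JSON-safe (NaN -> None, numpy scalars -> python)."""
    if isinstance(obj, dict):
        return {str(k): _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if hasattr(obj, "item"):
        return _clean(obj.item())
    return obj


def display_round(value: float, kind: str) -> float | None:
    """Presentation rounding: 'aud' to whole dollars, 'years'/'nnt' to one
    decimal, 'fraction' to three decimals."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if kind == "aud":
        return round(value)
    if kind in ("years", "nnt"):
        return round(value, 1)
    if kind == "fraction":
        return round(value, 3)
    raise ValueError(f"unknown display kind {kind!r}")


@dataclass
class RunReport:
    """Aggregated, serializable record of one analysis run."""

    config: ModelConfig
    arms: dict[ArmLabel, ArmResults]
    icer: ICERResult
    events: EventDiff
    seed: int | None = None
    dsa_table: object | None = None  # pandas DataFrame
    psa_summary: dict | None = None
    scenario_results: dict[str, ICERResult] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "package_version": PACKAGE_VERSION,
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "config_hash": config_hash(self.config),
            "seed": self.seed,
            "arms": {a.value: r.summary() for a, r in self.arms.items()},
            "incremental": self.icer.as_dict(),
            "events": self.events.as_dict(),
            "display": {
                "icer_per_yols_aud": display_round(self.icer.icer_per_yols, "aud"),
                "icer_per_qaly_aud": display_round(self.icer.icer_per_qaly, "aud"),
                "delta_cost_aud": display_round(self.icer.delta_cost, "aud"),
                "delta_ly": round(self.icer.delta_ly, 2),
                "delta_qaly": round(self.icer.delta_qaly, 2),
                "nnt_hosp": display_round(self.events.nnt_hosp, "nnt"),
                "nnt_death": display_round(self.events.nnt_death, "nnt"),
            },
        }
        if self.psa_summary is not None:
            d["psa"] = self.psa_summary
        if self.scenario_results:
            d["scenarios"] = {k: v.as_dict()
                              for k, v in self.scenario_results.items()}
        return _clean(d)

    def write(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        if self.dsa_table is not None:
            self.dsa_table.to_csv(path.with_name(path.stem + "_dsa.csv"),
                                  index=False)

    def write_traces(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for arm, res in self.arms.items():
            res.trace.to_frame().to_csv(
                out_dir / f"trace_{arm.value.lower()}.csv", index=False)
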