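"""File formats: CSV for curves/panels/cohorts, JSON for params/maps/regions.

The CAT domain has no entrenched interchange format, so the package settles
on explicitly headered CSV for tabular data and flat JSON for fitted
objects.  Every writer here has a matching reader and round-trips exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .controller import GCMRecommendation
from .model import CATCurve, ThrombinModelParams
from .cohortstats import PatientTimeline
from .region import NormalRegion
from .regression import FACTORS, FactorPanel, RegressionMap

__all__ = [
    "read_curve", "write_curve", "read_params", "write_params",
    "validate_panel_file", "write_panels", "read_map", "write_map",
    "read_region", "write_region", "write_recommendation",
    "read_cohort", "write_cohort", "read_scenario_yaml",
    "PanelFileError",
]

_CURVE_COLS = ["time_min", "thrombin_nM"]
_COHORT_COLS = ["patient_id", "outcome", "time_h", *FACTORS]


class PanelFileError(ValueError):
    """A panel CSV violates the expected schema."""


def write_curve(curve: CATCurve, path) -> None:
    pd.DataFrame({"time_min": curve.times,
                  "thrombin_nM": curve.thrombin}).to_csv(path, index=False)


def read_curve(path) -> CATCurve:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _CURVE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing curve columns {missing}")
    return CATCurve(df["time_min"].to_numpy(float),
                    df["thrombin_nM"].to_numpy(float))


def write_params(params: ThrombinModelParams, path) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=2) + "\n")


def read_params(path) -> ThrombinModelParams:
    return ThrombinModelParams.from_dict(json.loads(Path(path).read_text()))


def write_panels(panels: list[FactorPanel], path) -> None:
    pd.DataFrame([p.to_dict() for p in panels]).to_csv(path, index=False)


def validate_panel_file(path) -> list[FactorPanel]:
    """Parse a factor-panel CSV (eight factor columns, % activity).

    Missing columns, non-numeric cells, and negative values are rejected
    with diagnostics naming the column and row.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in FACTORS if c not in df.columns]
    if missing:
        raise PanelFileError(f"{path}: missing column(s) {missing}")
    panels = []
    for i, row in df.iterrows():
        vals = {}
        for c in FACTORS:
            v = pd.to_numeric(pd.Series([row[c]]), errors="coerce").iloc[0]
            if pd.isna(v):
                raise PanelFileError(
                    f"{path}: row {i}: non-numeric value {row[c]!r} in {c}")
            if v < 0:
                raise PanelFileError(
                    f"{path}: row {i}: negative value {v} in {c}")
            vals[c] = float(v)
        panels.append(FactorPanel(**vals))
    if not panels:
        raise PanelFileError(f"{path}: no panel rows")
    return panels


def write_map(map: RegressionMap, path) -> None:
    Path(path).write_text(json.dumps(map.to_dict(), indent=2) + "\n")


def read_map(path) -> RegressionMap:
    return RegressionMap.from_dict(json.loads(Path(path).read_text()))


def write_region(region: NormalRegion, path) -> None:
    Path(path).write_text(json.dumps(region.to_dict(), indent=2) + "\n")


def read_region(path) -> NormalRegion:
    return NormalRegion.from_dict(json.loads(Path(path).read_text()))


def write_recommendation(rec: GCMRecommendation, path) -> None:
    doc = {
        "input_panel": rec.input_panel.to_dict(),
        "recommended_panel": rec.recommended_panel.to_dict(),
        "initial_mre": rec.initial_mre,
        "final_mre": rec.final_mre,
        "steps": [dataclasses.asdict(s) for s in rec.steps],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def write_cohort(timelines: list[PatientTimeline], path) -> None:
    rows = []
    for tl in timelines:
        for t in tl.times:
            rows.append({"patient_id": tl.patient_id, "outcome": tl.outcome,
                         "time_h": t, **tl.panels[t].to_dict()})
    pd.DataFrame(rows, columns=_COHORT_COLS).to_csv(path, index=False)


def read_cohort(path) -> list[PatientTimeline]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _COHORT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing cohort columns {missing}")
    timelines = []
    for (pid, outcome), grp in df.groupby(["patient_id", "outcome"],
                                          sort=False):
        panels = {
            float(r["time_h"]): FactorPanel(**{f: float(r[f]) for f in FACTORS})
            for _, r in grp.iterrows()}
        timelines.append(PatientTimeline(patient_id=str(pid),
                                         outcome=str(outcome),
                                         panels=panels))
    return timelines


def read_scenario_yaml(path) -> "CohortScenario":
    """Load a cohort scenario from YAML.

    Schema (all keys except ``equilibria`` optional)::

        n_patients: 50
        outcome: alive
        equilibria: {fii: 95, fv: 100, fvii: 90, fviii: 120,
                     fix: 110, fx: 95, atiii: 90, pc: 100}
        initial_means: {fii: 55}
        initial_sd: 30.0
        rate_per_h: 0.12
        panel_noise_sd: 4.0
        cat_noise_sd: 0.01
        seed: 7
    """
    from .synthetic import CohortScenario

    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "equilibria" not in doc:
        raise ValueError(f"{path}: scenario YAML must define 'equilibria'")
    allowed = {f.name for f in dataclasses.fields(CohortScenario)}
    unknown = set(doc) - allowed
    if unknown:
        raise ValueError(f"{path}: unknown scenario keys {sorted(unknown)}")
    doc.setdefault("n_patients", 50)
    doc.setdefault("outcome", "alive")
    return CohortScenario(**doc)
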