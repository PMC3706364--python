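"""Result surfaces: scenario comparison table, trend series, subgroup shares.

The comparison table mirrors the published presentation order — tobacco
control rows, pharmacological rows, combination rows — with deaths averted
(mean and 95% CI), percent reductions and subgroup shares, plus run metadata
(seeds, parameter digest) so outputs are traceable to inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .engine import SimulationResult
from .interventions import PRESET_CATEGORY
from .uncertainty import AvertedDeathsTable

_CATEGORY_ORDER = {"tobacco_control": 0, "pharmacological": 1, "combination": 2, "other": 3}


@dataclass
class ReportBundle:
    comparison: pd.DataFrame
    trend_series: pd.DataFrame | None
    subgroup_gender_location: pd.DataFrame
    subgroup_age: pd.DataFrame
    meta: dict = field(default_factory=dict)


def build_report(
    results: Mapping[str, AvertedDeathsTable],
    sim_results: Mapping[str, SimulationResult] | None = None,
    meta: Mapping | None = None,
) -> ReportBundle:
    """Assemble the comparison table and share tables from per-scenario results."""
    frames = []
    sub_gl = []
    sub_age = []
    for name, adt in results.items():
        t = adt.table.copy()
        t.insert(0, "category", PRESET_CATEGORY.get(name, "other"))
        frames.append(t)
        g = adt.subgroup_gender_location.copy()
        g.insert(0, "scenario", name)
        sub_gl.append(g)
        a = adt.subgroup_age.copy()
        a.insert(0, "scenario", name)
        sub_age.append(a)
    if frames:
        comparison = pd.concat(frames, ignore_index=True)
        comparison["_order"] = comparison["category"].map(_CATEGORY_ORDER)
        comparison = (
            comparison.sort_values(["_order", "scenario", "cause"], kind="stable")
            .drop(columns="_order")
            .reset_index(drop=True)
        )
        subgroup_gl = pd.concat(sub_gl, ignore_index=True)
        subgroup_age = pd.concat(sub_age, ignore_index=True)
    else:
        comparison = pd.DataFrame(
            columns=["category", "scenario", "cause", "baseline", "averted",
                     "ci_lo", "ci_hi", "percent_reduction"]
        )
        subgroup_gl = pd.DataFrame(columns=["scenario", "cause", "gender", "location",
                                            "averted", "share"])
        subgroup_age = pd.DataFrame(columns=["scenario", "cause", "age_band",
                                             "averted", "share"])

    trend = None
    if sim_results:
        rows = []
        for name, res in sim_results.items():
            by_year = res.deaths.groupby(["year", "cause"], observed=True)["deaths"].sum()
            for (year, cause), deaths in by_year.items():
                rows.append({"scenario": name, "year": year, "cause": cause, "deaths": deaths})
        trend = pd.DataFrame(rows)

    bundle_meta = dict(meta or {})
    for name, adt in results.items():
        bundle_meta.setdefault("per_scenario", {})[name] = {
            "n_runs": adt.n_runs, "failures": adt.failures, **adt.meta,
        }
    return ReportBundle(comparison, trend, subgroup_gl, subgroup_age, bundle_meta)


def write_report(bundle: ReportBundle, outdir: str | Path) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.comparison.to_csv(out / "comparison.csv", index=False)
    bundle.subgroup_gender_location.to_csv(out / "subgroup_gender_location.csv", index=False)
    bundle.subgroup_age.to_csv(out / "subgroup_age.csv", index=False)
    if bundle.trend_series is not None:
        bundle.trend_series.to_csv(out / "trend_series.csv", index=False)
    summary = {
        "meta": bundle.meta,
        "comparison": bundle.comparison.to_dict(orient="records"),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return out


def read_report(path: str | Path) -> ReportBundle:
    """Reload a persisted report losslessly (no recomputation)."""
    p = Path(path)
    comparison = pd.read_csv(p / "comparison.csv")
    subgroup_gl = pd.read_csv(p / "subgroup_gender_location.csv")
    subgroup_age = pd.read_csv(p / "subgroup_age.csv")
    trend_path = p / "trend_series.csv"
    trend = pd.read_csv(trend_path) if trend_path.exists() else None
    meta = json.loads((p / "summary.json").read_text())["meta"]
    return ReportBundle(comparison, trend, subgroup_gl, subgroup_age, meta)
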