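"""Monte Carlo parameter uncertainty: paired runs and percentile intervals.

Each replicate draws intervention effect sizes, medication effect sizes and
adherence from normal distributions defined by their 95% CIs (truncated to
the legal domain), optionally perturbs price elasticities and the demographic
projection, redraws the simulated population, and runs the baseline plus
every scenario with shared random streams.  Averted deaths are summarized by
the mean and the 2.5/97.5 percentiles across replicates (output distributions
are skewed, so percentile intervals rather than normal approximations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import derive_seed, stream
from .constants import CAUSES, LOCATIONS, PRODUCTS
from .engine import EngineError, averted, averted_by, run_scenario
from .interventions import ScenarioSpec
from .medications import DrugClass
from .params_io import InterventionEffect, ParameterSet, TaxParameters

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class UncertaintySpec:
    """Monte Carlo configuration (defaults sized for test-scale runs)."""

    n_runs: int = 200
    master_seed: int = 0
    n_per_cohort: int = 1000
    draw_effects: bool = True
    draw_medications: bool = True
    draw_elasticities: bool = True
    draw_pop_trend: bool = True
    elasticity_rel_sd: float = 0.10
    pop_trend_sd: float = 0.003
    max_failure_frac: float = 0.01
    add_entrants: bool = True

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass
class AvertedDeathsTable:
    """Mean averted deaths with 95% percentile CIs per scenario and cause."""

    table: pd.DataFrame  # scenario, cause, baseline, averted, ci_lo, ci_hi, percent_reduction
    subgroup_gender_location: pd.DataFrame
    subgroup_age: pd.DataFrame
    n_runs: int
    failures: int
    meta: dict = field(default_factory=dict)


def _truncated_normal(
    central: float, lo: float, hi: float, rng: np.random.Generator,
    domain: tuple[float, float] = (0.0, 1.0),
) -> float:
    """One draw from N(central, ((hi-lo)/3.92)^2) truncated to ``domain``."""
    sd = (hi - lo) / 3.92
    if sd <= 0:
        return central
    a, b = (domain[0] - central) / sd, (domain[1] - central) / sd
    return float(stats.truncnorm.rvs(a, b, loc=central, scale=sd, random_state=rng))


def draw_parameter_set(ps: ParameterSet, spec: UncertaintySpec, run: int) -> ParameterSet:
    """Perturbed copy of ``ps`` for one Monte Carlo replicate.

    One stream per parameter family, keyed by run index, so adding a scenario
    or toggling a family never perturbs another family's draws.
    """
    out = ps
    if spec.draw_effects:
        rng = stream(spec.master_seed, "mc-effects", run)
        effects = []
        for e in ps.intervention_effects:
            c = _truncated_normal(e.central, e.ci95[0], e.ci95[1], rng)
            lo = min(e.ci95[0], c)
            hi = max(e.ci95[1], c)
            effects.append(InterventionEffect(e.name, e.policy, e.targets, c, (lo, hi)))
        out = replace(out, intervention_effects=tuple(effects))
    if spec.draw_medications:
        rng = stream(spec.master_seed, "mc-medications", run)
        med = ps.medications
        classes = {}
        for name, cls in med.classes.items():
            rrr = {}
            for cause in CAUSES:
                c0, lo, hi = cls.rrr[cause]
                c = _truncated_normal(c0, lo, hi, rng)
                rrr[cause] = (c, min(lo, c), max(hi, c))
            classes[name] = DrugClass(name, rrr)
        adh = []
        for c0, lo, hi in (med.adherence_no_history, med.adherence_history):
            c = _truncated_normal(c0, lo, hi, rng)
            adh.append((c, min(lo, c), max(hi, c)))
        out = replace(
            out,
            medications=replace(
                med, classes=classes, adherence_no_history=adh[0], adherence_history=adh[1]
            ),
        )
    if spec.draw_elasticities:
        rng = stream(spec.master_seed, "mc-elasticity", run)
        elasticity = {}
        for p in PRODUCTS:
            for loc in LOCATIONS:
                e0 = ps.tax.elasticity[(p, loc)]
                sd = abs(e0) * spec.elasticity_rel_sd
                lo, hi = e0 - 1.96 * sd, e0 + 1.96 * sd
                elasticity[(p, loc)] = _truncated_normal(e0, lo, hi, rng, domain=(-1.999, -1e-6))
        out = replace(out, tax=TaxParameters(ps.tax.tax_share, elasticity))
    if spec.draw_pop_trend:
        rng = stream(spec.master_seed, "mc-demography", run)
        lo = ps.pop_trend - 1.96 * spec.pop_trend_sd
        hi = ps.pop_trend + 1.96 * spec.pop_trend_sd
        trend = _truncated_normal(ps.pop_trend, lo, hi, rng, domain=(-0.199, 0.199))
        out = replace(out, pop_trend=trend)
    return out


def run_uncertainty(
    ps: ParameterSet,
    scenarios: Sequence[ScenarioSpec],
    spec: UncertaintySpec,
) -> dict[str, AvertedDeathsTable]:
    """Paired baseline/scenario Monte Carlo; one table per scenario."""
    if not scenarios:
        raise ValueError("need at least one scenario")
    baseline_spec = ScenarioSpec("baseline")
    records: dict[str, list[pd.DataFrame]] = {s.name: [] for s in scenarios}
    sub_gl: dict[str, list[pd.DataFrame]] = {s.name: [] for s in scenarios}
    sub_age: dict[str, list[pd.DataFrame]] = {s.name: [] for s in scenarios}
    failures = 0
    completed = 0
    for run in range(spec.n_runs):
        run_seed = derive_seed(spec.master_seed, "mc-run", run)
        try:
            ps_r = draw_parameter_set(ps, spec, run)
            base = run_scenario(
                ps_r, baseline_spec, spec.n_per_cohort, run_seed, spec.add_entrants
            )
            for s in scenarios:
                res = run_scenario(ps_r, s, spec.n_per_cohort, run_seed, spec.add_entrants)
                records[s.name].append(averted(base, res))
                sub_gl[s.name].append(averted_by(base, res, ["gender", "location"]))
                sub_age[s.name].append(averted_by(base, res, ["age_band"]))
        except EngineError as exc:
            failures += 1
            logger.warning("run %d failed: %s", run, exc)
            if failures / spec.n_runs > spec.max_failure_frac:
                raise RuntimeError(
                    f"{failures} failed runs out of {run + 1} exceeds "
                    f"{spec.max_failure_frac:.0%} tolerance"
                ) from exc
            continue
        completed += 1

    out: dict[str, AvertedDeathsTable] = {}
    for s in scenarios:
        per_run = records[s.name]
        rows = []
        for cause in CAUSES:
            av = np.array([df.loc[cause, "averted"] for df in per_run])
            base_tot = np.array([df.loc[cause, "baseline"] for df in per_run])
            mean_av = float(av.mean())
            mean_base = float(base_tot.mean())
            rows.append(
                {
                    "scenario": s.name,
                    "cause": cause,
                    "baseline": mean_base,
                    "averted": mean_av,
                    "ci_lo": float(np.percentile(av, 2.5)),
                    "ci_hi": float(np.percentile(av, 97.5)),
                    "percent_reduction": 100.0 * mean_av / mean_base if mean_base else 0.0,
                }
            )
        table = pd.DataFrame(rows)

        def _shares(frames: list[pd.DataFrame], keys: list[str]) -> pd.DataFrame:
            cat = pd.concat(frames, ignore_index=True)
            agg = cat.groupby(["cause", *keys], observed=True)["averted"].mean().reset_index()
            outf = []
            for cause, grp in agg.groupby("cause", observed=True):
                total = grp["averted"].sum()
                g = grp.copy()
                g["share"] = g["averted"] / total if total != 0 else np.nan
                outf.append(g)
            return pd.concat(outf, ignore_index=True)

        out[s.name] = AvertedDeathsTable(
            table=table,
            subgroup_gender_location=_shares(sub_gl[s.name], ["gender", "location"]),
            subgroup_age=_shares(sub_age[s.name], ["age_band"]),
            n_runs=completed,
            failures=failures,
            meta={
                "master_seed": spec.master_seed,
                "n_per_cohort": spec.n_per_cohort,
                "scenario": s.name,
                "mode": s.mode,
                "ramp": s.ramp,
            },
        )
    return out
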