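"""Annual discrete-time simulation loop and baseline/scenario differencing.

One run simulates ``n_per_cohort`` individuals per cohort over the decade.
Each year: secular trends update risk factors and mortality, the scenario
converts tobacco users to quitters and assigns medication coverage, cause
probabilities are computed with mean-RR normalization against the
counterfactual (no-intervention) tobacco state, one categorical outcome
{MI death, stroke death, other death, survive} is drawn per alive person,
survivors age one year, and new 20-year-olds enter per the census projection.

Randomness is split into named independent streams (profiles, outcomes,
intervention, medication, trends, entrants) derived from one master seed, so
paired baseline/scenario runs share all randomness the intervention does not
touch (common random numbers): identical scenarios are bitwise identical and
averted-death differences are low-variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace
import numpy as np
import pandas as pd

from ._rng import stream
from .cohort_sampler import Population, sample_profiles
from .constants import AGE_BANDS, ALL_CAUSES, CAUSES, GENDERS, LOCATIONS
from .hazard import PROB_CLAMP, population_rr, scaled_mortality
from .interventions import (
    ChannelState,
    QuitLag,
    ScenarioSpec,
    apply_tobacco_scenario,
    channel_user_masks,
)
from .medications import multiplier_arrays
from .params_io import CohortKey, ParameterSet, parameter_digest

logger = logging.getLogger(__name__)

_N_BANDS = len(AGE_BANDS)
_BAND_OVERAGE = _N_BANDS  # attained age >= 80: keeps 70-79 rates, not reported


class EngineError(RuntimeError):
    pass


@dataclass
class _TobaccoState:
    """Snapshot of the tobacco-related arrays (the counterfactual state)."""

    tobacco: np.ndarray
    months_since_quit: np.ndarray
    rr_pre_mi: np.ndarray
    rr_pre_stroke: np.ndarray
    rr_post_mi: np.ndarray
    rr_post_stroke: np.ndarray

    @classmethod
    def snapshot(cls, pop: Population) -> "_TobaccoState":
        return cls(
            pop.tobacco.copy(),
            pop.months_since_quit.copy(),
            pop.rr_pre_mi.copy(),
            pop.rr_pre_stroke.copy(),
            pop.rr_post_mi.copy(),
            pop.rr_post_stroke.copy(),
        )

    def extend(self, pop_tail: Population) -> None:
        self.tobacco = np.concatenate([self.tobacco, pop_tail.tobacco])
        self.months_since_quit = np.concatenate(
            [self.months_since_quit, pop_tail.months_since_quit]
        )
        self.rr_pre_mi = np.concatenate([self.rr_pre_mi, pop_tail.rr_pre_mi])
        self.rr_pre_stroke = np.concatenate([self.rr_pre_stroke, pop_tail.rr_pre_stroke])
        self.rr_post_mi = np.concatenate([self.rr_post_mi, pop_tail.rr_post_mi])
        self.rr_post_stroke = np.concatenate([self.rr_post_stroke, pop_tail.rr_post_stroke])

    def override(self, cause: str):
        pre = self.rr_pre_mi if cause == "mi" else self.rr_pre_stroke
        post = self.rr_post_mi if cause == "mi" else self.rr_post_stroke
        return (self.tobacco, self.months_since_quit, pre, post)


@dataclass
class SimulationResult:
    """Per-cohort, per-year, per-cause deaths scaled to population."""

    deaths: pd.DataFrame  # age_band, gender, location, year, cause, deaths, deaths_sim
    person_years: float
    prevalence: pd.DataFrame  # final tobacco-category shares per cohort
    meta: dict

    def total(self, cause: str | None = None) -> float:
        df = self.deaths
        if cause is not None:
            df = df[df["cause"] == cause]
        return float(df["deaths"].sum())

    def totals_by(self, columns: list[str], cause: str | None = None) -> pd.Series:
        df = self.deaths
        if cause is not None:
            df = df[df["cause"] == cause]
        return df.groupby(columns, observed=True)["deaths"].sum()


def _band_of(age: np.ndarray) -> np.ndarray:
    band = ((age - 20.0) // 10.0).astype(np.int64)
    return np.where(age >= 80.0, _BAND_OVERAGE, np.clip(band, 0, _N_BANDS - 1))


def run_scenario(
    ps: ParameterSet,
    scenario: ScenarioSpec,
    n_per_cohort: int,
    seed: int,
    add_entrants: bool = True,
) -> SimulationResult:
    """Run the annual loop for one parameter draw and one scenario."""
    if n_per_cohort < 100:
        raise ValueError("n_per_cohort must be >= 100")
    cohorts = ps.cohorts
    lag = QuitLag(ps.quit_lag_months)

    pops = [
        sample_profiles(c, n_per_cohort, ps, stream(seed, "profiles", i))
        for i, c in enumerate(cohorts)
    ]
    pop = pops[0]
    for tail in pops[1:]:
        pop.extend(tail)
    cf = _TobaccoState.snapshot(pop)

    outcome_rng = stream(seed, "outcomes")
    intervention_rng = stream(seed, "intervention")
    medication_rng = stream(seed, "medication")
    trends_rng = stream(seed, "trends")
    entrants_rng = stream(seed, "entrants")

    state = ChannelState()
    state.register_users(_channel_counts(pop))

    med_policy = ps.medications
    if scenario.med_coverage_end is not None:
        med_policy = dc_replace(med_policy, coverage_end=scenario.med_coverage_end)
    active_classes = (
        tuple(scenario.med_classes) if scenario.med_classes else tuple(med_policy.classes)
    )
    if scenario.medications:
        u_cov = medication_rng.random(len(pop))
        u_adh = medication_rng.random(len(pop))
    else:
        u_cov = u_adh = None

    tr_sbp = ps.trends.risk_factors.get("sbp", 0.0)
    tr_chol = ps.trends.risk_factors.get("chol", 0.0)
    tr_diab = ps.trends.risk_factors.get("diabetes", 0.0)

    n_years = ps.n_years
    deaths_sim = np.zeros((_N_BANDS, len(GENDERS), len(LOCATIONS), n_years, len(ALL_CAUSES)))
    deaths_scaled = np.zeros_like(deaths_sim)
    person_years = 0.0

    for t in range(n_years):
        year = ps.start_year + t
        if t > 0:
            pop.sbp *= 1.0 + tr_sbp
            pop.chol *= 1.0 + tr_chol
            if tr_diab:
                p0 = pop.diabetes_p0
                growth = p0 * ((1.0 + tr_diab) ** t - (1.0 + tr_diab) ** (t - 1))
                p_flip = np.clip(growth / np.maximum(1.0 - p0, 1e-9), 0.0, 1.0)
                u = trends_rng.random(len(pop))
                flip = (~pop.diabetes) & pop.alive & (u < p_flip)
                pop.diabetes |= flip
            else:
                trends_rng.random(len(pop))  # keep stream alignment
            for months in (pop.months_since_quit, cf.months_since_quit):
                quit = ~np.isnan(months)
                months[quit] += 12.0

        apply_tobacco_scenario(pop, scenario, ps, t, intervention_rng, state)

        band = _band_of(pop.age)
        rr_act = {c: population_rr(pop, ps.relative_risks, c, lag) for c in CAUSES}
        if scenario.policies or scenario.tax_increase_pct:
            rr_norm = {
                c: population_rr(pop, ps.relative_risks, c, lag, tobacco_override=cf.override(c))
                for c in CAUSES
            }
        else:
            rr_norm = rr_act
        if scenario.medications:
            med_mult = multiplier_arrays(pop, med_policy, active_classes, t, u_cov, u_adh)
        else:
            med_mult = None

        p_mi = np.zeros(len(pop))
        p_stroke = np.zeros(len(pop))
        p_other = np.zeros(len(pop))
        weight = np.zeros(len(pop))
        growth_t = (1.0 + ps.pop_trend) ** t

        for gi, g in enumerate(GENDERS):
            for li, loc in enumerate(LOCATIONS):
                gl = (pop.gender == gi) & (pop.location == li)
                for bi in range(_N_BANDS + 1):
                    rate_band = min(bi, _N_BANDS - 1)
                    cohort = CohortKey(AGE_BANDS[rate_band][0], g, loc)
                    if cohort not in ps.census:
                        continue
                    members = gl & (band == bi)
                    alive_members = members & pop.alive
                    n_alive = int(alive_members.sum())
                    if bi < _N_BANDS:
                        if n_alive == 0:
                            if members.any() or t == 0:
                                raise EngineError(
                                    f"cohort {cohort} extinct in year {year}"
                                )
                            continue
                        w = ps.census[cohort] * growth_t / n_alive
                        weight[members] = w
                        person_years += w * n_alive
                        norm_members = alive_members
                    else:
                        if n_alive == 0:
                            continue
                        weight[members] = 0.0
                        # normalize over-79s against the 70-79 reported group
                        ref = gl & (band == _N_BANDS - 1) & pop.alive
                        norm_members = ref if ref.any() else alive_members
                    for cause in CAUSES:
                        m = scaled_mortality(
                            ps.mortality, ps.trends, cohort, cause, year, ps.start_year
                        )
                        denom = float(rr_norm[cause][norm_members].mean())
                        p = m * rr_act[cause][members] / denom
                        if med_mult is not None:
                            p = p * med_mult[cause][members]
                        if cause == "mi":
                            p_mi[members] = p
                        else:
                            p_stroke[members] = p
                    p_other[members] = scaled_mortality(
                        ps.mortality, ps.trends, cohort, "other", year, ps.start_year
                    )

        total_p = p_mi + p_stroke + p_other
        over = total_p > PROB_CLAMP
        if over.any():
            logger.warning(
                "year %d: %d individuals' total annual death probability clamped",
                year, int(over.sum()),
            )
            scale = np.where(over, PROB_CLAMP / np.maximum(total_p, 1e-12), 1.0)
            p_mi, p_stroke, p_other = p_mi * scale, p_stroke * scale, p_other * scale

        u = outcome_rng.random(len(pop))
        die_mi = pop.alive & (u < p_mi)
        die_stroke = pop.alive & ~die_mi & (u < p_mi + p_stroke)
        die_other = pop.alive & ~die_mi & ~die_stroke & (u < p_mi + p_stroke + p_other)

        for ci, mask in ((0, die_mi), (1, die_stroke), (2, die_other)):
            idx = np.flatnonzero(mask & (band < _N_BANDS))
            if idx.size:
                np.add.at(
                    deaths_sim,
                    (band[idx], pop.gender[idx], pop.location[idx], t, ci),
                    1.0,
                )
                np.add.at(
                    deaths_scaled,
                    (band[idx], pop.gender[idx], pop.location[idx], t, ci),
                    weight[idx],
                )
        pop.alive &= ~(die_mi | die_stroke | die_other)
        pop.age[pop.alive] += 1.0

        if add_entrants and t < n_years - 1:
            _add_entrants(pop, cf, state, ps, t, entrants_rng, n_per_cohort)
            if scenario.medications:
                n_new = len(pop) - u_cov.size
                u_cov = np.concatenate([u_cov, medication_rng.random(n_new)])
                u_adh = np.concatenate([u_adh, medication_rng.random(n_new)])

    deaths = _deaths_frame(deaths_sim, deaths_scaled, ps)
    prevalence = _prevalence_frame(pop)
    meta = {
        "scenario": scenario.name,
        "mode": scenario.mode,
        "ramp": scenario.ramp,
        "seed": int(seed),
        "n_per_cohort": int(n_per_cohort),
        "add_entrants": bool(add_entrants),
        "params_digest": parameter_digest(ps),
        "start_year": ps.start_year,
        "n_years": ps.n_years,
    }
    return SimulationResult(deaths, person_years, prevalence, meta)


def _channel_counts(pop: Population) -> dict[tuple[str, str], float]:
    masks = channel_user_masks(pop)
    out: dict[tuple[str, str], float] = {}
    for channel, mask in masks.items():
        for li, loc in enumerate(LOCATIONS):
            out[(channel, loc)] = float((mask & pop.alive & (pop.location == li)).sum())
    return out


def _add_entrants(
    pop: Population,
    cf: _TobaccoState,
    state: ChannelState,
    ps: ParameterSet,
    t: int,
    rng: np.random.Generator,
    n_per_cohort: int,
) -> None:
    """Add new 20-year-olds per gender/location, per the census projection."""
    for g in GENDERS:
        for loc in LOCATIONS:
            cohort = CohortKey(20, g, loc)
            if cohort not in ps.marginals:
                continue
            n_new = int(round(n_per_cohort / 10.0 * (1.0 + ps.pop_trend) ** (t + 1)))
            if n_new <= 0:
                continue
            tail = sample_profiles(cohort, n_new, ps, rng)
            tail.age = 20.0 + rng.random(n_new)  # entrants are new 20-year-olds
            pop.extend(tail)
            cf.extend(tail)
            state.register_users(_channel_counts(tail))


def _deaths_frame(
    deaths_sim: np.ndarray, deaths_scaled: np.ndarray, ps: ParameterSet
) -> pd.DataFrame:
    rows = []
    for bi, (lo, hi) in enumerate(AGE_BANDS):
        for gi, g in enumerate(GENDERS):
            for li, loc in enumerate(LOCATIONS):
                if CohortKey(lo, g, loc) not in ps.census:
                    continue
                for t in range(ps.n_years):
                    for ci, cause in enumerate(ALL_CAUSES):
                        rows.append(
                            {
                                "age_band": f"{lo}-{hi}",
                                "gender": g,
                                "location": loc,
                                "year": ps.start_year + t,
                                "cause": cause,
                                "deaths": deaths_scaled[bi, gi, li, t, ci],
                                "deaths_sim": deaths_sim[bi, gi, li, t, ci],
                            }
                        )
    return pd.DataFrame(rows)


def _prevalence_frame(pop: Population) -> pd.DataFrame:
    from .constants import TOBACCO_CATEGORIES

    rows = []
    band = _band_of(pop.age)
    for bi, (lo, hi) in enumerate(AGE_BANDS):
        for gi, g in enumerate(GENDERS):
            for li, loc in enumerate(LOCATIONS):
                mask = pop.alive & (band == bi) & (pop.gender == gi) & (pop.location == li)
                n = int(mask.sum())
                if n == 0:
                    continue
                row = {"age_band": f"{lo}-{hi}", "gender": g, "location": loc, "n": n}
                for ki, cat in enumerate(TOBACCO_CATEGORIES):
                    row[cat] = float((pop.tobacco[mask] == ki).sum()) / n
                rows.append(row)
    return pd.DataFrame(rows)


def averted(baseline: SimulationResult, scenario: SimulationResult) -> pd.DataFrame:
    """Deaths averted per cause (baseline - scenario) with percent reduction.

    Both results must come from the same seed, parameter draw and population
    size (common random numbers); otherwise the difference confounds
    intervention effect with sampling noise and an error is raised.
    """
    for key in ("seed", "params_digest", "n_per_cohort", "add_entrants"):
        if baseline.meta[key] != scenario.meta[key]:
            raise ValueError(
                f"baseline/scenario mismatch on {key}: "
                f"{baseline.meta[key]!r} != {scenario.meta[key]!r}"
            )
    rows = []
    for cause in CAUSES:
        b = baseline.total(cause)
        s = scenario.total(cause)
        rows.append(
            {
                "cause": cause,
                "baseline": b,
                "scenario": s,
                "averted": b - s,
                "percent_reduction": 100.0 * (b - s) / b if b > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("cause")


def averted_by(
    baseline: SimulationResult, scenario: SimulationResult, columns: list[str]
) -> pd.DataFrame:
    """Subgroup decomposition of averted deaths with shares per cause."""
    frames = []
    for cause in CAUSES:
        b = baseline.totals_by(columns, cause)
        s = scenario.totals_by(columns, cause)
        diff = (b - s).rename("averted").reset_index()
        total = diff["averted"].sum()
        diff["share"] = diff["averted"] / total if total != 0 else np.nan
        diff.insert(0, "cause", cause)
        frames.append(diff)
    return pd.concat(frames, ignore_index=True)
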