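"""The five FCTC tobacco-control measures and their combination algebra.

Four measures have fixed fractional effects on tobacco-use probability
(smoke-free laws, brief cessation advice, mass media, advertising ban); tax
increases are converted to consumption reductions mechanistically through
price elasticities and tax shares, assuming full pass-through to retail
prices.  Combined packages use one of three modes: ``max_only`` (largest
single effect), ``cumulative`` (independent effects, 1 - prod(1 - e_j)) or
``synergy25`` (cumulative with each effect inflated 25%).

The baseline implementation schedule assumes legislation arrives immediately
nationwide while its effect on smoking phases in linearly over the decade.
The delayed schedule ramps legislative coverage 0 -> 80% over five years; the
smoking response of each newly covered tranche still phases in over ten
years, so the delayed schedule's effective strength is the convolution of the
two ramps (``effective_ramp``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np

from .constants import (
    CHANNELS,
    LOCATIONS,
    PRODUCT_BIDI,
    PRODUCT_CIGARETTE,
    PRODUCT_NONE,
    TOBACCO_INDEX,
)

if TYPE_CHECKING:  # pragma: no cover
    from .cohort_sampler import Population
    from .params_io import ParameterSet, TaxParameters

logger = logging.getLogger(__name__)

COMBINATION_MODES = ("max_only", "cumulative", "synergy25")
RAMPS = ("baseline_10yr_linear", "delayed_80pct_5yr")

_CAT_PASSIVE = TOBACCO_INDEX["passive"]
_CAT_FORMER = TOBACCO_INDEX["former"]
_CAT_CIG = TOBACCO_INDEX["cigarette"]
_CAT_BIDI = TOBACCO_INDEX["bidi"]
_CAT_CHEW = TOBACCO_INDEX["chewing"]
_CAT_DUAL = TOBACCO_INDEX["dual"]


@dataclass(frozen=True)
class QuitLag:
    """Exponential decay time constant for post-quit excess risk (months)."""

    tau_months: float = 19.1

    def __post_init__(self) -> None:
        if self.tau_months <= 0:
            raise ValueError("quit-lag time constant must be > 0")


@dataclass(frozen=True)
class ScenarioSpec:
    """Which interventions are active and how they are applied."""

    name: str = "baseline"
    policies: frozenset[str] = frozenset()  # of the four fixed-effect measures
    tax_increase_pct: Mapping[str, float] = field(default_factory=dict)  # product -> %
    mode: str = "cumulative"
    ramp: str = "baseline_10yr_linear"
    medications: bool = False
    med_classes: frozenset[str] = frozenset()  # empty = all classes in policy
    med_coverage_end: float | None = None  # override coverage endpoint

    def __post_init__(self) -> None:
        if self.mode not in COMBINATION_MODES:
            raise ValueError(f"mode must be one of {COMBINATION_MODES}")
        if self.ramp not in RAMPS:
            raise ValueError(f"ramp must be one of {RAMPS}")
        if any(v < 0 for v in self.tax_increase_pct.values()):
            raise ValueError("tax increase must be >= 0")

    @property
    def is_null(self) -> bool:
        return not self.policies and not self.tax_increase_pct and not self.medications


def _preset_table() -> dict[str, ScenarioSpec]:
    tc_all = frozenset({"smoke_free", "cessation_advice", "mass_media", "advertising_ban"})
    tax300 = {"cigarette": 300.0, "bidi": 300.0}
    t = {
        "baseline": ScenarioSpec("baseline"),
        "smoke_free": ScenarioSpec("smoke_free", frozenset({"smoke_free"})),
        "cessation_advice": ScenarioSpec("cessation_advice", frozenset({"cessation_advice"})),
        "mass_media": ScenarioSpec("mass_media", frozenset({"mass_media"})),
        "advertising_ban": ScenarioSpec("advertising_ban", frozenset({"advertising_ban"})),
        "bidi_tax_300": ScenarioSpec("bidi_tax_300", tax_increase_pct={"bidi": 300.0}),
        "cigarette_tax_300": ScenarioSpec("cigarette_tax_300", tax_increase_pct={"cigarette": 300.0}),
        "tax_300_both": ScenarioSpec("tax_300_both", tax_increase_pct=dict(tax300)),
        "aspirin": ScenarioSpec("aspirin", medications=True, med_classes=frozenset({"aspirin"})),
        "antihypertensive": ScenarioSpec(
            "antihypertensive", medications=True, med_classes=frozenset({"antihypertensive"})
        ),
        "statin": ScenarioSpec("statin", medications=True, med_classes=frozenset({"statin"})),
        "all_meds": ScenarioSpec("all_meds", medications=True),
        "all_tc_max_only": ScenarioSpec(
            "all_tc_max_only", tc_all, dict(tax300), mode="max_only"
        ),
        "all_tc_cumulative": ScenarioSpec("all_tc_cumulative", tc_all, dict(tax300)),
        "all_tc_synergy25": ScenarioSpec(
            "all_tc_synergy25", tc_all, dict(tax300), mode="synergy25"
        ),
        "all_tc_all_meds": ScenarioSpec(
            "all_tc_all_meds", tc_all, dict(tax300), medications=True
        ),
    }
    return t


#: Scenario presets mirroring the published comparison table rows.
SCENARIO_PRESETS: dict[str, ScenarioSpec] = _preset_table()

#: Preset -> result-table category, in presentation order.
PRESET_CATEGORY: dict[str, str] = {
    **{k: "tobacco_control" for k in (
        "smoke_free", "cessation_advice", "mass_media", "advertising_ban",
        "bidi_tax_300", "cigarette_tax_300", "tax_300_both")},
    **{k: "pharmacological" for k in ("aspirin", "antihypertensive", "statin")},
    **{k: "combination" for k in (
        "all_meds", "all_tc_max_only", "all_tc_cumulative", "all_tc_synergy25",
        "all_tc_all_meds")},
}


def scenario_preset(name: str) -> ScenarioSpec:
    try:
        return SCENARIO_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario preset {name!r}; available: {sorted(SCENARIO_PRESETS)}"
        ) from None


def delayed(scenario: ScenarioSpec) -> ScenarioSpec:
    """The same scenario under the delayed 0->80%-over-5-years schedule."""
    return replace(scenario, name=scenario.name + "_delayed", ramp="delayed_80pct_5yr")


# ---------------------------------------------------------------------------
# Effect algebra
# ---------------------------------------------------------------------------


def tax_effect(
    product: str, location: str, tax_increase_pct: float, tp: "TaxParameters"
) -> float:
    """Fractional reduction in smoking probability from a tax increase.

    reduction = |elasticity| * tax_share * increase% / 100, capped at 1.
    Assumes full pass-through of the tax to retail price.
    """
    if tax_increase_pct < 0:
        raise ValueError("tax increase must be >= 0")
    el = abs(tp.elasticity[(product, location)])
    share = tp.tax_share[product]
    return min(1.0, el * share * tax_increase_pct / 100.0)


def combine_effects(effects: Sequence[float], mode: str) -> float:
    """Combine fractional reductions under one of the three modes."""
    if mode not in COMBINATION_MODES:
        raise ValueError(f"mode must be one of {COMBINATION_MODES}")
    eff = list(effects)
    if not eff:
        return 0.0
    if any(not 0.0 <= e <= 1.0 for e in eff):
        raise ValueError("each effect must lie in [0,1]")
    if mode == "max_only":
        return max(eff)
    if mode == "synergy25":
        eff = [min(1.0, 1.25 * e) for e in eff]
    out = 1.0
    for e in eff:
        out *= 1.0 - e
    return 1.0 - out


def coverage_ramp(ramp: str, year_index: int) -> float:
    """Legislative coverage schedule (fraction of full coverage) in a year."""
    if not 0 <= year_index <= 9:
        raise ValueError("year_index must lie in [0, 9]")
    if ramp == "baseline_10yr_linear":
        return (year_index + 1) / 10.0
    if ramp == "delayed_80pct_5yr":
        return 0.8 * min(1.0, (year_index + 1) / 5.0)
    raise ValueError(f"ramp must be one of {RAMPS}")


def effective_ramp(ramp: str, year_index: int) -> float:
    """Fraction of the full steady-state effect realized in a year.

    Under the baseline schedule legislation covers the whole country at once
    and the smoking response phases in linearly over 10 years, so the
    effective fraction is the 10-year ramp itself.  Under the delayed
    schedule each year's newly covered tranche (coverage increments of the
    0->80%-over-5-years schedule) starts its own 10-year response, so the
    effective fraction is the convolution of coverage increments with the
    response ramp.
    """
    if not 0 <= year_index <= 9:
        raise ValueError("year_index must lie in [0, 9]")
    if ramp == "baseline_10yr_linear":
        return coverage_ramp(ramp, year_index)
    if ramp == "delayed_80pct_5yr":
        total = 0.0
        prev = 0.0
        for k in range(year_index + 1):
            cov = coverage_ramp(ramp, k)
            increment = cov - prev
            prev = cov
            if increment > 0:
                total += increment * (year_index - k + 1) / 10.0
        return total
    raise ValueError(f"ramp must be one of {RAMPS}")


def quit_benefit(
    rr_current: float | np.ndarray,
    months_since_quit: float | np.ndarray,
    lag: QuitLag = QuitLag(),
) -> float | np.ndarray:
    """Residual relative risk after quitting.

    Excess risk decays exponentially with time constant tau and is floored at
    the fully recovered level (RR = 1) once 120 months have elapsed.
    """
    return decayed_rr(rr_current, 1.0, months_since_quit, lag)


def decayed_rr(
    rr_pre: float | np.ndarray,
    rr_post: float | np.ndarray,
    months: float | np.ndarray,
    lag: QuitLag = QuitLag(),
) -> float | np.ndarray:
    """Exponential decay from ``rr_pre`` toward ``rr_post``; floored at 120 mo."""
    m = np.asarray(months, dtype=float)
    val = rr_post + (rr_pre - rr_post) * np.exp(-m / lag.tau_months)
    val = np.where(m >= 120.0, rr_post, val)
    if np.ndim(val) == 0:
        return float(val)
    return val


# ---------------------------------------------------------------------------
# Applying a scenario to a population
# ---------------------------------------------------------------------------


@dataclass
class ChannelState:
    """Cumulative-quit bookkeeping per (channel, location).

    ``n0`` counts everyone who has ever been a user of the channel during the
    run (initial users plus entering users); the year target is a fraction of
    n0 and quitter selection is without replacement among current users, so
    the achieved trajectory is monotone.
    """

    n0: dict[tuple[str, str], float] = field(default_factory=dict)
    quit: dict[tuple[str, str], float] = field(default_factory=dict)

    def register_users(self, counts: Mapping[tuple[str, str], float]) -> None:
        for key, n in counts.items():
            self.n0[key] = self.n0.get(key, 0.0) + float(n)
            self.quit.setdefault(key, 0.0)


def channel_user_masks(pop: "Population") -> dict[str, np.ndarray]:
    """Current members of each intervention channel."""
    return {
        "active_cigarette": (pop.tobacco == _CAT_CIG)
        | ((pop.tobacco == _CAT_DUAL) & (pop.smoked_product == PRODUCT_CIGARETTE)),
        "active_bidi": (pop.tobacco == _CAT_BIDI)
        | ((pop.tobacco == _CAT_DUAL) & (pop.smoked_product == PRODUCT_BIDI)),
        "passive": pop.tobacco == _CAT_PASSIVE,
    }


def channel_reduction(
    scenario: ScenarioSpec, ps: "ParameterSet", channel: str, location: str
) -> float:
    """Combined steady-state prevalence reduction for one channel/location."""
    effects = [
        e.central
        for e in ps.intervention_effects
        if e.policy in scenario.policies and channel in e.targets
    ]
    product = {"active_cigarette": "cigarette", "active_bidi": "bidi"}.get(channel)
    if product is not None:
        pct = float(scenario.tax_increase_pct.get(product, 0.0))
        if pct > 0:
            effects.append(tax_effect(product, location, pct, ps.tax))
    return combine_effects(effects, scenario.mode)


def apply_tobacco_scenario(
    pop: "Population",
    scenario: ScenarioSpec,
    ps: "ParameterSet",
    year_index: int,
    rng: np.random.Generator,
    state: ChannelState,
) -> None:
    """Convert users to quitters to hit each channel's year target (in place).

    Quitters become former users with a fresh quit clock; dual users lose the
    smoked component and keep chewing (their risk decays from the dual level
    to the chewing level); passive-exposed individuals lose passive excess
    risk under the same lag.
    """
    if scenario.is_null or (not scenario.policies and not scenario.tax_increase_pct):
        return
    rr = ps.relative_risks
    lag_frac = effective_ramp(scenario.ramp, year_index)
    masks = channel_user_masks(pop)
    for channel in CHANNELS:
        for loc_idx, loc in enumerate(LOCATIONS):
            key = (channel, loc)
            n0 = state.n0.get(key, 0.0)
            if n0 <= 0:
                continue
            target = channel_reduction(scenario, ps, channel, loc) * lag_frac
            needed = int(round(n0 * target - state.quit.get(key, 0.0)))
            if needed <= 0:
                continue  # already at or past the target trajectory
            idx = np.flatnonzero(masks[channel] & pop.alive & (pop.location == loc_idx))
            k = min(needed, idx.size)
            if k <= 0:
                continue
            chosen = rng.choice(idx, size=k, replace=False)
            _quit(pop, chosen, rr)
            state.quit[key] = state.quit.get(key, 0.0) + k
            for m in masks.values():
                m[chosen] = False  # dual users leave both active channels


def _quit(pop: "Population", idx: np.ndarray, rr) -> None:
    """Transition the chosen users out of their channel with a fresh clock."""
    cats = pop.tobacco[idx]
    for cause, pre, post in (("mi", pop.rr_pre_mi, pop.rr_post_mi),
                             ("stroke", pop.rr_pre_stroke, pop.rr_post_stroke)):
        cur = np.ones(idx.size)
        cur[cats == _CAT_CIG] = rr.tobacco_rr(cause, "cigarette")
        cur[cats == _CAT_BIDI] = rr.tobacco_rr(cause, "bidi")
        cur[cats == _CAT_DUAL] = rr.tobacco_rr(cause, "dual")
        cur[cats == _CAT_PASSIVE] = rr.tobacco_rr(cause, "passive")
        tgt = np.ones(idx.size)
        tgt[cats == _CAT_DUAL] = rr.tobacco_rr(cause, "chewing")
        pre[idx] = cur
        post[idx] = tgt
    pop.months_since_quit[idx] = 0.0
    new_cat = np.where(cats == _CAT_DUAL, _CAT_CHEW, _CAT_FORMER)
    pop.tobacco[idx] = new_cat
    pop.smoked_product[idx] = np.where(new_cat == _CAT_CHEW, PRODUCT_NONE, pop.smoked_product[idx])
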