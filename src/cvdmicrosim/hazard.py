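"""Annual cause-specific death probabilities from risk profiles.

Each individual's relative risk (RR) for a cause is the product over risk
factors of per-unit or per-state multipliers.  Cause probabilities are
mean-RR normalized so that, absent interventions, the cohort mean probability
equals the input mortality rate for that cohort and year exactly
(population-consistency calibration):

    p_i = m_cohort(year) * RR_i / mean_alive(RR)

Other-cause mortality carries no individual RR.  Annual rates are treated as
probabilities directly (rates are small; the rate-to-probability conversion
is taken as the identity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .constants import CAUSES, TOBACCO_INDEX
from .cohort_sampler import Population, RiskProfile
from .interventions import QuitLag, decayed_rr
from .params_io import CohortKey, MortalityTable, ParameterSet, RelativeRiskTable, SecularTrends

logger = logging.getLogger(__name__)

#: Individual annual probabilities are clamped here if normalization pushes
#: them past certainty; a structured warning is logged when it happens.
PROB_CLAMP = 0.999


@dataclass
class CauseProbabilities:
    """Annual death probabilities per individual (arrays or scalars)."""

    p_mi: np.ndarray
    p_stroke: np.ndarray
    p_other: np.ndarray


def tobacco_rr_arrays(
    tobacco: np.ndarray,
    months_since_quit: np.ndarray,
    rr_pre: np.ndarray,
    rr_post: np.ndarray,
    rr_table: RelativeRiskTable,
    cause: str,
    lag: QuitLag,
) -> np.ndarray:
    """Tobacco RR per person: category multiplier, or lag-decayed for quitters."""
    out = np.ones(tobacco.size)
    for cat in ("passive", "cigarette", "bidi", "chewing", "dual"):
        out[tobacco == TOBACCO_INDEX[cat]] = rr_table.tobacco_rr(cause, cat)
    quitters = ~np.isnan(months_since_quit)
    if quitters.any():
        out[quitters] = decayed_rr(
            rr_pre[quitters], rr_post[quitters], months_since_quit[quitters], lag
        )
    return out


def population_rr(
    pop: Population,
    rr_table: RelativeRiskTable,
    cause: str,
    lag: QuitLag,
    tobacco_override: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Vectorized per-person RR for one cause.

    ``tobacco_override`` supplies (tobacco, months_since_quit, rr_pre,
    rr_post) arrays from an alternative tobacco state — the engine uses this
    to evaluate counterfactual RRs for normalization.
    """
    crr_sbp = rr_table.continuous[cause]["sbp"]
    crr_chol = rr_table.continuous[cause]["chol"]
    rr = np.power(crr_sbp.rr_per_unit, (pop.sbp - crr_sbp.reference) / crr_sbp.unit)
    rr *= np.power(crr_chol.rr_per_unit, (pop.chol - crr_chol.reference) / crr_chol.unit)
    for factor, mask in (
        ("diabetes", pop.diabetes),
        ("chd_hist", pop.chd_hist),
        ("cvd_hist", pop.cvd_hist),
    ):
        rr *= np.where(mask, rr_table.binary[cause][factor], 1.0)
    if tobacco_override is None:
        tob = (pop.tobacco, pop.months_since_quit,
               pop.rr_pre_mi if cause == "mi" else pop.rr_pre_stroke,
               pop.rr_post_mi if cause == "mi" else pop.rr_post_stroke)
    else:
        tob = tobacco_override
    rr *= tobacco_rr_arrays(tob[0], tob[1], tob[2], tob[3], rr_table, cause, lag)
    return rr


def individual_rr(
    profile: RiskProfile,
    rr_table: RelativeRiskTable,
    cause: str,
    lag: QuitLag = QuitLag(),
) -> float:
    """RR for a single profile (product of per-factor multipliers)."""
    crr_sbp = rr_table.continuous[cause]["sbp"]
    crr_chol = rr_table.continuous[cause]["chol"]
    rr = crr_sbp.rr_per_unit ** ((profile.sbp - crr_sbp.reference) / crr_sbp.unit)
    rr *= crr_chol.rr_per_unit ** ((profile.chol - crr_chol.reference) / crr_chol.unit)
    if profile.diabetes:
        rr *= rr_table.binary[cause]["diabetes"]
    if profile.chd_hist:
        rr *= rr_table.binary[cause]["chd_hist"]
    if profile.cvd_hist:
        rr *= rr_table.binary[cause]["cvd_hist"]
    if profile.tobacco == "former":
        if profile.months_since_quit is None:
            raise ValueError("former user requires months_since_quit")
        pre = rr_table.tobacco_rr(cause, "cigarette")
        rr *= decayed_rr(pre, 1.0, profile.months_since_quit, lag)
    else:
        rr *= rr_table.tobacco_rr(cause, profile.tobacco)
    return float(rr)


def scaled_mortality(
    mort: MortalityTable, trends: SecularTrends, cohort: CohortKey, cause: str, year: int,
    start_year: int,
) -> float:
    """m(year) = m(start_year) * (1 + trend_cause)^(year - start_year)."""
    return mort.rate(cohort, cause) * (1.0 + trends.mortality.get(cause, 0.0)) ** (
        year - start_year
    )


def normalized_cause_probs(
    pop: Population,
    cohort: CohortKey,
    ps: ParameterSet,
    year: int,
    norm_rr: dict[str, np.ndarray] | None = None,
    med_multiplier: dict[str, np.ndarray] | None = None,
) -> CauseProbabilities:
    """Mean-RR-normalized annual probabilities for one cohort's population.

    ``norm_rr`` optionally supplies per-cause RR arrays to normalize against
    (the counterfactual state under interventions); by default the actual RRs
    are used, making the cohort mean equal the input rate exactly.
    """
    if not pop.alive.any():
        raise ValueError(f"cohort {cohort}: no alive individuals")
    lag = QuitLag(ps.quit_lag_months)
    out: dict[str, np.ndarray] = {}
    for cause in CAUSES:
        m = scaled_mortality(ps.mortality, ps.trends, cohort, cause, year, ps.start_year)
        rr = population_rr(pop, ps.relative_risks, cause, lag)
        denom_rr = norm_rr[cause] if norm_rr is not None else rr
        denom = float(denom_rr[pop.alive].mean())
        p = m * rr / denom
        if med_multiplier is not None:
            p = p * med_multiplier[cause]
        if (p >= 1.0).any():
            logger.warning(
                "cohort %s cause %s year %d: %d probabilities clamped to %.3f",
                cohort, cause, year, int((p >= 1.0).sum()), PROB_CLAMP,
            )
            p = np.minimum(p, PROB_CLAMP)
        out[cause] = p
    m_other = scaled_mortality(ps.mortality, ps.trends, cohort, "other", year, ps.start_year)
    p_other = np.full(len(pop), min(m_other, PROB_CLAMP))
    return CauseProbabilities(p_mi=out["mi"], p_stroke=out["stroke"], p_other=p_other)
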