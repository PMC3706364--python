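"""India-like synthetic parameter sets for fully self-contained runs.

The generator emulates the *structure* of the WHO/GATS-derived input tables —
24 cohorts, normal blood-pressure and cholesterol marginals, binary
comorbidity prevalences, a 7-category tobacco distribution, pairwise
correlations, secular trends and age-rising cause-specific mortality — with
magnitudes chosen to be demographically plausible for India (urban men use
tobacco most; the 60-69 band carries the largest baseline CVD death counts;
hypertension and diabetes drift upward).  It makes no attempt to match
India's true prevalence numerically; it is an emulation for testing and
method exploration, not a transcription of any survey.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .constants import AGE_BANDS, GENDERS, LOCATIONS, TOBACCO_CATEGORIES
from .medications import default_medication_policy
from .params_io import (
    CohortKey,
    CorrelationMatrix,
    ContinuousRR,
    MortalityTable,
    ParameterSet,
    RelativeRiskTable,
    RiskFactorMarginals,
    SecularTrends,
    default_intervention_effects,
    default_tax_parameters,
    validate_parameter_set,
)

#: Base tobacco-category probabilities by (gender, location); rows follow
#: TOBACCO_CATEGORIES order and are renormalized after age adjustment.
_TOBACCO_BASE: dict[tuple[str, str], tuple[float, ...]] = {
    # never, passive, former, cigarette, bidi, chewing, dual
    ("male", "urban"): (0.32, 0.17, 0.06, 0.15, 0.08, 0.15, 0.07),
    ("male", "rural"): (0.32, 0.18, 0.05, 0.06, 0.18, 0.16, 0.05),
    ("female", "urban"): (0.60, 0.24, 0.02, 0.010, 0.010, 0.100, 0.020),
    ("female", "rural"): (0.545, 0.25, 0.02, 0.005, 0.025, 0.130, 0.025),
}

#: Passive exposure skews younger; multiplier per age band before renormalizing.
_PASSIVE_AGE_MULT = (1.20, 1.10, 1.00, 0.95, 0.90, 0.85)

_CORRELATION = np.array(
    [
        # sbp   chol  diab  chd   cvd   tobacco
        [1.00, 0.20, 0.15, 0.12, 0.10, 0.05],
        [0.20, 1.00, 0.15, 0.12, 0.08, 0.03],
        [0.15, 0.15, 1.00, 0.15, 0.10, 0.02],
        [0.12, 0.12, 0.15, 1.00, 0.20, 0.05],
        [0.10, 0.08, 0.10, 0.20, 1.00, 0.05],
        [0.05, 0.03, 0.02, 0.05, 0.05, 1.00],
    ]
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Knobs of the synthetic-parameter generator (defaults = study conditions)."""

    seed: int = 0
    scale: float = 1.0  # multiplies all census sizes

    # demography
    total_population: float = 750e6  # adults 20-79
    urban_share: float = 0.32
    male_share: float = 0.52
    age_weights: tuple[float, ...] = (0.30, 0.25, 0.19, 0.13, 0.08, 0.05)
    pop_trend: float = 0.013

    # blood pressure (mmHg)
    sbp_base: float = 118.0
    sbp_age_step: float = 3.5
    sbp_male_shift: float = 2.0
    sbp_urban_shift: float = 2.0
    sbp_sd: float = 14.0

    # total cholesterol (mmol/l)
    chol_base: float = 4.3
    chol_age_step: float = 0.15
    chol_urban_shift: float = 0.25
    chol_sd: float = 0.9

    # comorbidity prevalences
    diabetes_base: float = 0.02
    diabetes_age_factor: float = 1.5
    diabetes_urban_mult: float = 1.8
    chd_base: float = 0.004
    chd_age_factor: float = 1.8
    cvd_hist_base: float = 0.003
    cvd_hist_age_factor: float = 1.8

    # baseline mortality (1/year) per age band
    mi_mortality: tuple[float, ...] = (2e-4, 6e-4, 1.8e-3, 5e-3, 1.1e-2, 1.6e-2)
    stroke_mortality: tuple[float, ...] = (1.2e-4, 3.5e-4, 1.1e-3, 3.2e-3, 7.5e-3, 1.2e-2)
    other_mortality: tuple[float, ...] = (2e-3, 3e-3, 5e-3, 1.0e-2, 2.5e-2, 6.0e-2)
    male_mortality_mult: float = 1.3
    urban_mortality_mult: float = 1.1

    # secular trends (fraction/year)
    trends_risk_factors: tuple[tuple[str, float], ...] = (
        ("sbp", 0.003),
        ("chol", 0.002),
        ("diabetes", 0.03),
    )
    trends_mortality: tuple[tuple[str, float], ...] = (
        ("mi", 0.01),
        ("stroke", 0.01),
        ("other", -0.005),
    )

    #: relative 2-sigma jitter applied per gender x location to marginal levels
    jitter: float = 0.02


def _relative_risks() -> RelativeRiskTable:
    """Synthetic per-unit/per-state relative risks (plausible magnitudes)."""
    continuous = {
        "mi": {
            "sbp": ContinuousRR(1.25, 10.0, 115.0),
            "chol": ContinuousRR(1.25, 1.0, 4.0),
        },
        "stroke": {
            "sbp": ContinuousRR(1.35, 10.0, 115.0),
            "chol": ContinuousRR(1.10, 1.0, 4.0),
        },
    }
    binary = {
        "mi": {"diabetes": 2.0, "chd_hist": 3.0, "cvd_hist": 1.5},
        "stroke": {"diabetes": 1.8, "chd_hist": 1.5, "cvd_hist": 3.0},
    }
    tobacco = {
        "mi": {"never": 1.0, "passive": 1.25, "cigarette": 2.2, "bidi": 2.0,
               "chewing": 1.3, "dual": 2.5},
        "stroke": {"never": 1.0, "passive": 1.20, "cigarette": 1.8, "bidi": 1.7,
                   "chewing": 1.2, "dual": 2.0},
    }
    return RelativeRiskTable(continuous, binary, tobacco)


def generate_parameter_set(spec: SyntheticSpec = SyntheticSpec()) -> ParameterSet:
    """A complete, validated, India-like ParameterSet (deterministic in seed)."""
    if spec.scale <= 0 or spec.total_population <= 0:
        raise ValueError("population scale must be positive")
    rng = np.random.default_rng(spec.seed)

    # One multiplicative jitter per gender x location per quantity keeps the
    # age gradients exactly monotone while letting seeds differ.
    jit = {
        (g, loc): 1.0 + spec.jitter * rng.standard_normal(4)
        for g in GENDERS
        for loc in LOCATIONS
    }

    census: dict[CohortKey, float] = {}
    marginals: dict[CohortKey, RiskFactorMarginals] = {}
    rates: dict[tuple[CohortKey, str], float] = {}

    for loc in LOCATIONS:
        loc_share = spec.urban_share if loc == "urban" else 1.0 - spec.urban_share
        urban = loc == "urban"
        for g in GENDERS:
            g_share = spec.male_share if g == "male" else 1.0 - spec.male_share
            male = g == "male"
            j_sbp, j_chol, j_prev, j_mort = jit[(g, loc)]
            for bi, (lo, _hi) in enumerate(AGE_BANDS):
                c = CohortKey(lo, g, loc)
                census[c] = spec.total_population * spec.scale * loc_share * g_share * spec.age_weights[bi]

                sbp_mean = (
                    spec.sbp_base
                    + spec.sbp_age_step * bi
                    + (spec.sbp_male_shift if male else 0.0)
                    + (spec.sbp_urban_shift if urban else 0.0)
                ) * j_sbp
                chol_mean = (
                    spec.chol_base
                    + spec.chol_age_step * bi
                    + (spec.chol_urban_shift if urban else 0.0)
                ) * j_chol
                diab = min(
                    0.5,
                    spec.diabetes_base
                    * spec.diabetes_age_factor**bi
                    * (spec.diabetes_urban_mult if urban else 1.0)
                    * j_prev,
                )
                chd = min(0.3, spec.chd_base * spec.chd_age_factor**bi * j_prev)
                cvd = min(0.3, spec.cvd_hist_base * spec.cvd_hist_age_factor**bi * j_prev)

                base = np.array(_TOBACCO_BASE[(g, loc)], dtype=float)
                base[1] *= _PASSIVE_AGE_MULT[bi]
                base /= base.sum()
                probs = {cat: float(p) for cat, p in zip(TOBACCO_CATEGORIES, base)}

                marginals[c] = RiskFactorMarginals(
                    sbp_mean=float(sbp_mean),
                    sbp_sd=spec.sbp_sd,
                    chol_mean=float(chol_mean),
                    chol_sd=spec.chol_sd,
                    diabetes_prev=float(diab),
                    chd_prev=float(chd),
                    cvd_hist_prev=float(cvd),
                    tobacco_probs=probs,
                )

                mult = (
                    (spec.male_mortality_mult if male else 1.0)
                    * (spec.urban_mortality_mult if urban else 1.0)
                    * j_mort
                )
                rates[(c, "mi")] = min(0.5, spec.mi_mortality[bi] * mult)
                rates[(c, "stroke")] = min(0.5, spec.stroke_mortality[bi] * mult)
                rates[(c, "other")] = min(0.9, spec.other_mortality[bi] * mult)

    ps = ParameterSet(
        census=census,
        pop_trend=spec.pop_trend,
        marginals=marginals,
        correlation=CorrelationMatrix(_CORRELATION.copy()),
        relative_risks=_relative_risks(),
        mortality=MortalityTable(rates),
        trends=SecularTrends(dict(spec.trends_risk_factors), dict(spec.trends_mortality)),
        intervention_effects=tuple(default_intervention_effects()),
        tax=default_tax_parameters(),
        medications=default_medication_policy(),
    )
    report = validate_parameter_set(ps)
    if not report.ok:  # pragma: no cover - generator contract
        raise AssertionError(f"generated parameter set invalid: {report.errors[:3]}")
    return ps


def generate_fixture(n_cohorts: int, seed: int = 0, **overrides) -> ParameterSet:
    """Reduced-cohort ParameterSet for fast unit tests.

    Takes the first ``n_cohorts`` of the 24 (sorted order) from the full
    generated set; ``n_cohorts=24`` equals :func:`generate_parameter_set`.
    """
    if not 1 <= n_cohorts <= 24:
        raise ValueError("n_cohorts must lie in 1..24")
    spec = SyntheticSpec(seed=seed, **overrides)
    ps = generate_parameter_set(spec)
    if n_cohorts == 24:
        return ps
    keep = tuple(sorted(ps.census)[:n_cohorts])
    return replace(
        ps,
        census={c: ps.census[c] for c in keep},
        marginals={c: ps.marginals[c] for c in keep},
        mortality=MortalityTable(
            {(c, cause): r for (c, cause), r in ps.mortality.rates.items() if c in keep}
        ),
        expected_cohorts=keep,
    )
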