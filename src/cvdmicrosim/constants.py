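"""Shared enumerations for the India CVD microsimulation.

The model population is stratified into 24 cohorts: six 10-year age bands
(20-29 ... 70-79) x gender x urban/rural location.  Six risk factors enter
each individual's profile; tobacco use is a single 7-level categorical
variable.
"""

from __future__ import annotations

AGE_BANDS: tuple[tuple[int, int], ...] = (
    (20, 29),
    (30, 39),
    (40, 49),
    (50, 59),
    (60, 69),
    (70, 79),
)
GENDERS: tuple[str, ...] = ("male", "female")
LOCATIONS: tuple[str, ...] = ("urban", "rural")

#: Fixed category order used everywhere (inverse-CDF assignment relies on it).
TOBACCO_CATEGORIES: tuple[str, ...] = (
    "never",
    "passive",
    "former",
    "cigarette",
    "bidi",
    "chewing",
    "dual",
)
TOBACCO_INDEX: dict[str, int] = {c: i for i, c in enumerate(TOBACCO_CATEGORIES)}

#: Ordered risk-factor list; the correlation matrix is indexed in this order.
RISK_FACTORS: tuple[str, ...] = (
    "sbp",
    "chol",
    "diabetes",
    "chd_hist",
    "cvd_hist",
    "tobacco",
)

CAUSES: tuple[str, ...] = ("mi", "stroke")  # causes with individual relative risk
ALL_CAUSES: tuple[str, ...] = ("mi", "stroke", "other")

PRODUCTS: tuple[str, ...] = ("cigarette", "bidi")

#: Exposure channels tobacco-control interventions act on.
CHANNELS: tuple[str, ...] = ("active_cigarette", "active_bidi", "passive")

START_YEAR: int = 2013
N_YEARS: int = 10

# Physiologic clamping bounds for sampled continuous factors.
SBP_RANGE: tuple[float, float] = (60.0, 300.0)
CHOL_RANGE: tuple[float, float] = (1.0, 15.0)

# Smoked-product codes stored alongside the tobacco category for dual users
# and former users (who carry residual risk of the product they smoked).
PRODUCT_NONE, PRODUCT_CIGARETTE, PRODUCT_BIDI = 0, 1, 2
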