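"""Correlated individual risk-profile sampling (Gaussian copula).

Each cohort's joint risk-factor distribution is induced by a multivariate
normal latent vector with the configured correlation matrix: continuous
factors are linear transforms of their latent coordinate, binary factors
threshold theirs at the prevalence quantile, and the 7-level tobacco variable
maps one latent coordinate through its CDF onto the category probabilities by
inverse-CDF assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from typing import Mapping

import numpy as np
from scipy.special import ndtr, ndtri

from .constants import (
    CHOL_RANGE,
    GENDERS,
    LOCATIONS,
    PRODUCT_BIDI,
    PRODUCT_CIGARETTE,
    PRODUCT_NONE,
    SBP_RANGE,
    TOBACCO_CATEGORIES,
    TOBACCO_INDEX,
)
from .params_io import CohortKey, ParameterSet, RiskFactorMarginals

logger = logging.getLogger(__name__)

#: Former users' baseline quit durations are uniform on [0, 120] months, so
#: their residual excess risk spans the whole lag curve.
BASELINE_QUIT_WINDOW_MONTHS = 120.0

_CAT_FORMER = TOBACCO_INDEX["former"]
_CAT_DUAL = TOBACCO_INDEX["dual"]


@dataclass
class RiskProfile:
    """One simulated person's risk-factor profile."""

    age: float
    gender: str
    location: str
    sbp: float
    chol: float
    diabetes: bool
    chd_hist: bool
    cvd_hist: bool
    tobacco: str
    months_since_quit: float | None = None
    alive: bool = True


@dataclass
class Population:
    """Struct-of-arrays container for simulated individuals."""

    gender: np.ndarray  # int8 index into GENDERS
    location: np.ndarray  # int8 index into LOCATIONS
    age: np.ndarray  # float years
    sbp: np.ndarray
    chol: np.ndarray
    diabetes: np.ndarray  # bool
    chd_hist: np.ndarray
    cvd_hist: np.ndarray
    tobacco: np.ndarray  # int8 index into TOBACCO_CATEGORIES
    smoked_product: np.ndarray  # int8: none / cigarette / bidi
    months_since_quit: np.ndarray  # float, NaN when not a quitter
    rr_pre_mi: np.ndarray  # pre-quit RR (quitters only, NaN otherwise)
    rr_pre_stroke: np.ndarray
    rr_post_mi: np.ndarray  # recovered-level RR the decay approaches
    rr_post_stroke: np.ndarray
    diabetes_p0: np.ndarray  # baseline cohort prevalence (for trend flips)
    alive: np.ndarray  # bool

    def __len__(self) -> int:
        return self.age.size

    def copy(self) -> "Population":
        return Population(**{f.name: getattr(self, f.name).copy() for f in fields(self)})

    def extend(self, other: "Population") -> None:
        for f in fields(self):
            setattr(self, f.name, np.concatenate([getattr(self, f.name), getattr(other, f.name)]))

    def profile(self, i: int) -> RiskProfile:
        msq = float(self.months_since_quit[i])
        return RiskProfile(
            age=float(self.age[i]),
            gender=GENDERS[self.gender[i]],
            location=LOCATIONS[self.location[i]],
            sbp=float(self.sbp[i]),
            chol=float(self.chol[i]),
            diabetes=bool(self.diabetes[i]),
            chd_hist=bool(self.chd_hist[i]),
            cvd_hist=bool(self.cvd_hist[i]),
            tobacco=TOBACCO_CATEGORIES[self.tobacco[i]],
            months_since_quit=None if np.isnan(msq) else msq,
            alive=bool(self.alive[i]),
        )


def assign_tobacco(u: np.ndarray, probs: Mapping[str, float]) -> np.ndarray:
    """Inverse-CDF category assignment over the fixed category order."""
    vec = np.array([probs[c] for c in TOBACCO_CATEGORIES], dtype=float)
    total = vec.sum()
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"tobacco probabilities sum to {total}, not 1")
    cum = np.cumsum(vec)
    cum[-1] = max(cum[-1], 1.0)  # guard rounding at the top end
    idx = np.searchsorted(cum, np.asarray(u, dtype=float), side="right")
    return np.clip(idx, 0, len(TOBACCO_CATEGORIES) - 1).astype(np.int8)


def _threshold(prev: float) -> float:
    """Latent-normal threshold whose lower tail has mass ``prev``."""
    if prev <= 0.0:
        return -np.inf
    if prev >= 1.0:
        return np.inf
    return float(ndtri(prev))


def sample_profiles(
    cohort: CohortKey,
    n: int,
    ps: ParameterSet,
    seed: int | np.random.Generator,
) -> Population:
    """Sample ``n`` correlated risk profiles for one cohort."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if cohort not in ps.marginals:
        raise KeyError(f"cohort {cohort} not present in parameter set")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m: RiskFactorMarginals = ps.marginals[cohort]

    corr = ps.correlation
    if not corr.is_psd():
        corr, _delta = corr.nearest_psd()
    # Small jitter keeps Cholesky stable when the repaired matrix is singular.
    L = np.linalg.cholesky(corr.values + 1e-10 * np.eye(corr.values.shape[0]))
    z = rng.standard_normal((n, corr.values.shape[0])) @ L.T

    sbp = m.sbp_mean + m.sbp_sd * z[:, 0]
    chol = m.chol_mean + m.chol_sd * z[:, 1]
    clamped = int((sbp < SBP_RANGE[0]).sum() + (sbp > SBP_RANGE[1]).sum())
    clamped += int((chol < CHOL_RANGE[0]).sum() + (chol > CHOL_RANGE[1]).sum())
    if clamped > 3 and clamped / n > 0.001:  # ignore single-draw noise at tiny n
        logger.warning(
            "cohort %s: %.2f%% of continuous draws clamped to physiologic range",
            cohort, 100.0 * clamped / n,
        )
    sbp = np.clip(sbp, *SBP_RANGE)
    chol = np.clip(chol, *CHOL_RANGE)

    diabetes = z[:, 2] < _threshold(m.diabetes_prev)
    chd = z[:, 3] < _threshold(m.chd_prev)
    cvd = z[:, 4] < _threshold(m.cvd_hist_prev)

    tobacco = assign_tobacco(ndtr(z[:, 5]), m.tobacco_probs)

    age = rng.uniform(cohort.age_lo, cohort.age_hi + 1.0, size=n)

    months = np.full(n, np.nan)
    rr_pre_mi = np.full(n, np.nan)
    rr_pre_st = np.full(n, np.nan)
    rr_post_mi = np.full(n, np.nan)
    rr_post_st = np.full(n, np.nan)
    smoked = np.full(n, PRODUCT_NONE, dtype=np.int8)

    # Dual users and former users carry a smoked-product flag, assigned by the
    # cohort's cigarette:bidi mix.
    p_cig = float(m.tobacco_probs["cigarette"])
    p_bidi = float(m.tobacco_probs["bidi"])
    cig_share = 0.5 if (p_cig + p_bidi) <= 0 else p_cig / (p_cig + p_bidi)
    for cat in (_CAT_DUAL, _CAT_FORMER):
        idx = np.flatnonzero(tobacco == cat)
        if idx.size:
            smoked[idx] = np.where(
                rng.random(idx.size) < cig_share, PRODUCT_CIGARETTE, PRODUCT_BIDI
            )

    former = np.flatnonzero(tobacco == _CAT_FORMER)
    if former.size:
        months[former] = rng.uniform(0.0, BASELINE_QUIT_WINDOW_MONTHS, size=former.size)
        rr = ps.relative_risks
        for cause, pre, post in (("mi", rr_pre_mi, rr_post_mi), ("stroke", rr_pre_st, rr_post_st)):
            pre_vals = np.where(
                smoked[former] == PRODUCT_CIGARETTE,
                rr.tobacco_rr(cause, "cigarette"),
                rr.tobacco_rr(cause, "bidi"),
            )
            pre[former] = pre_vals
            post[former] = 1.0

    return Population(
        gender=np.full(n, GENDERS.index(cohort.gender), dtype=np.int8),
        location=np.full(n, LOCATIONS.index(cohort.location), dtype=np.int8),
        age=age,
        sbp=sbp,
        chol=chol,
        diabetes=diabetes,
        chd_hist=chd,
        cvd_hist=cvd,
        tobacco=tobacco,
        smoked_product=smoked,
        months_since_quit=months,
        rr_pre_mi=rr_pre_mi,
        rr_pre_stroke=rr_pre_st,
        rr_post_mi=rr_post_mi,
        rr_post_stroke=rr_post_st,
        diabetes_p0=np.full(n, m.diabetes_prev, dtype=float),
        alive=np.ones(n, dtype=bool),
    )
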