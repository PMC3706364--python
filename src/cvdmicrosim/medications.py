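"""Pharmacological comparator: aspirin, antihypertensives and statins.

Eligibility follows WHO-style rules: aspirin for anyone with a coronary or
cerebrovascular history; statins for hyperlipidemia or history; blood-pressure
treatment (ACE inhibitor + thiazide without history, beta-blocker regimen with
history) for hypertension or history.  Class benefits are annual relative risk
reductions (RRR) assumed additive across classes, gated by person-level
coverage and adherence draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np

from .constants import CAUSES

if TYPE_CHECKING:  # pragma: no cover
    from .cohort_sampler import Population

logger = logging.getLogger(__name__)

DRUG_CLASSES = ("aspirin", "antihypertensive", "statin")


@dataclass(frozen=True)
class DrugClass:
    """One medication class with per-cause RRR (central, 95% CI)."""

    name: str
    rrr: Mapping[str, tuple[float, float, float]]  # cause -> (central, lo, hi)

    def central(self, cause: str) -> float:
        return float(self.rrr[cause][0])


@dataclass(frozen=True)
class MedicationPolicy:
    """Eligibility thresholds, effect sizes, adherence and coverage path."""

    classes: Mapping[str, DrugClass]
    adherence_no_history: tuple[float, float, float] = (0.40, 0.20, 0.60)
    adherence_history: tuple[float, float, float] = (0.60, 0.40, 0.80)
    coverage_start: float = 0.15
    coverage_end: float = 0.45
    coverage_years: int = 10
    sbp_threshold_mmHg: float = 140.0
    chol_threshold_mmol_l: float = 5.2
    multiplier_floor: float = 0.1

    def validation_errors(self) -> list[str]:
        errs: list[str] = []
        for name, cls in self.classes.items():
            for cause in CAUSES:
                c, lo, hi = cls.rrr[cause]
                if not (0.0 <= lo <= c <= hi <= 1.0):
                    errs.append(f"medications.{name}.rrr[{cause}]: require 0 <= lo <= central <= hi <= 1")
        for label, (c, lo, hi) in (
            ("adherence_no_history", self.adherence_no_history),
            ("adherence_history", self.adherence_history),
        ):
            if not (0.0 <= lo <= c <= hi <= 1.0):
                errs.append(f"medications.{label}: require 0 <= lo <= central <= hi <= 1")
        if not (0.0 <= self.coverage_start <= self.coverage_end <= 1.0):
            errs.append("medications.coverage: require 0 <= start <= end <= 1")
        if self.coverage_years < 1:
            errs.append("medications.coverage_years: must be >= 1")
        return errs

    def to_dict(self) -> dict:
        return {
            "classes": {
                name: {f"rrr_{cause}": list(cls.rrr[cause]) for cause in CAUSES}
                for name, cls in sorted(self.classes.items())
            },
            "adherence": {
                "no_history": list(self.adherence_no_history),
                "history": list(self.adherence_history),
            },
            "coverage": {
                "start": self.coverage_start,
                "end": self.coverage_end,
                "years": self.coverage_years,
            },
            "thresholds": {
                "sbp_mmHg": self.sbp_threshold_mmHg,
                "chol_mmol_l": self.chol_threshold_mmol_l,
            },
            "floor": self.multiplier_floor,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MedicationPolicy":
        classes = {
            name: DrugClass(
                name,
                {cause: tuple(float(x) for x in spec[f"rrr_{cause}"]) for cause in CAUSES},
            )
            for name, spec in d["classes"].items()
        }
        return cls(
            classes=classes,
            adherence_no_history=tuple(float(x) for x in d["adherence"]["no_history"]),
            adherence_history=tuple(float(x) for x in d["adherence"]["history"]),
            coverage_start=float(d["coverage"]["start"]),
            coverage_end=float(d["coverage"]["end"]),
            coverage_years=int(d["coverage"]["years"]),
            sbp_threshold_mmHg=float(d["thresholds"]["sbp_mmHg"]),
            chol_threshold_mmol_l=float(d["thresholds"]["chol_mmol_l"]),
            multiplier_floor=float(d["floor"]),
        )


def default_medication_policy() -> MedicationPolicy:
    """Literature-plausible placeholder effect sizes (synthetic defaults).

    The numeric RRR values are package defaults, not transcriptions of any
    study's treatment table; adherence and the 15%->45%-over-10-years
    coverage path follow the published simulation conventions.
    """
    classes = {
        "aspirin": DrugClass("aspirin", {"mi": (0.25, 0.15, 0.35), "stroke": (0.15, 0.05, 0.25)}),
        "antihypertensive": DrugClass(
            "antihypertensive", {"mi": (0.20, 0.10, 0.30), "stroke": (0.35, 0.25, 0.45)}
        ),
        "statin": DrugClass("statin", {"mi": (0.30, 0.20, 0.40), "stroke": (0.10, 0.00, 0.20)}),
    }
    return MedicationPolicy(classes=classes)


def preset_policy(name: str) -> MedicationPolicy:
    """Coverage presets: 'who_45pct' (default path) and 'who_80pct'."""
    base = default_medication_policy()
    if name == "who_45pct":
        return base
    if name == "who_80pct":
        from dataclasses import replace

        return replace(base, coverage_end=0.80)
    raise KeyError(f"unknown medication preset {name!r}")


def coverage(policy: MedicationPolicy, year_index: int) -> float:
    """Fraction of the eligible population with treatment access in a year."""
    frac = min(1.0, (year_index + 1) / policy.coverage_years)
    return policy.coverage_start + (policy.coverage_end - policy.coverage_start) * frac


def eligible(profile, policy: MedicationPolicy) -> set[str]:
    """Drug classes a single profile qualifies for (duck-typed profile)."""
    out: set[str] = set()
    history = bool(profile.chd_hist or profile.cvd_hist)
    if history:
        out.add("aspirin")
    if history or profile.chol >= policy.chol_threshold_mmol_l:
        out.add("statin")
    if history or profile.sbp >= policy.sbp_threshold_mmHg:
        out.add("antihypertensive")
    return out & set(policy.classes)


def eligibility_masks(pop: "Population", policy: MedicationPolicy) -> dict[str, np.ndarray]:
    """Vectorized eligibility over a population."""
    history = pop.chd_hist | pop.cvd_hist
    masks = {
        "aspirin": history.copy(),
        "statin": history | (pop.chol >= policy.chol_threshold_mmol_l),
        "antihypertensive": history | (pop.sbp >= policy.sbp_threshold_mmHg),
    }
    return {k: v for k, v in masks.items() if k in policy.classes}


def medication_multiplier(profile, policy: MedicationPolicy, year_index: int, rng) -> dict[str, float]:
    """Per-cause hazard multiplier for one profile (Bernoulli gate via rng)."""
    classes = eligible(profile, policy)
    if not classes:
        return {cause: 1.0 for cause in CAUSES}
    history = bool(profile.chd_hist or profile.cvd_hist)
    adh = (policy.adherence_history if history else policy.adherence_no_history)[0]
    covered = rng.random() < coverage(policy, year_index)
    adherent = rng.random() < adh
    if not (covered and adherent):
        return {cause: 1.0 for cause in CAUSES}
    out = {}
    for cause in CAUSES:
        total = sum(policy.classes[c].central(cause) for c in classes)
        if total > 0.9:
            logger.warning("summed RRR %.2f for cause %s floored", total, cause)
        out[cause] = max(policy.multiplier_floor, 1.0 - total)
    return out


def multiplier_arrays(
    pop: "Population",
    policy: MedicationPolicy,
    active_classes: Iterable[str],
    year_index: int,
    u_cov: np.ndarray,
    u_adh: np.ndarray,
) -> dict[str, np.ndarray]:
    """Per-cause multiplier arrays for the whole population.

    ``u_cov`` / ``u_adh`` are person-level uniforms drawn once at scenario
    start (fixed-at-assignment coverage and adherence); a person is covered in
    year ``t`` iff u_cov < coverage(t), which makes coverage monotone over
    time without annual redraws.
    """
    n = len(pop.age)
    active = [c for c in active_classes if c in policy.classes]
    masks = eligibility_masks(pop, policy)
    history = pop.chd_hist | pop.cvd_hist
    adh_p = np.where(history, policy.adherence_history[0], policy.adherence_no_history[0])
    on_treatment = (u_cov < coverage(policy, year_index)) & (u_adh < adh_p)
    out: dict[str, np.ndarray] = {}
    for cause in CAUSES:
        total = np.zeros(n)
        for cname in active:
            total += np.where(masks[cname], policy.classes[cname].central(cause), 0.0)
        if (total > 0.9).any():
            logger.warning(
                "summed RRR exceeds 0.9 for %d individuals (cause %s); flooring",
                int((total > 0.9).sum()), cause,
            )
        mult = np.maximum(policy.multiplier_floor, 1.0 - total)
        out[cause] = np.where(on_treatment, mult, 1.0)
    return out
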