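"""Parameter data model, on-disk schema, validation and printed defaults.

A :class:`ParameterSet` bundles everything the simulator needs: cohort census
sizes, per-cohort risk-factor marginals, the risk-factor correlation matrix,
relative risks per cause, cause-specific baseline mortality, secular trends,
tobacco-control effect sizes, tax/elasticity parameters and the medication
policy.

On disk a parameter set is a directory bundle: ``manifest.yaml`` plus one
UTF-8 CSV per tabular role (census, marginals, correlation, relative risks,
mortality, trends).  Column headers carry explicit units (mmHg, mmol/l); the
loader rejects unit mismatches and unknown keys.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .constants import (
    AGE_BANDS,
    ALL_CAUSES,
    CAUSES,
    CHANNELS,
    GENDERS,
    LOCATIONS,
    N_YEARS,
    PRODUCTS,
    RISK_FACTORS,
    START_YEAR,
    TOBACCO_CATEGORIES,
)
from .medications import MedicationPolicy

SCHEMA_ID = "cvdmicrosim-parameters/1"

#: Maximum Frobenius distance allowed for the nearest-PSD correlation repair.
PSD_REPAIR_LIMIT = 0.05


class SchemaError(ValueError):
    """A parameter bundle violates the documented schema."""


@dataclass(frozen=True, order=True)
class CohortKey:
    """One of the 24 cohorts: 10-year age band x gender x location."""

    age_lo: int
    gender: str
    location: str

    def __post_init__(self) -> None:
        if (self.age_lo, self.age_hi) not in AGE_BANDS:
            raise ValueError(f"invalid age band start {self.age_lo}")
        if self.gender not in GENDERS:
            raise ValueError(f"invalid gender {self.gender!r}")
        if self.location not in LOCATIONS:
            raise ValueError(f"invalid location {self.location!r}")

    @property
    def age_hi(self) -> int:
        return self.age_lo + 9

    @property
    def age_band(self) -> str:
        return f"{self.age_lo}-{self.age_hi}"

    @property
    def band_index(self) -> int:
        return AGE_BANDS.index((self.age_lo, self.age_hi))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.age_band}/{self.gender}/{self.location}"

    @classmethod
    def all_cohorts(cls) -> tuple["CohortKey", ...]:
        return tuple(
            cls(lo, g, loc)
            for loc in LOCATIONS
            for g in GENDERS
            for (lo, _hi) in AGE_BANDS
        )

    @classmethod
    def from_parts(cls, age_band: str, gender: str, location: str) -> "CohortKey":
        lo = int(str(age_band).split("-")[0])
        return cls(lo, gender, location)

    @classmethod
    def from_age(cls, age: float, gender: str, location: str) -> "CohortKey | None":
        """Cohort containing ``age``, or None outside 20-79."""
        for lo, hi in AGE_BANDS:
            if lo <= age < hi + 1:
                return cls(lo, gender, location)
        return None


@dataclass(frozen=True)
class RiskFactorMarginals:
    """Marginal risk-factor distribution for one cohort.

    Continuous factors (systolic blood pressure in mmHg, total cholesterol in
    mmol/l) are normal with the given mean/sd; diabetes and disease histories
    are prevalences; tobacco is a 7-category probability vector.
    """

    sbp_mean: float
    sbp_sd: float
    chol_mean: float
    chol_sd: float
    diabetes_prev: float
    chd_prev: float
    cvd_hist_prev: float
    tobacco_probs: Mapping[str, float]

    def tobacco_vector(self) -> np.ndarray:
        return np.array([self.tobacco_probs[c] for c in TOBACCO_CATEGORIES])


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise correlations over the ordered risk-factor list."""

    values: np.ndarray  # (6, 6), order = RISK_FACTORS

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(RISK_FACTORS),) * 2:
            raise ValueError(f"correlation matrix must be {len(RISK_FACTORS)}x{len(RISK_FACTORS)}")
        object.__setattr__(self, "values", v)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CorrelationMatrix) and np.array_equal(self.values, other.values)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh((self.values + self.values.T) / 2.0).min())

    def is_psd(self, tol: float = 1e-10) -> bool:
        return self.min_eigenvalue() >= -tol

    def nearest_psd(self) -> tuple["CorrelationMatrix", float]:
        """Eigenvalue-clipped PSD repair with renormalized unit diagonal.

        Returns the repaired matrix and the Frobenius distance moved.
        Published correlation tables are typically printed rounded, which
        can push them marginally indefinite.
        """
        a = (self.values + self.values.T) / 2.0
        w, q = np.linalg.eigh(a)
        repaired = (q * np.clip(w, 0.0, None)) @ q.T
        d = np.sqrt(np.clip(np.diag(repaired), 1e-12, None))
        repaired = repaired / np.outer(d, d)
        np.fill_diagonal(repaired, 1.0)
        delta = float(np.linalg.norm(repaired - self.values, "fro"))
        return CorrelationMatrix(repaired), delta


@dataclass(frozen=True)
class ContinuousRR:
    """Relative risk per ``unit`` increase above ``reference``."""

    rr_per_unit: float
    unit: float
    reference: float


@dataclass(frozen=True)
class RelativeRiskTable:
    """Per-cause multiplicative relative risks for each risk factor.

    ``continuous`` maps cause -> {sbp, chol} -> ContinuousRR;
    ``binary`` maps cause -> {diabetes, chd_hist, cvd_hist} -> multiplier;
    ``tobacco`` maps cause -> category -> multiplier (never-user = 1).
    """

    continuous: Mapping[str, Mapping[str, ContinuousRR]]
    binary: Mapping[str, Mapping[str, float]]
    tobacco: Mapping[str, Mapping[str, float]]

    def tobacco_rr(self, cause: str, category: str) -> float:
        if category in ("never", "former"):
            return 1.0
        return float(self.tobacco[cause][category])


@dataclass(frozen=True)
class MortalityTable:
    """Annual baseline death rates (1/year) per cohort and cause."""

    rates: Mapping[tuple[CohortKey, str], float]

    def rate(self, cohort: CohortKey, cause: str) -> float:
        return float(self.rates[(cohort, cause)])

    def cohorts(self) -> set[CohortKey]:
        return {c for (c, _cause) in self.rates}


@dataclass(frozen=True)
class SecularTrends:
    """Annual fractional change in risk-factor levels and mortality rates."""

    risk_factors: Mapping[str, float]  # factor -> fraction/year
    mortality: Mapping[str, float]  # cause -> fraction/year


@dataclass(frozen=True)
class InterventionEffect:
    """One tobacco-control effect: fractional reduction in use probability."""

    name: str
    policy: str  # which of the five FCTC measures this effect belongs to
    targets: frozenset[str]  # subset of CHANNELS
    central: float
    ci95: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (0.0 <= lo <= self.central <= hi <= 1.0):
            raise ValueError(f"effect {self.name}: require 0 <= lo <= central <= hi <= 1")
        bad = set(self.targets) - set(CHANNELS)
        if bad:
            raise ValueError(f"effect {self.name}: unknown channels {sorted(bad)}")


@dataclass(frozen=True)
class TaxParameters:
    """Tax share of retail price and price elasticity of consumption."""

    tax_share: Mapping[str, float]  # product -> fraction of retail price
    elasticity: Mapping[tuple[str, str], float]  # (product, location) -> negative


@dataclass(frozen=True)
class ParameterSet:
    """Complete model configuration."""

    census: Mapping[CohortKey, float]  # persons in 2013
    pop_trend: float  # annual fractional census growth
    marginals: Mapping[CohortKey, RiskFactorMarginals]
    correlation: CorrelationMatrix
    relative_risks: RelativeRiskTable
    mortality: MortalityTable
    trends: SecularTrends
    intervention_effects: tuple[InterventionEffect, ...]
    tax: TaxParameters
    medications: MedicationPolicy
    quit_lag_months: float = 19.1
    start_year: int = START_YEAR
    n_years: int = N_YEARS
    expected_cohorts: tuple[CohortKey, ...] = field(default_factory=CohortKey.all_cohorts)

    @property
    def cohorts(self) -> tuple[CohortKey, ...]:
        return tuple(sorted(self.census.keys()))

    def effects_for_policy(self, policy: str) -> list[InterventionEffect]:
        return [e for e in self.intervention_effects if e.policy == policy]


def default_intervention_effects() -> list[InterventionEffect]:
    """The five FCTC tobacco-control measures with published effect sizes.

    Smoke-free laws act on two channels (a large passive-exposure reduction
    and a small active-smoking reduction) and are represented as two effect
    records under one policy.  Tax effects are computed mechanistically from
    :class:`TaxParameters` and are not listed here.
    """
    return [
        InterventionEffect(
            "smoke_free_passive", "smoke_free", frozenset({"passive"}), 0.64, (0.39, 0.89)
        ),
        InterventionEffect(
            "smoke_free_active",
            "smoke_free",
            frozenset({"active_cigarette", "active_bidi"}),
            0.01,
            (0.00, 0.02),
        ),
        InterventionEffect(
            "cessation_advice",
            "cessation_advice",
            frozenset({"active_cigarette", "active_bidi"}),
            0.01,
            (0.00, 0.03),
        ),
        InterventionEffect(
            "mass_media",
            "mass_media",
            frozenset({"active_cigarette", "active_bidi"}),
            0.05,
            (0.01, 0.11),
        ),
        InterventionEffect(
            "advertising_ban",
            "advertising_ban",
            frozenset({"active_cigarette", "active_bidi"}),
            0.06,
            (0.05, 0.07),
        ),
    ]


def default_tax_parameters() -> TaxParameters:
    """Indian tax shares of retail price and price elasticities of consumption."""
    return TaxParameters(
        tax_share={"cigarette": 0.38, "bidi": 0.09},
        elasticity={
            ("cigarette", "rural"): -0.34,
            ("cigarette", "urban"): -0.19,
            ("bidi", "rural"): -0.92,
            ("bidi", "urban"): -0.85,
        },
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    psd_repair_delta: float | None = None

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_parameter_set(ps: ParameterSet) -> ValidationReport:
    """Check every schema invariant; report errors and warnings, never raise."""
    rep = ValidationReport()
    expected = set(ps.expected_cohorts)

    for role, keys in (
        ("census", set(ps.census)),
        ("marginals", set(ps.marginals)),
        ("mortality", ps.mortality.cohorts()),
    ):
        missing = expected - keys
        extra = keys - expected
        for c in sorted(missing):
            rep.errors.append(f"{role}: missing cohort {c}")
        for c in sorted(extra):
            rep.errors.append(f"{role}: unexpected cohort {c}")

    for c, pop in ps.census.items():
        if not pop > 0:
            rep.errors.append(f"census: non-positive population for {c}")
    if not np.isfinite(ps.pop_trend) or abs(ps.pop_trend) >= 0.2:
        rep.errors.append("pop_trend: must be finite with |trend| < 20%/year")

    for c, m in ps.marginals.items():
        if m.sbp_sd <= 0 or m.chol_sd <= 0:
            rep.errors.append(f"marginals[{c}]: sd must be > 0")
        for name, p in (
            ("diabetes_prev", m.diabetes_prev),
            ("chd_prev", m.chd_prev),
            ("cvd_hist_prev", m.cvd_hist_prev),
        ):
            if not 0.0 <= p <= 1.0:
                rep.errors.append(f"marginals[{c}].{name}: probability outside [0,1]")
        probs = m.tobacco_probs
        if set(probs) != set(TOBACCO_CATEGORIES):
            rep.errors.append(f"marginals[{c}].tobacco_probs: categories must be {TOBACCO_CATEGORIES}")
        else:
            vec = m.tobacco_vector()
            if (vec < 0).any() or (vec > 1).any():
                rep.errors.append(f"marginals[{c}].tobacco_probs: probability outside [0,1]")
            if abs(float(vec.sum()) - 1.0) > 1e-9:
                rep.errors.append(
                    f"marginals[{c}].tobacco_probs: sums to {float(vec.sum()):.6f}, not 1"
                )

    v = ps.correlation.values
    if not np.allclose(v, v.T, atol=1e-12):
        rep.errors.append("correlation: matrix not symmetric")
    if not np.allclose(np.diag(v), 1.0, atol=1e-12):
        rep.errors.append("correlation: diagonal must be 1")
    if (np.abs(v) > 1.0 + 1e-12).any():
        rep.errors.append("correlation: entries must lie in [-1, 1]")
    if not ps.correlation.is_psd():
        repaired, delta = ps.correlation.nearest_psd()
        rep.psd_repair_delta = delta
        if delta > PSD_REPAIR_LIMIT:
            rep.errors.append(
                f"correlation: not PSD and repair distance {delta:.4f} exceeds {PSD_REPAIR_LIMIT}"
            )
        else:
            rep.warnings.append(
                f"correlation: not PSD; eigenvalue-clipped repair moved it by "
                f"{delta:.2e} (Frobenius)"
            )

    rr = ps.relative_risks
    for cause in CAUSES:
        for f, crr in rr.continuous[cause].items():
            if crr.rr_per_unit <= 0 or crr.unit <= 0:
                rep.errors.append(f"relative_risks[{cause}].{f}: multiplier and unit must be > 0")
        for f, val in rr.binary[cause].items():
            if val <= 0:
                rep.errors.append(f"relative_risks[{cause}].{f}: multiplier must be > 0")
        for cat, val in rr.tobacco[cause].items():
            if val <= 0:
                rep.errors.append(f"relative_risks[{cause}].tobacco.{cat}: multiplier must be > 0")
        if abs(rr.tobacco_rr(cause, "never") - 1.0) > 1e-12:
            rep.errors.append(f"relative_risks[{cause}].tobacco.never: reference must be 1")

    for (c, cause), rate in ps.mortality.rates.items():
        if not 0.0 < rate < 1.0:
            rep.errors.append(f"mortality[{c},{cause}]: rate outside (0,1)")
    # Non-decreasing mortality in age is plausibility only (warning).
    for loc in LOCATIONS:
        for g in GENDERS:
            for cause in ALL_CAUSES:
                rates = [
                    ps.mortality.rates.get((CohortKey(lo, g, loc), cause))
                    for (lo, _hi) in AGE_BANDS
                    if CohortKey(lo, g, loc) in expected
                ]
                rates = [r for r in rates if r is not None]
                if any(b < a for a, b in zip(rates, rates[1:])):
                    rep.warnings.append(
                        f"mortality: {cause} rates not non-decreasing in age for {g}/{loc}"
                    )

    for name, t in {**dict(ps.trends.risk_factors), **dict(ps.trends.mortality)}.items():
        if not np.isfinite(t) or abs(t) >= 0.2:
            rep.errors.append(f"trends.{name}: must be finite with |trend| < 20%/year")

    for e in ps.intervention_effects:
        lo, hi = e.ci95
        if not (0.0 <= lo <= e.central <= hi <= 1.0):
            rep.errors.append(f"intervention {e.name}: require 0 <= lo <= central <= hi <= 1")

    for p in PRODUCTS:
        share = ps.tax.tax_share.get(p)
        if share is None or not 0.0 < share < 1.0:
            rep.errors.append(f"tax.tax_share[{p}]: must lie in (0,1)")
        for loc in LOCATIONS:
            el = ps.tax.elasticity.get((p, loc))
            if el is None or not -2.0 < el < 0.0:
                rep.errors.append(f"tax.elasticity[{p},{loc}]: must lie in (-2,0)")

    rep.errors.extend(ps.medications.validation_errors())

    if ps.quit_lag_months <= 0:
        rep.errors.append("quit_lag_months: must be > 0")
    return rep


# ---------------------------------------------------------------------------
# On-disk bundle I/O
# ---------------------------------------------------------------------------

_MARGINAL_COLUMNS = [
    "age_band",
    "gender",
    "location",
    "sbp_mean_mmHg",
    "sbp_sd_mmHg",
    "chol_mean_mmol_l",
    "chol_sd_mmol_l",
    "diabetes_prev",
    "chd_prev",
    "cvd_hist_prev",
    *[f"p_{c}" for c in TOBACCO_CATEGORIES],
]
_CENSUS_COLUMNS = ["age_band", "gender", "location", "population"]
_MORTALITY_COLUMNS = ["age_band", "gender", "location", "cause", "rate_per_year"]
_TRENDS_COLUMNS = ["kind", "name", "annual_change"]
_RR_COLUMNS = ["cause", "factor", "kind", "value", "unit", "reference"]
_FILE_ROLES = ("census", "marginals", "correlation", "relative_risks", "mortality", "trends")

_MANIFEST_KEYS = {
    "schema",
    "start_year",
    "n_years",
    "pop_trend_per_year",
    "quit_lag_months",
    "cohorts",
    "files",
    "interventions",
    "tax",
    "medications",
}


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    if list(df.columns) != cols:
        raise SchemaError(
            f"{name}: expected columns {cols} (units are part of the header), got {list(df.columns)}"
        )


def save_parameter_set(ps: ParameterSet, path: str | Path) -> Path:
    """Write a parameter bundle directory; returns the manifest path."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)

    rows = [
        {"age_band": c.age_band, "gender": c.gender, "location": c.location, "population": pop}
        for c, pop in sorted(ps.census.items())
    ]
    pd.DataFrame(rows, columns=_CENSUS_COLUMNS).to_csv(out / "census.csv", index=False)

    rows = []
    for c, m in sorted(ps.marginals.items()):
        row = {
            "age_band": c.age_band,
            "gender": c.gender,
            "location": c.location,
            "sbp_mean_mmHg": m.sbp_mean,
            "sbp_sd_mmHg": m.sbp_sd,
            "chol_mean_mmol_l": m.chol_mean,
            "chol_sd_mmol_l": m.chol_sd,
            "diabetes_prev": m.diabetes_prev,
            "chd_prev": m.chd_prev,
            "cvd_hist_prev": m.cvd_hist_prev,
        }
        row.update({f"p_{cat}": m.tobacco_probs[cat] for cat in TOBACCO_CATEGORIES})
        rows.append(row)
    pd.DataFrame(rows, columns=_MARGINAL_COLUMNS).to_csv(out / "marginals.csv", index=False)

    corr = pd.DataFrame(ps.correlation.values, columns=list(RISK_FACTORS))
    corr.insert(0, "factor", list(RISK_FACTORS))
    corr.to_csv(out / "correlation.csv", index=False)

    rows = []
    for cause in CAUSES:
        for f, crr in ps.relative_risks.continuous[cause].items():
            rows.append(
                {"cause": cause, "factor": f, "kind": "continuous", "value": crr.rr_per_unit,
                 "unit": crr.unit, "reference": crr.reference}
            )
        for f, val in ps.relative_risks.binary[cause].items():
            rows.append({"cause": cause, "factor": f, "kind": "binary", "value": val,
                         "unit": "", "reference": ""})
        for cat, val in ps.relative_risks.tobacco[cause].items():
            rows.append({"cause": cause, "factor": cat, "kind": "tobacco", "value": val,
                         "unit": "", "reference": ""})
    pd.DataFrame(rows, columns=_RR_COLUMNS).to_csv(out / "relative_risks.csv", index=False)

    rows = [
        {"age_band": c.age_band, "gender": c.gender, "location": c.location,
         "cause": cause, "rate_per_year": rate}
        for (c, cause), rate in sorted(ps.mortality.rates.items(), key=lambda kv: (kv[0][0], kv[0][1]))
    ]
    pd.DataFrame(rows, columns=_MORTALITY_COLUMNS).to_csv(out / "mortality.csv", index=False)

    rows = [
        {"kind": "risk_factor", "name": n, "annual_change": t}
        for n, t in sorted(ps.trends.risk_factors.items())
    ] + [
        {"kind": "mortality", "name": n, "annual_change": t}
        for n, t in sorted(ps.trends.mortality.items())
    ]
    pd.DataFrame(rows, columns=_TRENDS_COLUMNS).to_csv(out / "trends.csv", index=False)

    all24 = set(ps.expected_cohorts) == set(CohortKey.all_cohorts())
    manifest = {
        "schema": SCHEMA_ID,
        "start_year": ps.start_year,
        "n_years": ps.n_years,
        "pop_trend_per_year": float(ps.pop_trend),
        "quit_lag_months": float(ps.quit_lag_months),
        "cohorts": "all" if all24 else [str(c) for c in sorted(ps.expected_cohorts)],
        "files": {role: f"{role}.csv" for role in _FILE_ROLES},
        "interventions": [
            {
                "name": e.name,
                "policy": e.policy,
                "targets": sorted(e.targets),
                "central": e.central,
                "ci95": [e.ci95[0], e.ci95[1]],
            }
            for e in ps.intervention_effects
        ],
        "tax": {
            "tax_share": {p: float(ps.tax.tax_share[p]) for p in PRODUCTS},
            "elasticity": {
                p: {loc: float(ps.tax.elasticity[(p, loc)]) for loc in LOCATIONS}
                for p in PRODUCTS
            },
        },
        "medications": ps.medications.to_dict(),
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return out / "manifest.yaml"


def load_parameter_set(path: str | Path) -> ParameterSet:
    """Load and validate a parameter bundle (directory or manifest path)."""
    p = Path(path)
    manifest_path = p / "manifest.yaml" if p.is_dir() else p
    if not manifest_path.exists():
        raise SchemaError(f"no manifest found at {manifest_path}")
    root = manifest_path.parent
    manifest = yaml.safe_load(manifest_path.read_text())
    if not isinstance(manifest, dict):
        raise SchemaError("manifest: expected a mapping")
    unknown = set(manifest) - _MANIFEST_KEYS
    if unknown:
        raise SchemaError(f"manifest: unknown keys {sorted(unknown)}")
    missing = _MANIFEST_KEYS - set(manifest)
    if missing:
        raise SchemaError(f"manifest: missing keys {sorted(missing)}")
    if manifest["schema"] != SCHEMA_ID:
        raise SchemaError(f"manifest.schema: expected {SCHEMA_ID!r}")

    if manifest["cohorts"] == "all":
        expected = CohortKey.all_cohorts()
    else:
        expected = tuple(
            sorted(CohortKey.from_parts(*str(s).split("/")) for s in manifest["cohorts"])
        )

    files = manifest["files"]
    if set(files) != set(_FILE_ROLES):
        raise SchemaError(f"manifest.files: expected roles {_FILE_ROLES}")

    def read(role: str) -> pd.DataFrame:
        fp = root / files[role]
        if not fp.exists():
            raise SchemaError(f"{role}: file {fp} not found")
        return pd.read_csv(fp, float_precision="round_trip")

    cdf = read("census")
    _require_columns(cdf, _CENSUS_COLUMNS, "census")
    census = {
        CohortKey.from_parts(r.age_band, r.gender, r.location): float(r.population)
        for r in cdf.itertuples()
    }

    mdf = read("marginals")
    _require_columns(mdf, _MARGINAL_COLUMNS, "marginals")
    marginals: dict[CohortKey, RiskFactorMarginals] = {}
    for r in mdf.itertuples():
        key = CohortKey.from_parts(r.age_band, r.gender, r.location)
        probs = {cat: float(getattr(r, f"p_{cat}")) for cat in TOBACCO_CATEGORIES}
        marginals[key] = RiskFactorMarginals(
            sbp_mean=float(r.sbp_mean_mmHg),
            sbp_sd=float(r.sbp_sd_mmHg),
            chol_mean=float(r.chol_mean_mmol_l),
            chol_sd=float(r.chol_sd_mmol_l),
            diabetes_prev=float(r.diabetes_prev),
            chd_prev=float(r.chd_prev),
            cvd_hist_prev=float(r.cvd_hist_prev),
            tobacco_probs=probs,
        )
    for c in expected:
        if c not in marginals:
            raise SchemaError(f"marginals: missing cohort {c}")

    xdf = read("correlation")
    _require_columns(xdf, ["factor", *RISK_FACTORS], "correlation")
    if list(xdf["factor"]) != list(RISK_FACTORS):
        raise SchemaError(f"correlation: factor rows must be {RISK_FACTORS} in order")
    correlation = CorrelationMatrix(xdf[list(RISK_FACTORS)].to_numpy(dtype=float))

    rdf = read("relative_risks")
    _require_columns(rdf, _RR_COLUMNS, "relative_risks")
    continuous: dict[str, dict[str, ContinuousRR]] = {c: {} for c in CAUSES}
    binary: dict[str, dict[str, float]] = {c: {} for c in CAUSES}
    tobacco: dict[str, dict[str, float]] = {c: {} for c in CAUSES}
    for r in rdf.itertuples():
        if r.cause not in CAUSES:
            raise SchemaError(f"relative_risks: unknown cause {r.cause!r}")
        if r.kind == "continuous":
            continuous[r.cause][r.factor] = ContinuousRR(
                float(r.value), float(r.unit), float(r.reference)
            )
        elif r.kind == "binary":
            binary[r.cause][r.factor] = float(r.value)
        elif r.kind == "tobacco":
            tobacco[r.cause][r.factor] = float(r.value)
        else:
            raise SchemaError(f"relative_risks: unknown kind {r.kind!r}")
    relative_risks = RelativeRiskTable(continuous, binary, tobacco)

    odf = read("mortality")
    _require_columns(odf, _MORTALITY_COLUMNS, "mortality")
    rates: dict[tuple[CohortKey, str], float] = {}
    for r in odf.itertuples():
        if r.cause not in ALL_CAUSES:
            raise SchemaError(f"mortality: unknown cause {r.cause!r}")
        rates[(CohortKey.from_parts(r.age_band, r.gender, r.location), r.cause)] = float(
            r.rate_per_year
        )
    for c in expected:
        for cause in ALL_CAUSES:
            if (c, cause) not in rates:
                raise SchemaError(f"mortality: missing cohort {c} cause {cause}")
    mortality = MortalityTable(rates)

    tdf = read("trends")
    _require_columns(tdf, _TRENDS_COLUMNS, "trends")
    rf_trends: dict[str, float] = {}
    mort_trends: dict[str, float] = {}
    for r in tdf.itertuples():
        if r.kind == "risk_factor":
            rf_trends[r.name] = float(r.annual_change)
        elif r.kind == "mortality":
            mort_trends[r.name] = float(r.annual_change)
        else:
            raise SchemaError(f"trends: unknown kind {r.kind!r}")
    trends = SecularTrends(rf_trends, mort_trends)

    effects = tuple(
        InterventionEffect(
            name=str(e["name"]),
            policy=str(e["policy"]),
            targets=frozenset(e["targets"]),
            central=float(e["central"]),
            ci95=(float(e["ci95"][0]), float(e["ci95"][1])),
        )
        for e in manifest["interventions"]
    )

    taxm = manifest["tax"]
    tax = TaxParameters(
        tax_share={p: float(taxm["tax_share"][p]) for p in PRODUCTS},
        elasticity={
            (p, loc): float(taxm["elasticity"][p][loc]) for p in PRODUCTS for loc in LOCATIONS
        },
    )

    medications = MedicationPolicy.from_dict(manifest["medications"])

    ps = ParameterSet(
        census=census,
        pop_trend=float(manifest["pop_trend_per_year"]),
        marginals=marginals,
        correlation=correlation,
        relative_risks=relative_risks,
        mortality=mortality,
        trends=trends,
        intervention_effects=effects,
        tax=tax,
        medications=medications,
        quit_lag_months=float(manifest["quit_lag_months"]),
        start_year=int(manifest["start_year"]),
        n_years=int(manifest["n_years"]),
        expected_cohorts=expected,
    )
    rep = validate_parameter_set(ps)
    if not rep.ok:
        raise SchemaError("invalid parameter set: " + "; ".join(rep.errors[:5]))
    return ps


def parameter_digest(ps: ParameterSet) -> str:
    """Stable short digest identifying a parameter set's numeric content."""

    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, Mapping):
            return {str(k): encode(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
        if isinstance(obj, (frozenset, set)):
            return sorted(obj)
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        return obj

    payload = json.dumps(encode(ps), sort_keys=True).encode()
    return hashlib.sha1(payload).hexdigest()[:12]
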