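"""Parameter schema: domain types, bundle I/O, validation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from cvdmicrosim import (
    CohortKey,
    default_intervention_effects,
    default_tax_parameters,
    load_parameter_set,
    save_parameter_set,
    validate_parameter_set,
)
from cvdmicrosim.params_io import (
    CorrelationMatrix,
    ParameterSet,
    SchemaError,
    parameter_digest,
)


class TestCohortKey:
    def test_exactly_24_distinct_cohorts(self):
        cohorts = CohortKey.all_cohorts()
        assert len(cohorts) == 24
        assert len(set(cohorts)) == 24
        assert all(20 <= c.age_lo and c.age_hi <= 79 for c in cohorts)

    @pytest.mark.parametrize("bad", [(25, "male", "urban"), (20, "m", "urban"), (20, "male", "city")])
    def test_invalid_parts_rejected(self, bad):
        with pytest.raises(ValueError):
            CohortKey(*bad)

    def test_from_age_covers_band_edges(self):
        assert CohortKey.from_age(29.9, "male", "urban").age_lo == 20
        assert CohortKey.from_age(30.0, "male", "urban").age_lo == 30
        assert CohortKey.from_age(80.0, "male", "urban") is None


class TestBundleIO:
    def test_roundtrip_identity(self, ps_full, tmp_path):
        """save(load(x)) is the identity on the documented schema."""
        save_parameter_set(ps_full, tmp_path / "bundle")
        loaded = load_parameter_set(tmp_path / "bundle")
        assert parameter_digest(loaded) == parameter_digest(ps_full)
        assert loaded.census == ps_full.census
        assert loaded.marginals == ps_full.marginals
        assert loaded.correlation == ps_full.correlation
        assert loaded.mortality.rates == ps_full.mortality.rates
        assert loaded.intervention_effects == ps_full.intervention_effects
        assert loaded.medications == ps_full.medications

    def test_small_fixture_roundtrip(self, ps_small, tmp_path):
        save_parameter_set(ps_small, tmp_path / "b")
        loaded = load_parameter_set(tmp_path / "b")
        assert len(loaded.cohorts) == 4
        assert parameter_digest(loaded) == parameter_digest(ps_small)

    def test_missing_cohort_named_in_error(self, ps_full, tmp_path):
        save_parameter_set(ps_full, tmp_path / "b")
        path = tmp_path / "b" / "marginals.csv"
        df = pd.read_csv(path)
        mask = (df.age_band == "70-79") & (df.gender == "female") & (df.location == "rural")
        df[~mask].to_csv(path, index=False)
        with pytest.raises(SchemaError, match="70-79/female/rural"):
            load_parameter_set(tmp_path / "b")

    def test_unknown_manifest_key_rejected(self, ps_small, tmp_path):
        manifest = save_parameter_set(ps_small, tmp_path / "b")
        manifest.write_text(manifest.read_text() + "\nextra_knob: 3\n")
        with pytest.raises(SchemaError, match="extra_knob"):
            load_parameter_set(tmp_path / "b")

    def test_unit_header_mismatch_rejected(self, ps_small, tmp_path):
        save_parameter_set(ps_small, tmp_path / "b")
        path = tmp_path / "b" / "marginals.csv"
        path.write_text(path.read_text().replace("sbp_mean_mmHg", "sbp_mean_kPa"))
        with pytest.raises(SchemaError, match="units"):
            load_parameter_set(tmp_path / "b")

    def test_missing_bundle_path(self, tmp_path):
        with pytest.raises(SchemaError, match="manifest"):
            load_parameter_set(tmp_path / "nowhere")


class TestDefaults:
    def test_fctc_intervention_effect_sizes(self):
        effects = {e.name: e for e in default_intervention_effects()}
        sf_passive = effects["smoke_free_passive"]
        assert (sf_passive.central, sf_passive.ci95) == (0.64, (0.39, 0.89))
        assert sf_passive.targets == {"passive"}
        sf_active = effects["smoke_free_active"]
        assert (sf_active.central, sf_active.ci95) == (0.01, (0.00, 0.02))
        assert effects["cessation_advice"].central == 0.01
        assert effects["cessation_advice"].ci95 == (0.00, 0.03)
        assert effects["mass_media"].central == 0.05
        assert effects["mass_media"].ci95 == (0.01, 0.11)
        assert effects["advertising_ban"].central == 0.06
        assert effects["advertising_ban"].ci95 == (0.05, 0.07)

    def test_tax_parameters(self):
        tp = default_tax_parameters()
        assert tp.tax_share == {"cigarette": 0.38, "bidi": 0.09}
        # a 10% cigarette price rise reduces rural consumption 3.4%
        assert tp.elasticity[("cigarette", "rural")] == -0.34
        assert tp.elasticity[("cigarette", "urban")] == -0.19
        assert tp.elasticity[("bidi", "rural")] == -0.92
        assert tp.elasticity[("bidi", "urban")] == -0.85


class TestValidation:
    def test_fixture_validates_clean(self, ps_full):
        rep = validate_parameter_set(ps_full)
        assert rep.errors == []
        assert rep.warnings == []

    def test_bad_tobacco_probability_sum(self, ps_small):
        c = ps_small.cohorts[0]
        m = ps_small.marginals[c]
        probs = dict(m.tobacco_probs)
        probs["never"] += 0.2
        bad = dict(ps_small.marginals)
        bad[c] = dataclasses.replace(m, tobacco_probs=probs)
        rep = validate_parameter_set(dataclasses.replace(ps_small, marginals=bad))
        assert any("tobacco_probs" in e and "sums to" in e for e in rep.errors)

    def test_non_psd_correlation_warns_with_repair_delta(self, ps_small):
        # Rank-deficient triangle pushed slightly indefinite, as printed
        # rounded matrices can be.
        v = ps_small.correlation.values.copy()
        v[0, 1] = v[1, 0] = 0.70
        v[0, 2] = v[2, 0] = 0.70
        v[1, 2] = v[2, 1] = -0.02
        corr = CorrelationMatrix(v)
        assert corr.min_eigenvalue() < 0
        rep = validate_parameter_set(dataclasses.replace(ps_small, correlation=corr))
        assert rep.errors == []
        assert any("repair" in w for w in rep.warnings)
        # oracle: the repaired matrix really is PSD and the delta matches
        repaired, delta = corr.nearest_psd()
        assert repaired.min_eigenvalue() >= -1e-10
        assert rep.psd_repair_delta == pytest.approx(delta)

    def test_severely_non_psd_correlation_is_error(self, ps_small):
        v = np.eye(6)
        v[0, 1] = v[1, 0] = 0.95
        v[0, 2] = v[2, 0] = 0.95
        v[1, 2] = v[2, 1] = -0.95
        rep = validate_parameter_set(
            dataclasses.replace(ps_small, correlation=CorrelationMatrix(v))
        )
        assert any("exceeds" in e for e in rep.errors)

    def test_probability_outside_unit_interval(self, ps_small):
        c = ps_small.cohorts[0]
        bad = dict(ps_small.marginals)
        bad[c] = dataclasses.replace(bad[c], diabetes_prev=1.3)
        rep = validate_parameter_set(dataclasses.replace(ps_small, marginals=bad))
        assert any("diabetes_prev" in e for e in rep.errors)

    def test_nearest_psd_clips_eigenvalues(self):
        """Repair oracle: min eigenvalue clipped at 0, unit diagonal restored."""
        v = np.eye(6)
        v[3, 4] = v[4, 3] = 0.9
        v[3, 5] = v[5, 3] = 0.9
        v[4, 5] = v[5, 4] = -0.5
        corr = CorrelationMatrix(v)
        repaired, delta = corr.nearest_psd()
        w = np.linalg.eigvalsh(repaired.values)
        assert w.min() >= -1e-12
        assert np.allclose(np.diag(repaired.values), 1.0)
        assert delta > 0
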