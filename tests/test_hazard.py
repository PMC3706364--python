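"""Hazard model: multiplicative RRs and mean-RR normalized probabilities."""

import dataclasses
import logging

import numpy as np
import pytest

from cvdmicrosim import individual_rr, normalized_cause_probs, sample_profiles
from cvdmicrosim.cohort_sampler import RiskProfile
from cvdmicrosim.constants import TOBACCO_INDEX
from cvdmicrosim.hazard import population_rr, scaled_mortality
from cvdmicrosim.interventions import QuitLag
from cvdmicrosim.params_io import ContinuousRR, MortalityTable, RelativeRiskTable


def _rr_table(sbp_rr=1.3, sbp_unit=10.0, diabetes=2.0) -> RelativeRiskTable:
    continuous = {
        cause: {"sbp": ContinuousRR(sbp_rr, sbp_unit, 115.0), "chol": ContinuousRR(1.0, 1.0, 4.0)}
        for cause in ("mi", "stroke")
    }
    binary = {cause: {"diabetes": diabetes, "chd_hist": 3.0, "cvd_hist": 1.5}
              for cause in ("mi", "stroke")}
    tobacco = {cause: {"never": 1.0, "passive": 1.25, "cigarette": 2.2, "bidi": 2.0,
                       "chewing": 1.3, "dual": 2.5} for cause in ("mi", "stroke")}
    return RelativeRiskTable(continuous, binary, tobacco)


def _profile(**kw) -> RiskProfile:
    base = dict(age=45.0, gender="male", location="urban", sbp=115.0, chol=4.0,
                diabetes=False, chd_hist=False, cvd_hist=False, tobacco="never")
    base.update(kw)
    return RiskProfile(**base)


class TestIndividualRR:
    def test_reference_profile_is_identity(self):
        assert individual_rr(_profile(), _rr_table(), "mi") == pytest.approx(1.0)

    def test_single_binary_factor(self):
        assert individual_rr(_profile(diabetes=True), _rr_table(), "mi") == pytest.approx(2.0)

    def test_continuous_factor_closed_form(self):
        """+20 mmHg at RR 1.3 per 10 mmHg gives 1.3^2 = 1.69."""
        rr = individual_rr(_profile(sbp=135.0), _rr_table(), "mi")
        assert rr == pytest.approx(1.69, abs=1e-12)

    def test_factors_multiply(self):
        rr = individual_rr(_profile(sbp=135.0, diabetes=True, tobacco="cigarette"),
                           _rr_table(), "mi")
        assert rr == pytest.approx(1.69 * 2.0 * 2.2, rel=1e-12)

    def test_former_user_decays_toward_reference(self):
        recent = individual_rr(_profile(tobacco="former", months_since_quit=0.0),
                               _rr_table(), "mi")
        old = individual_rr(_profile(tobacco="former", months_since_quit=119.0),
                            _rr_table(), "mi")
        done = individual_rr(_profile(tobacco="former", months_since_quit=120.0),
                             _rr_table(), "mi")
        assert recent == pytest.approx(2.2)
        assert 1.0 < old < recent
        assert done == pytest.approx(1.0)

    def test_matches_vectorized_path(self, ps_one):
        c = ps_one.cohorts[0]
        pop = sample_profiles(c, 200, ps_one, seed=11)
        vec = population_rr(pop, ps_one.relative_risks, "mi", QuitLag(ps_one.quit_lag_months))
        for i in range(0, 200, 37):
            scalar = individual_rr(pop.profile(i), ps_one.relative_risks, "mi",
                                   QuitLag(ps_one.quit_lag_months))
            # scalar path assumes former users smoked cigarettes; skip those
            if pop.tobacco[i] != TOBACCO_INDEX["former"]:
                assert scalar == pytest.approx(vec[i], rel=1e-12)


class TestNormalizedProbs:
    def test_identical_profiles_get_cohort_rate(self, ps_one):
        """Normalization identity: homogeneous cohort -> p equals m exactly."""
        c = ps_one.cohorts[0]
        pop = sample_profiles(c, 500, ps_one, seed=12)
        # collapse heterogeneity
        pop.sbp[:] = 120.0
        pop.chol[:] = 4.5
        pop.diabetes[:] = False
        pop.chd_hist[:] = False
        pop.cvd_hist[:] = False
        pop.tobacco[:] = TOBACCO_INDEX["never"]
        pop.months_since_quit[:] = np.nan
        probs = normalized_cause_probs(pop, c, ps_one, ps_one.start_year)
        m = ps_one.mortality.rate(c, "mi")
        np.testing.assert_allclose(probs.p_mi, m, rtol=1e-12)

    def test_two_person_normalization_oracle(self, ps_one):
        """RRs {1, 3} with m=0.01 give p = {0.005, 0.015} (hand-computed)."""
        c = ps_one.cohorts[0]
        pop = sample_profiles(c, 2, ps_one, seed=13)
        pop.sbp[:] = 115.0
        pop.chol[:] = 4.0
        pop.diabetes[:] = [False, True]
        pop.chd_hist[:] = False
        pop.cvd_hist[:] = False
        pop.tobacco[:] = TOBACCO_INDEX["never"]
        pop.months_since_quit[:] = np.nan
        rr3 = dataclasses.replace(ps_one, relative_risks=_rr_table(sbp_rr=1.0, diabetes=3.0))
        rates = {k: v for k, v in rr3.mortality.rates.items()}
        rates[(c, "mi")] = 0.01
        ps = dataclasses.replace(rr3, mortality=MortalityTable(rates))
        probs = normalized_cause_probs(pop, c, ps, ps.start_year)
        np.testing.assert_allclose(probs.p_mi, [0.005, 0.015], rtol=1e-12)

    def test_mortality_trend_closed_form(self, ps_one):
        """m(year) = m(2013) * (1 + trend)^(year - 2013)."""
        c = ps_one.cohorts[0]
        trends = dataclasses.replace(ps_one.trends, mortality={"mi": -0.02, "stroke": 0.0, "other": 0.0})
        ps = dataclasses.replace(ps_one, trends=trends)
        m0 = ps.mortality.rate(c, "mi")
        assert scaled_mortality(ps.mortality, ps.trends, c, "mi", ps.start_year + 2,
                                ps.start_year) == pytest.approx(m0 * 0.98**2, rel=1e-12)

    def test_conservation_to_machine_precision(self, ps_one):
        """Cohort mean probability equals the input rate to 1e-12."""
        c = ps_one.cohorts[0]
        pop = sample_profiles(c, 2_000, ps_one, seed=14)
        for year in (ps_one.start_year, ps_one.start_year + 5):
            probs = normalized_cause_probs(pop, c, ps_one, year)
            for cause, p in (("mi", probs.p_mi), ("stroke", probs.p_stroke)):
                m = scaled_mortality(ps_one.mortality, ps_one.trends, c, cause, year,
                                     ps_one.start_year)
                assert abs(p[pop.alive].mean() - m) < 1e-12

    def test_other_cause_has_no_individual_rr(self, ps_one):
        c = ps_one.cohorts[0]
        pop = sample_profiles(c, 100, ps_one, seed=15)
        probs = normalized_cause_probs(pop, c, ps_one, ps_one.start_year)
        assert np.unique(probs.p_other).size == 1

    def test_monotone_in_risk_factors(self, ps_one):
        """Raising a factor with RR>1 weakly increases p_mi and p_stroke."""
        c = ps_one.cohorts[0]
        pop = sample_profiles(c, 300, ps_one, seed=16)
        base = normalized_cause_probs(pop, c, ps_one, ps_one.start_year)
        raised = pop.copy()
        raised.sbp += 10.0
        norm = {
            cause: population_rr(pop, ps_one.relative_risks, cause,
                                 QuitLag(ps_one.quit_lag_months))
            for cause in ("mi", "stroke")
        }
        up = normalized_cause_probs(raised, c, ps_one, ps_one.start_year, norm_rr=norm)
        assert (up.p_mi >= base.p_mi).all()
        assert (up.p_stroke >= base.p_stroke).all()

    def test_removing_tobacco_never_raises_risk(self, ps_one):
        c = ps_one.cohorts[0]
        pop = sample_profiles(c, 1_000, ps_one, seed=17)
        norm = {
            cause: population_rr(pop, ps_one.relative_risks, cause,
                                 QuitLag(ps_one.quit_lag_months))
            for cause in ("mi", "stroke")
        }
        cleared = pop.copy()
        cleared.tobacco[:] = TOBACCO_INDEX["never"]
        cleared.months_since_quit[:] = np.nan
        base = normalized_cause_probs(pop, c, ps_one, ps_one.start_year, norm_rr=norm)
        off = normalized_cause_probs(cleared, c, ps_one, ps_one.start_year, norm_rr=norm)
        assert (off.p_mi <= base.p_mi + 1e-15).all()
        assert (off.p_stroke <= base.p_stroke + 1e-15).all()

    def test_runaway_probability_clamped_with_warning(self, ps_one, caplog):
        c = ps_one.cohorts[0]
        pop = sample_profiles(c, 50, ps_one, seed=18)
        rates = {k: v for k, v in ps_one.mortality.rates.items()}
        rates[(c, "mi")] = 0.9
        ps = dataclasses.replace(ps_one, mortality=MortalityTable(rates))
        with caplog.at_level(logging.WARNING, logger="cvdmicrosim.hazard"):
            probs = normalized_cause_probs(pop, c, ps, ps.start_year)
        assert probs.p_mi.max() <= 0.999
        assert any("clamped" in r.message for r in caplog.records)
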