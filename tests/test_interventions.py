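"""Tobacco-control effect algebra and scenario application."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvdmicrosim import (
    QuitLag,
    combine_effects,
    coverage_ramp,
    effective_ramp,
    quit_benefit,
    sample_profiles,
    scenario_preset,
    tax_effect,
)
from cvdmicrosim.constants import LOCATIONS, TOBACCO_INDEX
from cvdmicrosim.interventions import (
    ChannelState,
    ScenarioSpec,
    apply_tobacco_scenario,
    channel_user_masks,
    delayed,
)
from cvdmicrosim.params_io import default_tax_parameters

TP = default_tax_parameters()

#: Published anchors: (product, increase %, expected location-averaged reduction)
TAX_ANCHORS = [
    ("bidi", 50.0, 0.04),
    ("bidi", 300.0, 0.24),
    ("bidi", 500.0, 0.40),
    ("cigarette", 50.0, 0.06),
    ("cigarette", 300.0, 0.31),
    ("cigarette", 500.0, 0.52),
]


class TestTaxEffect:
    def test_zero_increase_is_zero(self):
        for product in ("bidi", "cigarette"):
            for loc in LOCATIONS:
                assert tax_effect(product, loc, 0.0, TP) == 0.0

    def test_bidi_rural_50_closed_form(self):
        # 0.92 x 0.09 x 50/100 = 0.0414
        assert tax_effect("bidi", "rural", 50.0, TP) == pytest.approx(0.0414, abs=1e-12)

    @pytest.mark.parametrize("product,pct,expected", TAX_ANCHORS)
    def test_published_anchors_within_3_points(self, product, pct, expected):
        avg = np.mean([tax_effect(product, loc, pct, TP) for loc in LOCATIONS])
        assert abs(avg - expected) <= 0.03

    def test_nondecreasing_and_piecewise_linear(self):
        grid = np.linspace(0, 1000, 101)
        vals = [tax_effect("cigarette", "rural", x, TP) for x in grid]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        # linear below the cap: second differences vanish
        below = [v for v in vals if v < 1.0]
        d2 = np.diff(below, 2)
        assert np.abs(d2).max() < 1e-12
        assert tax_effect("bidi", "rural", 1e6, TP) == 1.0

    def test_negative_increase_rejected(self):
        with pytest.raises(ValueError):
            tax_effect("bidi", "rural", -1.0, TP)


class TestCombineEffects:
    def test_examples(self):
        assert combine_effects([0.24], "cumulative") == pytest.approx(0.24)
        assert combine_effects([0.5, 0.5], "cumulative") == pytest.approx(0.75)
        assert combine_effects([0.04, 0.31], "max_only") == pytest.approx(0.31)
        assert combine_effects([], "cumulative") == 0.0

    def test_cigarette_pathway_product_oracle(self):
        """Direct product over the five cigarette-channel central effects."""
        effects = [0.01, 0.01, 0.05, 0.06, 0.31]
        expected = 1.0 - math.prod(1.0 - e for e in effects)
        assert combine_effects(effects, "cumulative") == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.3961, abs=1e-4)

    def test_synergy_inflates_each_effect_25pct(self):
        assert combine_effects([0.2], "synergy25") == pytest.approx(0.25)
        assert combine_effects([0.9], "synergy25") == 1.0  # capped per effect

    @settings(deadline=None, max_examples=200)
    @given(st.lists(st.floats(0.0, 1.0), max_size=6), st.randoms(use_true_random=False))
    def test_mode_ordering_and_permutation_invariance(self, effects, rnd):
        m = combine_effects(effects, "max_only")
        c = combine_effects(effects, "cumulative")
        s = combine_effects(effects, "synergy25")
        assert 0.0 <= m <= c + 1e-12 <= s + 2e-12 <= 1.0 + 2e-12
        shuffled = list(effects)
        rnd.shuffle(shuffled)
        assert combine_effects(shuffled, "cumulative") == pytest.approx(c, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            combine_effects([0.5], "average")
        with pytest.raises(ValueError):
            combine_effects([1.5], "cumulative")


class TestRamps:
    def test_baseline_closed_form(self):
        assert coverage_ramp("baseline_10yr_linear", 0) == pytest.approx(0.1)
        assert coverage_ramp("baseline_10yr_linear", 9) == pytest.approx(1.0)

    def test_delayed_closed_form(self):
        assert coverage_ramp("delayed_80pct_5yr", 2) == pytest.approx(0.48)
        assert coverage_ramp("delayed_80pct_5yr", 4) == pytest.approx(0.8)
        assert coverage_ramp("delayed_80pct_5yr", 9) == pytest.approx(0.8)

    def test_year_bounds(self):
        with pytest.raises(ValueError):
            coverage_ramp("baseline_10yr_linear", 10)
        with pytest.raises(ValueError):
            effective_ramp("baseline_10yr_linear", -1)

    def test_effective_ramp_baseline_is_response_ramp(self):
        for y in range(10):
            assert effective_ramp("baseline_10yr_linear", y) == coverage_ramp(
                "baseline_10yr_linear", y
            )

    def test_effective_ramp_delayed_convolution_oracle(self):
        """Each covered tranche starts its own 10-year response."""
        for y in range(10):
            expected = sum(0.16 * (y - k + 1) / 10.0 for k in range(min(y, 4) + 1))
            assert effective_ramp("delayed_80pct_5yr", y) == pytest.approx(expected, abs=1e-12)

    def test_delayed_effect_always_below_baseline(self):
        for y in range(10):
            assert effective_ramp("delayed_80pct_5yr", y) < effective_ramp(
                "baseline_10yr_linear", y
            )


class TestQuitBenefit:
    def test_no_elapsed_time(self):
        assert quit_benefit(2.0, 0.0) == pytest.approx(2.0)

    def test_one_time_constant(self):
        assert quit_benefit(1.5, 19.1) == pytest.approx(1.0 + 0.5 * math.exp(-1.0), abs=1e-9)
        assert quit_benefit(1.5, 19.1) == pytest.approx(1.1839, abs=1e-4)

    def test_floor_at_120_months(self):
        assert quit_benefit(2.0, 120.0) == 1.0
        assert quit_benefit(2.0, 119.9) > 1.0  # raw value ~1.0019 just before

    def test_strictly_decreasing_and_continuous(self):
        months = np.linspace(0.0, 119.9, 500)
        vals = quit_benefit(2.0, months)
        assert (np.diff(vals) < 0).all()
        assert np.abs(np.diff(vals)).max() < 0.02  # no jumps on a fine grid
        assert vals[0] == pytest.approx(2.0)

    def test_custom_time_constant(self):
        assert quit_benefit(3.0, 10.0, QuitLag(10.0)) == pytest.approx(
            1.0 + 2.0 * math.exp(-1.0)
        )
        with pytest.raises(ValueError):
            QuitLag(0.0)


def _pooled_population(ps, n, seed):
    pop = sample_profiles(ps.cohorts[0], n, ps, seed=seed)
    state = ChannelState()
    counts = {}
    for channel, mask in channel_user_masks(pop).items():
        for li, loc in enumerate(LOCATIONS):
            counts[(channel, loc)] = float((mask & (pop.location == li)).sum())
    state.register_users(counts)
    return pop, state


class TestApplyScenario:
    def test_null_scenario_is_noop(self, ps_full):
        pop, state = _pooled_population(ps_full, 2_000, seed=21)
        before = pop.tobacco.copy()
        rng = np.random.default_rng(0)
        apply_tobacco_scenario(pop, ScenarioSpec("baseline"), ps_full, 3, rng, state)
        np.testing.assert_array_equal(pop.tobacco, before)

    def test_brief_advice_final_year_quitter_count(self, ps_full):
        """1% effect fully phased in converts ~1% of smokers, cumulatively."""
        # use a male cohort with many smokers
        cohort = [c for c in ps_full.cohorts if c.gender == "male"][0]
        ps = dataclasses.replace(ps_full, census={cohort: ps_full.census[cohort]})
        pop, state = _pooled_population(ps, 10_000, seed=22)
        scenario = scenario_preset("cessation_advice")
        rng = np.random.default_rng(1)
        n0_active = sum(state.n0[(ch, loc)] for ch in ("active_cigarette", "active_bidi")
                        for loc in LOCATIONS)
        for t in range(10):
            apply_tobacco_scenario(pop, scenario, ps, t, rng, state)
        total_quit = sum(state.quit.values())
        assert total_quit == pytest.approx(0.01 * n0_active, abs=2.0)

    def test_smoke_free_passive_channel(self, ps_full):
        """Passive exposure falls by 64% x ramp; quitters carry the lag."""
        pop, state = _pooled_population(ps_full, 20_000, seed=23)
        loc = LOCATIONS[pop.location[0]]
        n_passive0 = state.n0[("passive", loc)]
        scenario = scenario_preset("smoke_free")
        rng = np.random.default_rng(2)
        for t in range(5):
            apply_tobacco_scenario(pop, scenario, ps_full, t, rng, state)
        expected = 0.64 * effective_ramp("baseline_10yr_linear", 4) * n_passive0
        assert state.quit[("passive", loc)] == pytest.approx(expected, abs=2.0)
        remaining = (pop.tobacco == TOBACCO_INDEX["passive"]).sum()
        assert remaining == pytest.approx(n_passive0 - expected, abs=2.0)
        passive_rr = ps_full.relative_risks.tobacco_rr("mi", "passive")
        quitters = ~np.isnan(pop.months_since_quit) & np.isclose(pop.rr_pre_mi, passive_rr)
        assert quitters.sum() > 0

    def test_dual_users_keep_chewing(self, ps_full):
        pop, state = _pooled_population(ps_full, 20_000, seed=24)
        dual_before = (pop.tobacco == TOBACCO_INDEX["dual"]).sum()
        scenario = scenario_preset("tax_300_both")
        rng = np.random.default_rng(3)
        for t in range(10):
            apply_tobacco_scenario(pop, scenario, ps_full, t, rng, state)
        dual_after = (pop.tobacco == TOBACCO_INDEX["dual"]).sum()
        assert dual_after < dual_before
        chew_quitters = (pop.tobacco == TOBACCO_INDEX["chewing"]) & ~np.isnan(
            pop.months_since_quit
        )
        assert chew_quitters.sum() > 0
        # their decay floor is the chewing RR, not full recovery
        rr_chew = ps_full.relative_risks.tobacco_rr("mi", "chewing")
        np.testing.assert_allclose(pop.rr_post_mi[chew_quitters], rr_chew)

    def test_monotone_trajectory_no_op_when_target_met(self, ps_full):
        pop, state = _pooled_population(ps_full, 5_000, seed=25)
        scenario = scenario_preset("advertising_ban")
        rng = np.random.default_rng(4)
        apply_tobacco_scenario(pop, scenario, ps_full, 5, rng, state)
        quit_after_first = dict(state.quit)
        # re-applying an earlier (lower) target must change nothing
        apply_tobacco_scenario(pop, scenario, ps_full, 2, rng, state)
        assert state.quit == quit_after_first

    def test_delayed_variant_renames_and_reramps(self):
        s = delayed(scenario_preset("all_tc_cumulative"))
        assert s.ramp == "delayed_80pct_5yr"
        assert s.name.endswith("_delayed")
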