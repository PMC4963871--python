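"""Healthy Beverage Index scoring engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hbi_swap import (
    BeverageGroup,
    FluidRequirement,
    HBIComponent,
    HBIComponentConfig,
    ScoringError,
    default_component_configs,
    score_component,
    score_hbi,
)
from hbi_swap.model import ML_PER_FL_OZ
from conftest import make_summary


def ssb_cfg(hi=8.0, zero=16.0, maxp=10.0, mode="proportional"):
    return HBIComponentConfig(
        component_id=HBIComponent.SSB, standard_lo=0.0, standard_hi=hi,
        zero_point=zero, max_points=maxp, mode=mode,
    )


class TestScoreComponent:
    def test_full_credit_at_band_edge(self):
        s = make_summary(oz_by_group={BeverageGroup.SSB: 8.0})
        assert score_component(s, ssb_cfg()) == 10.0

    def test_zero_at_zero_point(self):
        s = make_summary(oz_by_group={BeverageGroup.SSB: 16.0}, total_kcal=3000)
        assert score_component(s, ssb_cfg()) == 0.0

    def test_linear_interpolation_matches_independent_piecewise_eval(self):
        """Engine output equals np.interp over the same breakpoints."""
        cfg = ssb_cfg(hi=8.0, zero=16.0, maxp=10.0)
        for oz in [0.0, 4.0, 8.0, 10.0, 12.0, 14.0, 16.0, 30.0]:
            s = make_summary(oz_by_group={BeverageGroup.SSB: oz}, total_kcal=3000)
            expected = float(np.interp(oz, [8.0, 16.0], [10.0, 0.0]))
            assert score_component(s, cfg) == pytest.approx(expected)
        # the documented midpoint: 12 oz with band edge 8 and zero point 16
        s = make_summary(oz_by_group={BeverageGroup.SSB: 12.0}, total_kcal=3000)
        assert score_component(s, cfg) == pytest.approx(5.0)

    def test_binary_mode_is_all_or_nothing(self):
        cfg = ssb_cfg(mode="binary")
        inside = make_summary(oz_by_group={BeverageGroup.SSB: 7.0})
        outside = make_summary(oz_by_group={BeverageGroup.SSB: 9.0})
        assert score_component(inside, cfg) == 10.0
        assert score_component(outside, cfg) == 0.0

    def test_more_is_better_side(self):
        cfg = HBIComponentConfig(
            component_id=HBIComponent.WATER, standard_lo=50.0, standard_hi=float("inf"),
            zero_point=0.0, max_points=15.0, mode="proportional",
        )
        req_oz = 2.7 * 1000 / ML_PER_FL_OZ  # female requirement in fl oz
        s = make_summary(oz_by_group={BeverageGroup.WATER: req_oz / 4})  # 25% of requirement
        assert score_component(s, cfg) == pytest.approx(15.0 * 25.0 / 50.0)

    def test_zero_point_inside_band_rejected(self):
        with pytest.raises(ValueError, match="zero_point"):
            ssb_cfg(hi=8.0, zero=4.0)


class TestFluidRequirement:
    def test_default_requirements_by_sex(self):
        fluid = FluidRequirement()
        assert fluid.liters_for("M") == 3.7
        assert fluid.liters_for("F") == 2.7

    def test_meets_fluid_requirement_component(self):
        cfg = next(
            c for c in default_component_configs()
            if c.component_id == HBIComponent.MEETS_FLUID_REQS
        )
        oz_needed = 2.7 * 1000 / ML_PER_FL_OZ
        meets = make_summary(sex="F", oz_by_group={BeverageGroup.WATER: oz_needed + 1})
        fails = make_summary(sex="F", oz_by_group={BeverageGroup.WATER: oz_needed - 1})
        assert score_component(meets, cfg) == cfg.max_points
        assert score_component(fails, cfg) == 0.0


class TestScoreHBI:
    def test_all_metrics_in_band_scores_100(self):
        # modest water-heavy pattern meeting every standard
        req_oz = 3.7 * 1000 / ML_PER_FL_OZ
        s = make_summary(
            sex="M",
            total_kcal=2500.0,
            oz_by_group={BeverageGroup.WATER: req_oz + 5, BeverageGroup.SSB: 2.0},
        )
        assert score_hbi(s).total == pytest.approx(100.0)

    def test_everything_beyond_zero_points_scores_0(self):
        s = make_summary(
            sex="F",
            total_kcal=8000.0,
            oz_by_group={
                BeverageGroup.WATER: 0.0,
                BeverageGroup.COFFEE_TEA_UNSWEETENED: 70.0,
                BeverageGroup.LOW_FAT_MILK: 40.0,
                BeverageGroup.DIET: 70.0,
                BeverageGroup.JUICE_100: 20.0,
                BeverageGroup.ALCOHOL: 50.0,
                BeverageGroup.WHOLE_MILK: 30.0,
                BeverageGroup.SSB: 120.0,
            },
            kcal_by_group={BeverageGroup.SSB: 4000.0},
        )
        # percent energy from beverages is far above its zero point too
        assert s.pct_energy_bev > 30
        # raise the fluid requirement so even 400 oz falls short of it
        strict_fluid = FluidRequirement(male_l=15.0, female_l=15.0)
        assert score_hbi(s, fluid=strict_fluid).total == 0.0

    def test_halving_ssb_strictly_improves_heavy_profile(self):
        heavy = make_summary(oz_by_group={BeverageGroup.SSB: 12.0}, total_kcal=2500)
        lighter = make_summary(oz_by_group={BeverageGroup.SSB: 6.0}, total_kcal=2500)
        assert score_hbi(lighter).total > score_hbi(heavy).total

    def test_wrong_point_total_rejected(self):
        configs = default_component_configs()
        configs[0].max_points += 1.0
        with pytest.raises(ScoringError, match="sum to 100"):
            score_hbi(make_summary(), configs)

    def test_duplicate_components_rejected(self):
        configs = default_component_configs()
        configs[1] = configs[0].model_copy()
        with pytest.raises(ScoringError):
            score_hbi(make_summary(), configs)

    @given(
        ssb=st.floats(0, 200),
        water=st.floats(0, 200),
        coffee=st.floats(0, 100),
        juice=st.floats(0, 60),
        alcohol=st.floats(0, 80),
        milk=st.floats(0, 60),
        total_kcal=st.floats(0, 6000),
        sex=st.sampled_from(["M", "F"]),
    )
    @settings(max_examples=200, deadline=None)
    def test_total_always_in_0_100(self, ssb, water, coffee, juice, alcohol, milk, total_kcal, sex):
        oz = {
            BeverageGroup.SSB: ssb,
            BeverageGroup.WATER: water,
            BeverageGroup.COFFEE_TEA_UNSWEETENED: coffee,
            BeverageGroup.JUICE_100: juice,
            BeverageGroup.ALCOHOL: alcohol,
            BeverageGroup.WHOLE_MILK: milk,
        }
        kcal = {g: 0.0 for g in oz}  # keep total >= beverage energy for any draw
        s = make_summary(sex=sex, total_kcal=total_kcal, oz_by_group=oz, kcal_by_group=kcal)
        total = score_hbi(s).total
        assert 0.0 <= total <= 100.0
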