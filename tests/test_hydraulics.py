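import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from microtrap.geometry import ChannelSegment, TrapUnitGeometry, preset_design, straight
from microtrap.hydraulics import (
    UM,
    FlowConditions,
    FluidSpec,
    WATER,
    criterion_check,
    f_re,
    flow_split,
    hydraulic_diameter,
    path_resistances,
    reynolds_number,
    segment_resistance,
)

# independently evaluated duct-formula values (exact-rational evaluation of
# fRe = 96(1 - 1.3553a + 1.9467a^2 - 1.7012a^3 + 0.9564a^4 - 0.2537a^5)
# and R = fRe L eta / (2 Dh^2 A) for water)
FRE_ORACLE = {1 / 3: 68.37977, 0.6: 59.94187, 1.0: 56.91840, 0.5: 62.22930, 0.2: 76.28616}
R_GAP_D1 = 4.0521347e13        # 5x15 μm², L=5 μm, Pa·s/m³
R_BYPASS_D1 = 1.8300476e14     # 25x15 μm², L=805 μm
R_CHAMBER_D1 = 1.1366756e13    # 25x15 μm², L=50 μm


class TestHydraulicDiameter:
    def test_square_duct_equals_side(self):
        assert hydraulic_diameter(straight(15, 1, 15)) == pytest.approx(15 * UM)

    def test_rectangular_duct_4A_over_P(self):
        # 4*375/80 = 18.75 μm
        assert hydraulic_diameter(straight(25, 1, 15)) == pytest.approx(18.75 * UM)

    def test_parallel_plate_limit(self):
        assert hydraulic_diameter(straight(1e9, 1, 15)) == pytest.approx(30 * UM, rel=1e-6)


class TestFRe:
    @pytest.mark.parametrize("aspect, expected", sorted(FRE_ORACLE.items()))
    def test_shah_london_values(self, aspect, expected):
        assert f_re(aspect) == pytest.approx(expected, abs=1e-4)

    def test_parallel_plate_limit_is_96(self):
        assert f_re(1e-9) == pytest.approx(96.0, abs=1e-5)

    @pytest.mark.parametrize("aspect", [0.0, -0.5, 1.2])
    def test_domain_enforced(self, aspect):
        with pytest.raises(ValueError):
            f_re(aspect)

    @given(st.floats(1e-6, 1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_within_rectangular_duct_bounds(self, aspect):
        assert 56.9 <= f_re(aspect) <= 96.0


class TestReynolds:
    def test_creeping_flow_magnitude(self):
        re = reynolds_number(WATER, 100e-6, 18.75e-6)
        assert re == pytest.approx(1.875e-3)

    def test_zero_velocity(self):
        assert reynolds_number(WATER, 0.0, 10e-6) == 0.0

    def test_linearity_in_velocity(self):
        assert reynolds_number(WATER, 2e-4, 1e-5) == pytest.approx(
            2 * reynolds_number(WATER, 1e-4, 1e-5))


class TestSegmentResistance:
    def test_frozen_oracle_values(self):
        assert segment_resistance(straight(5, 5, 15)) == pytest.approx(R_GAP_D1, rel=1e-6)
        assert segment_resistance(straight(25, 805, 15)) == pytest.approx(R_BYPASS_D1, rel=1e-6)
        assert segment_resistance(straight(25, 50, 15)) == pytest.approx(R_CHAMBER_D1, rel=1e-6)

    def test_series_additivity(self):
        one = segment_resistance(straight(12, 30, 15))
        two = segment_resistance(straight(12, 60, 15))
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_degenerate_taper_matches_straight(self):
        taper = ChannelSegment(10.0, 10.0 + 1e-12, 20.0, 15.0)
        ref = segment_resistance(straight(10, 20, 15))
        assert segment_resistance(taper) == pytest.approx(ref, rel=1e-10)

    @given(st.floats(4, 40), st.floats(4, 40), st.floats(1, 100))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_taper_between_end_width_straights(self, w0, w1, length):
        taper = ChannelSegment(w0, w1, length, 15.0)
        r = segment_resistance(taper)
        r0 = segment_resistance(straight(w0, length, 15.0))
        r1 = segment_resistance(straight(w1, length, 15.0))
        assert min(r0, r1) * (1 - 1e-9) <= r <= max(r0, r1) * (1 + 1e-9)

    def test_resistance_linear_in_viscosity(self):
        seg = straight(10, 50, 15)
        r1 = segment_resistance(seg, FluidSpec(viscosity=1e-3))
        r2 = segment_resistance(seg, FluidSpec(viscosity=3e-3))
        assert r2 == pytest.approx(3 * r1)


class TestFlowConditions:
    def test_exactly_one_spec(self):
        with pytest.raises(ValueError):
            FlowConditions(mean_velocity=1e-4, volumetric_rate=1e-12)
        with pytest.raises(ValueError):
            FlowConditions()

    def test_ul_per_h_conversion(self):
        fc = FlowConditions.from_ul_per_h(3600.0)
        assert fc.volumetric_rate == pytest.approx(1e-9)

    def test_rate_from_velocity(self):
        fc = FlowConditions(mean_velocity=1e-4)
        assert fc.rate(2e-9) == pytest.approx(2e-13)


class TestFlowSplit:
    def test_conservation(self, design1):
        fs = flow_split(design1)
        q_in = FlowConditions(mean_velocity=100e-6).rate(25 * UM * 15 * UM)
        assert fs.Q1 + fs.Q2 == pytest.approx(q_in, rel=1e-12)

    def test_pressure_drops_balance_and_sum(self, design1):
        fs = flow_split(design1)
        assert fs.dp1 == pytest.approx(fs.dp2, rel=1e-12)
        assert fs.dp1 == pytest.approx(sum(fs.dp_regions), rel=1e-12)

    def test_valve_on_blocks_path1(self, design1):
        fs = flow_split(design1, valve_on=True)
        q_in = FlowConditions(mean_velocity=100e-6).rate(25 * UM * 15 * UM)
        assert fs.Q1 == 0.0
        assert fs.Q2 == pytest.approx(q_in)

    def test_occupied_trap_blocks_path1(self, design1):
        assert flow_split(design1, trap_occupied=True).Q1 == 0.0

    def test_symmetric_parallel_paths_split_evenly(self):
        # bypass identical to the middle chamber, vestigial pockets/gaps
        unit = TrapUnitGeometry.from_dims(
            L11=1e-6, L12=1e-6, W12=24.999, W13=25, L13=50, W2=25, L2=50, H=15)
        fs = flow_split(unit)
        assert fs.ratio == pytest.approx(1.0, rel=1e-3)

    def test_dp_linear_in_viscosity_and_velocity(self, design1):
        base = flow_split(design1, WATER, FlowConditions(mean_velocity=100e-6))
        thick = flow_split(design1, FluidSpec(viscosity=2e-3),
                           FlowConditions(mean_velocity=100e-6))
        fast = flow_split(design1, WATER, FlowConditions(mean_velocity=200e-6))
        assert thick.dp1 == pytest.approx(2 * base.dp1)
        assert fast.dp1 == pytest.approx(2 * base.dp1)

    @given(st.floats(300, 3000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_longer_bypass_decreases_ratio(self, L2):
        u1 = TrapUnitGeometry.from_dims(L11=10, L12=5, W12=5, W13=25,
                                        L13=50, W2=25, L2=L2, H=15)
        u2 = TrapUnitGeometry.from_dims(L11=10, L12=5, W12=5, W13=25,
                                        L13=50, W2=25, L2=L2 * 1.1, H=15)
        assert flow_split(u2).ratio < flow_split(u1).ratio

    @given(st.floats(2, 20))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_narrower_gap_decreases_trap_flow(self, W12):
        u1 = TrapUnitGeometry.from_dims(L11=10, L12=5, W12=W12, W13=25,
                                        L13=50, W2=25, L2=805, H=15)
        u2 = TrapUnitGeometry.from_dims(L11=10, L12=5, W12=0.9 * W12, W13=25,
                                        L13=50, W2=25, L2=805, H=15)
        assert flow_split(u2).Q1 < flow_split(u1).Q1

    def test_lumped_pocket_variant_is_more_resistive(self, design1):
        r_tapered, _ = path_resistances(design1)
        r_lumped, _ = path_resistances(design1, lump_pockets=True)
        assert r_lumped.sum() > r_tapered.sum()


class TestCriterion:
    @pytest.mark.parametrize("design", [1, 2])
    def test_catalogue_designs_pass_at_15um_height(self, design):
        rep = criterion_check(preset_design(design, 15))
        assert rep.passed and rep.ratio < 1.0

    def test_report_table_lists_all_regions(self, design1):
        rep = criterion_check(design1)
        assert list(rep.table["region"]) == [
            "pocket_in", "gap_in", "chamber", "gap_out", "pocket_out", "bypass"]
        assert (rep.table["R_Pa_s_per_m3"] > 0).all()

    def test_identical_parallel_paths_are_borderline(self):
        unit = TrapUnitGeometry.from_dims(
            L11=1e-6, L12=1e-6, W12=24.999, W13=25, L13=50, W2=25, L2=50, H=15)
        rep = criterion_check(unit)
        assert rep.ratio == pytest.approx(1.0, rel=1e-3)
        assert not rep.passed
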