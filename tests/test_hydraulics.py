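"""Unit conversions, conduit resistances and the Whitaker inversion."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pyeloflow.hydraulics import (
    AccessSheath,
    Anatomy,
    FluidProperties,
    Ureteroscope,
    WhitakerMeasurement,
    annular_effective_d4,
    annular_resistance,
    circular_resistance,
    inflow_resistance,
    outflow_resistance,
    resistance_set,
    sheath_from_label,
    stretched_diameter,
    table1_anatomy,
    table1_scope,
    whitaker_upj_diameter,
    withdrawal_resistance,
)
from pyeloflow.units import (
    cmH2O_to_Pa,
    cP_to_PaS,
    french_to_meters,
    meters_to_french,
    ml_per_min_to_m3_per_s,
    ml_per_s_to_m3_per_s,
    parse_quantity,
)

MU = 1e-3  # saline, 1 cP


@pytest.mark.parametrize(
    "fr, meters",
    [(3.0, 1.0e-3), (0.0, 0.0), (7.5, 2.5e-3), (10.0, 10.0e-3 / 3.0)],
)
def test_french_gauge_conversion(fr, meters):
    assert french_to_meters(fr) == pytest.approx(meters, rel=1e-15)
    assert meters_to_french(french_to_meters(fr)) == pytest.approx(fr, rel=1e-15)


@pytest.mark.parametrize("cm, pa", [(1.0, 98.1), (0.0, 0.0), (40.0, 3924.0)])
def test_cmH2O_conversion(cm, pa):
    assert cmH2O_to_Pa(cm) == pytest.approx(pa, rel=1e-15)


def test_negative_french_rejected():
    with pytest.raises(ValueError):
        french_to_meters(-1.0)


def test_quantity_parsing_matches_direct_conversions():
    assert parse_quantity("7.5 Fr", expect="length") == french_to_meters(7.5)
    assert parse_quantity("150 cmH2O", expect="pressure") == cmH2O_to_Pa(150)
    assert parse_quantity("1 cP", expect="viscosity") == cP_to_PaS(1.0)
    assert parse_quantity("15 mL/min", expect="flow") == ml_per_min_to_m3_per_s(15)
    assert parse_quantity("2 min", expect="time") == 120.0
    with pytest.raises(ValueError):
        parse_quantity("10 furlong")
    with pytest.raises(ValueError):
        parse_quantity("10 Fr", expect="pressure")
    with pytest.raises(ValueError):
        parse_quantity(150, expect="pressure")  # bare number for a pressure


class TestCircularResistance:
    def test_scope_channel_value(self):
        # 67 cm channel of 1.2 mm bore in saline
        r = circular_resistance(0.67, 1.2e-3, MU)
        assert r == pytest.approx(1.316e10, rel=1e-3)

    def test_fourth_power_scaling(self):
        r1 = circular_resistance(0.1, 1e-3, MU)
        assert circular_resistance(0.1, 2e-3, MU) == pytest.approx(r1 / 16, rel=1e-12)

    def test_nominal_upj_value(self):
        r = circular_resistance(0.005, french_to_meters(1.3), MU)
        assert r == pytest.approx(5.78e9, rel=1e-2)

    @pytest.mark.parametrize("bad", [(-1, 1e-3, MU), (0.1, 0, MU), (0.1, 1e-3, 0)])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            circular_resistance(*bad)


class TestAnnularEffectiveD4:
    def test_ten_fr_lumen_around_scope(self):
        d4 = annular_effective_d4(french_to_meters(10), french_to_meters(7.5))
        assert d4 == pytest.approx(2.2536e-12, rel=1e-3)

    def test_circular_limit(self):
        # the correction term decays like 1/ln(d_o/d_i), so convergence to
        # the circular value is slow but monotone
        d_o = 3e-3
        errors = [
            abs(annular_effective_d4(d_o, d_o * r) - d_o**4) / d_o**4
            for r in (1e-3, 1e-30, 1e-300)
        ]
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] < 2e-3

    def test_closing_annulus_vanishes(self):
        d_o = 3e-3
        assert annular_effective_d4(d_o, d_o * (1 - 1e-7)) < 1e-4 * d_o**4

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            annular_effective_d4(2e-3, 2e-3)
        with pytest.raises(ValueError):
            annular_effective_d4(2e-3, 3e-3)

    @given(
        d_o=st.floats(1e-4, 1e-2),
        gap=st.floats(1e-6, 5e-3),
        delta=st.floats(1e-6, 5e-3),
    )
    @settings(max_examples=50, deadline=None)
    def test_positive_bounded_and_monotone_in_outer(self, d_o, gap, delta):
        d_i = d_o
        d_o = d_i + gap
        d4 = annular_effective_d4(d_o, d_i)
        assert 0 < d4 < d_o**4 - d_i**4  # the log term is strictly positive
        assert annular_effective_d4(d_o + delta, d_i) > d4


class TestAnnularResistance:
    def test_sheath_segment_value(self):
        r = annular_resistance(0.35, french_to_meters(10), french_to_meters(7.5), MU)
        assert r == pytest.approx(6.33e9, rel=1e-2)

    def test_circular_limit_consistency(self):
        r_ann = annular_resistance(0.1, 3e-3, 3e-303, MU)
        assert r_ann == pytest.approx(circular_resistance(0.1, 3e-3, MU), rel=2e-3)

    def test_linear_in_length(self):
        r = annular_resistance(0.2, 3e-3, 2e-3, MU)
        assert annular_resistance(0.1, 3e-3, 2e-3, MU) == pytest.approx(r / 2, rel=1e-12)


def test_stretched_diameter():
    assert stretched_diameter(2.5e-3, 1.14) == pytest.approx(2.85e-3)
    assert stretched_diameter(2.5e-3, 1.11) == pytest.approx(2.775e-3)
    assert stretched_diameter(2.5e-3, 1.0) == 2.5e-3
    with pytest.raises(ValueError):
        stretched_diameter(2.5e-3, 0.9)


class TestCircuitResistances:
    def test_inflow_value_and_scalings(self, scope):
        r = inflow_resistance(scope, MU)
        assert r == pytest.approx(1.316e10, rel=1e-3)
        double_len = Ureteroscope(scope.shaft_diameter, scope.channel_diameter, 2 * scope.working_length)
        assert inflow_resistance(double_len, MU) == pytest.approx(2 * r, rel=1e-12)
        wide = Ureteroscope(scope.shaft_diameter, 2 * scope.channel_diameter, scope.working_length)
        assert inflow_resistance(wide, MU) == pytest.approx(r / 16, rel=1e-12)

    def test_outflow_no_sheath(self, scope, anatomy):
        r = outflow_resistance(scope, anatomy, None, MU)
        assert r == pytest.approx(6.94e10, rel=1e-2)

    def test_outflow_with_sheath(self, scope, anatomy):
        r = outflow_resistance(scope, anatomy, sheath_from_label("10/12"), MU)
        assert r == pytest.approx(9.11e9, rel=1e-2)

    def test_outflow_monotone_in_sheath_diameter(self, scope, anatomy):
        sizes = [9.0, 10.0, 12.0, 14.0, 16.0]
        values = [
            outflow_resistance(
                scope, anatomy, AccessSheath(french_to_meters(s), 0.35), MU
            )
            for s in sizes
        ]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_sheath_narrower_than_scope_rejected(self, scope, anatomy):
        with pytest.raises(ValueError):
            outflow_resistance(scope, anatomy, AccessSheath(french_to_meters(7.0), 0.35), MU)

    def test_withdrawal_value_and_limit(self, anatomy):
        r = withdrawal_resistance(anatomy, sheath_from_label("10/12"), MU)
        assert r > 0
        assert r == pytest.approx(5.89e9, rel=1e-2)
        huge = AccessSheath(inner_diameter=0.05, length=0.35)
        upj_only = circular_resistance(anatomy.upj_length, anatomy.upj_diameter, MU)
        assert withdrawal_resistance(anatomy, huge, MU) == pytest.approx(upj_only, rel=1e-3)

    def test_series_composition_matches_flow_computation(self):
        # at fixed pressure drop, flow through two tubes in series must match
        # the flow implied by the summed resistance
        r1 = circular_resistance(0.1, 1.5e-3, MU)
        r2 = circular_resistance(0.25, 2.5e-3, MU)
        dp = 1000.0
        q = dp / (r1 + r2)
        # consistency: pressure drops across the segments add up to dp
        assert q * r1 + q * r2 == pytest.approx(dp, rel=1e-12)
        # and the series resistance reproduces the same flow as solving the
        # two-segment network with an intermediate node pressure
        p_mid = dp - q * r1
        assert p_mid / r2 == pytest.approx(q, rel=1e-12)

    def test_unit_boundary_round_trip(self, anatomy):
        """Identical resistances whether inputs arrive in SI or clinical units."""
        scope_si = Ureteroscope(2.5e-3, 1.2e-3, 0.67)
        scope_clinical = Ureteroscope(
            parse_quantity("7.5 Fr", expect="length"),
            parse_quantity("3.6 Fr", expect="length"),
            parse_quantity("67 cm", expect="length"),
        )
        mu = parse_quantity("1 cP", expect="viscosity")
        rs_si = resistance_set(scope_si, anatomy, None, FluidProperties(1e-3))
        rs_cl = resistance_set(scope_clinical, anatomy, None, FluidProperties(mu))
        assert rs_si == rs_cl


class TestWhitakerInversion:
    def test_paper_operating_point_ml_per_min(self):
        m = WhitakerMeasurement(cmH2O_to_Pa(15), ml_per_min_to_m3_per_s(15))
        d = whitaker_upj_diameter(m, 0.005, cP_to_PaS(1))
        assert meters_to_french(d) == pytest.approx(1.3, abs=0.05)

    def test_ml_per_s_reading_gives_wider_upj(self):
        # the same operating point read in mL/s lands near 3.6 Fr — the two
        # flow-rate unit readings are mutually exclusive and only mL/min
        # is consistent with a 1.3 Fr junction
        m = WhitakerMeasurement(cmH2O_to_Pa(15), ml_per_s_to_m3_per_s(15))
        d = whitaker_upj_diameter(m, 0.005, cP_to_PaS(1))
        assert meters_to_french(d) == pytest.approx(3.6, abs=0.05)

    def test_quarter_power_flow_scaling(self):
        m1 = WhitakerMeasurement(1471.5, 2.5e-7)
        m16 = WhitakerMeasurement(1471.5, 16 * 2.5e-7)
        d1 = whitaker_upj_diameter(m1, 0.005, MU)
        assert whitaker_upj_diameter(m16, 0.005, MU) == pytest.approx(2 * d1, rel=1e-12)

    @given(
        d=st.floats(1e-4, 5e-3),
        length=st.floats(1e-3, 0.5),
        q=st.floats(1e-8, 1e-4),
    )
    @settings(max_examples=50, deadline=None)
    def test_exact_inverse_of_poiseuille(self, d, length, q):
        dp = circular_resistance(length, d, MU) * q
        m = WhitakerMeasurement(pressure_drop=dp, flow_rate=q)
        assert whitaker_upj_diameter(m, length, MU) == pytest.approx(d, rel=1e-12)


class TestTypeInvariants:
    def test_channel_wider_than_shaft_rejected(self):
        with pytest.raises(ValueError):
            Ureteroscope(shaft_diameter=2e-3, channel_diameter=3e-3, working_length=0.5)

    def test_stretch_below_one_rejected(self):
        with pytest.raises(ValueError):
            Anatomy(4e-4, 0.005, 3e-3, 0.25, 1e7, upj_stretch=0.5)

    def test_sheath_label_parsing(self):
        assert sheath_from_label("10/12").inner_diameter == french_to_meters(10)
        assert sheath_from_label("12/14 Fr").inner_diameter == french_to_meters(12)
        with pytest.raises(ValueError):
            sheath_from_label("big")
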