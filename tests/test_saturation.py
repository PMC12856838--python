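"""Measurement-variable conversions: Dalton's-law chain and GC quantitation."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cannavap.saturation import (
    HELIUM,
    CalibrationLine,
    CarrierGasSpec,
    ChromatogramPeakSet,
    CompoundSpec,
    MeasurementRecord,
    carrier_mass_from_standard_volume,
    condensed_purity,
    mass_from_internal_standard,
    purity_from_areas,
    saturator_pressure,
    vapor_mole_fraction,
    vapor_pressure,
)

THC = CompoundSpec(name="THC", molar_mass=314.47, cp_gas=407.3, purity_mole_fraction=0.96)


class TestCarrierMass:
    @pytest.mark.parametrize(
        "volume, expected, rtol",
        [
            (0.0, 0.0, 0.0),
            (22_414.0, 4.0026, 1e-4),  # one mole of helium at STP
            (3000.0, 0.5358, 1e-3),
        ],
    )
    def test_ideal_gas_conversion(self, volume, expected, rtol):
        mass = carrier_mass_from_standard_volume(volume)
        assert mass == pytest.approx(expected, rel=rtol, abs=1e-12)

    def test_rejects_bad_standard_conditions(self):
        with pytest.raises(ValueError):
            carrier_mass_from_standard_volume(100.0, std_temperature=0.0)
        with pytest.raises(ValueError):
            carrier_mass_from_standard_volume(100.0, std_pressure=-1.0)
        with pytest.raises(ValueError):
            carrier_mass_from_standard_volume(-1.0)


class TestVaporMoleFraction:
    def test_zero_analyte(self):
        assert vapor_mole_fraction(0.5, 0.0, compound=THC) == 0.0

    def test_equal_mole_amounts_give_half(self):
        # one mole of each species
        y2 = vapor_mole_fraction(HELIUM.molar_mass, THC.molar_mass, compound=THC)
        assert y2 == pytest.approx(0.5)

    def test_hand_evaluated_trace_level(self):
        y2 = vapor_mole_fraction(0.5358, 10e-6, compound=THC)
        assert y2 == pytest.approx(2.376e-7, rel=1e-3)

    def test_requires_positive_carrier_mass(self):
        with pytest.raises(ValueError):
            vapor_mole_fraction(0.0, 1e-6, compound=THC)

    @given(
        m2=st.floats(1e-9, 1e-3),
        m2_larger=st.floats(1.0001, 10.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_strictly_increasing_in_trapped_mass(self, m2, m2_larger):
        lo = vapor_mole_fraction(0.5, m2, compound=THC)
        hi = vapor_mole_fraction(0.5, m2 * m2_larger, compound=THC)
        assert hi > lo
        assert 0 <= lo < 1 and 0 <= hi < 1


class TestPurity:
    def test_pure_compound(self):
        assert condensed_purity(0.0) == 1.0

    @pytest.mark.parametrize("x_imp, expected", [(0.040, 0.960), (0.009, 0.991)])
    def test_impurity_subtraction(self, x_imp, expected):
        assert condensed_purity(x_imp) == pytest.approx(expected)

    def test_impurities_plus_solubility_must_leave_analyte(self):
        gas = CarrierGasSpec(solubility=0.5)
        with pytest.raises(ValueError):
            condensed_purity(0.5, gas)

    @pytest.mark.parametrize(
        "analyte, impurities, expected",
        [(960.0, (30.0, 10.0), 0.960), (991.0, (9.0,), 0.991), (5.0, (), 1.0)],
    )
    def test_area_percent(self, analyte, impurities, expected):
        peaks = ChromatogramPeakSet(analyte_area=analyte, impurity_areas=impurities)
        assert purity_from_areas(peaks) == pytest.approx(expected)

    def test_all_zero_areas_rejected(self):
        with pytest.raises(ValueError):
            purity_from_areas(ChromatogramPeakSet(analyte_area=0.0))


class TestInternalStandard:
    @pytest.mark.parametrize(
        "slope, intercept, area, is_area, is_mass, expected",
        [
            (1.0, 0.0, 0.0, 100.0, 2.0e-4, 0.0),
            (1.0, 0.0, 5.0, 100.0, 2.0e-4, 1.0e-5),
            (0.9, 0.002, 10.0, 100.0, 1.6e-4, 1.472e-5),
        ],
    )
    def test_linear_quantitation(self, slope, intercept, area, is_area, is_mass, expected):
        peaks = ChromatogramPeakSet(
            analyte_area=area,
            internal_standard_area=is_area,
            internal_standard_mass=is_mass,
        )
        cal = CalibrationLine(slope=slope, intercept=intercept)
        assert mass_from_internal_standard(peaks, cal) == pytest.approx(expected, rel=1e-9)

    def test_negative_mass_clipped_to_zero(self, caplog):
        peaks = ChromatogramPeakSet(
            analyte_area=0.0, internal_standard_area=100.0, internal_standard_mass=1e-4
        )
        cal = CalibrationLine(slope=1.0, intercept=-0.5)
        with caplog.at_level("WARNING"):
            assert mass_from_internal_standard(peaks, cal) == 0.0
        assert "clipping" in caplog.text

    def test_zero_internal_standard_area_rejected(self):
        peaks = ChromatogramPeakSet(analyte_area=5.0, internal_standard_mass=1e-4)
        with pytest.raises(ValueError):
            mass_from_internal_standard(peaks, CalibrationLine(slope=1.0))


@pytest.mark.parametrize(
    "p_ambient, p_over, expected",
    [(83_000.0, 0.0, 83_000.0), (83_000.0, 500.0, 83_500.0), (101_325.0, 1200.0, 102_525.0)],
)
def test_saturator_pressure_additivity(p_ambient, p_over, expected):
    assert saturator_pressure(p_ambient, p_over) == expected


class TestVaporPressure:
    def _record(self, m2, m1=0.5358, p_ambient=83_000.0, p_over=500.0):
        return MeasurementRecord(
            compound="THC",
            temperature=394.0,
            carrier_mass=m1,
            trapped_mass=m2,
            p_ambient=p_ambient,
            p_overpressure=p_over,
        )

    def test_zero_trapped_mass_gives_zero_pressure(self):
        assert vapor_pressure(self._record(0.0), THC).p_sat == 0.0

    def test_hand_chain(self):
        # 10 ug THC in 0.5358 g He at 83.5 kPa vial pressure, x2 = 0.96
        point = vapor_pressure(self._record(10e-6), THC)
        assert point.p_sat == pytest.approx(0.02066, rel=1e-3)

    def test_pressure_inverse_in_purity(self):
        # Dalton's law correction: p_sat scales as 1/x2 at fixed y2
        pure = CompoundSpec(name="X", molar_mass=314.47, purity_mole_fraction=1.0)
        half = CompoundSpec(name="X", molar_mass=314.47, purity_mole_fraction=0.5)
        rec = self._record(10e-6)
        assert vapor_pressure(rec, half).p_sat == pytest.approx(
            2.0 * vapor_pressure(rec, pure).p_sat, rel=1e-12
        )

    def test_linear_in_trapped_mass_at_trace_level(self):
        p1 = vapor_pressure(self._record(1e-6), THC).p_sat
        p2 = vapor_pressure(self._record(2e-6), THC).p_sat
        assert p2 / p1 == pytest.approx(2.0, rel=1e-6)

    def test_uncertainty_left_unset(self):
        assert vapor_pressure(self._record(1e-6), THC).u_c is None
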