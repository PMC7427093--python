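"""Hydrodynamic conversions: viscosity, radii, masses, oligomer calls."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ddstate.hydro import (
    Conditions,
    HydroMeasurement,
    calibrate_rh_mw,
    classify_oligomer,
    d_to_rh,
    mw_to_rh,
    rh_to_d,
    rh_to_mw,
    rh_to_tau_c,
    sequence_mw,
    tau_c_to_rh,
    water_viscosity,
)


class TestWaterViscosity:
    @pytest.mark.parametrize(
        "T, expected",
        [(303.15, 0.797e-3), (298.15, 0.890e-3)],
    )
    def test_reference_values(self, T, expected):
        assert water_viscosity(T) == pytest.approx(expected, rel=2e-3)

    def test_decreases_with_temperature(self):
        assert water_viscosity(293.15) > water_viscosity(303.15) > water_viscosity(313.15)

    @pytest.mark.parametrize("T", [273.15, 400.0, -5.0])
    def test_out_of_range_names_interval(self, T):
        with pytest.raises(ValueError, match="273.15"):
            water_viscosity(T)


class TestRadiusConversions:
    def test_rotational_radius_of_rat_dd(self, cond):
        # tau_c measured at 1 mM protein, 30 C, aqueous phosphate buffer
        assert tau_c_to_rh(6.03, cond) == pytest.approx(1.96, abs=0.005)

    def test_rotational_radius_dimer_regime(self, cond):
        assert tau_c_to_rh(10.3, cond) == pytest.approx(2.34, abs=0.01)

    def test_translational_radius_of_rat_dd(self, cond):
        assert d_to_rh(154e-12, cond) == pytest.approx(1.80, abs=0.01)

    def test_translational_radius_larger_particle(self, cond):
        assert d_to_rh(123e-12, cond) == pytest.approx(2.26, abs=0.01)

    @given(r=st.floats(0.5, 10.0))
    def test_round_trip_identities(self, r):
        cond = Conditions()
        assert tau_c_to_rh(rh_to_tau_c(r, cond), cond) == pytest.approx(r, rel=1e-9)
        assert d_to_rh(rh_to_d(r, cond), cond) == pytest.approx(r, rel=1e-9)

    def test_dimensional_sanity_in_viscosity(self):
        """Halving eta doubles D and halves tau_c at fixed radius."""
        thick = Conditions(viscosity=1.0e-3)
        thin = Conditions(viscosity=0.5e-3)
        assert rh_to_d(2.0, thin) == pytest.approx(2.0 * rh_to_d(2.0, thick), rel=1e-12)
        assert rh_to_tau_c(2.0, thin) == pytest.approx(
            0.5 * rh_to_tau_c(2.0, thick), rel=1e-12
        )

    @pytest.mark.parametrize("fn", [tau_c_to_rh, d_to_rh])
    def test_nonpositive_observable_rejected(self, fn, cond):
        with pytest.raises(ValueError):
            fn(-1.0, cond)


class TestMassRelation:
    def test_reproduces_monomer_calibration_points(self):
        assert rh_to_mw(1.96) == pytest.approx(13.0, abs=0.05)
        assert rh_to_mw(1.80) == pytest.approx(10.2, abs=0.05)

    @given(r1=st.floats(0.5, 9.0), dr=st.floats(0.01, 1.0))
    def test_strictly_monotone(self, r1, dr):
        assert rh_to_mw(r1 + dr) > rh_to_mw(r1)

    @given(mw=st.floats(1.0, 500.0))
    def test_inverse(self, mw):
        assert rh_to_mw(mw_to_rh(mw)) == pytest.approx(mw, rel=1e-12)

    def test_calibration_recovers_constants(self):
        A, b = calibrate_rh_mw([(r, 1.91 * r**2.85) for r in (1.0, 1.5, 2.0, 3.0)])
        assert A == pytest.approx(1.91, rel=1e-9)
        assert b == pytest.approx(2.85, rel=1e-9)

    def test_two_point_calibration_is_exact(self):
        A, b = calibrate_rh_mw([(1.96, 13.0), (1.80, 10.2)])
        assert A * 1.96**b == pytest.approx(13.0, rel=1e-12)
        assert A * 1.80**b == pytest.approx(10.2, rel=1e-12)


class TestSequenceMass:
    def test_dipeptide(self):
        # G 57.05 + S 87.08 + one water 18.02, in kDa
        assert sequence_mw("GS") == pytest.approx(0.16215, abs=1e-4)

    def test_empty_chain_is_water(self):
        assert sequence_mw("") == pytest.approx(0.0180, abs=1e-4)

    def test_serine_heavier_than_glycine(self):
        assert sequence_mw("GG") < sequence_mw("GS")

    def test_unknown_letter_reports_position(self):
        with pytest.raises(ValueError, match=r"'B'.*position 3"):
            sequence_mw("GABG")


class TestOligomerCall:
    # Table rows: construct, tau_c (ns), D (m2/s), monomer mass (kDa), label
    TABLE_ROWS = [
        ("rat DD", 6.0, 154e-12, 10.6, "monomer"),
        ("rat DD C416S", 6.1, 151e-12, 10.6, "monomer"),
        ("rat DD C416S cross-linked", 10.3, 123e-12, 10.6, "dimer"),
        ("human DD", 6.1, 151e-12, 10.5, "monomer"),
        ("human DD 2nd state", 6.0, None, 10.5, "monomer"),
    ]

    @pytest.mark.parametrize("name, tau, D, mono, label", TABLE_ROWS)
    def test_construct_table_regression(self, cond, name, tau, D, mono, label):
        m = HydroMeasurement(name, tau_c=tau, D=D)
        call = classify_oligomer(m, cond, mono)
        assert call.label == label

    def test_identity_case(self, cond):
        """Predicted MW exactly the monomer mass -> n = 1."""
        mw = rh_to_mw(tau_c_to_rh(6.0, cond))
        call = classify_oligomer(HydroMeasurement("x", tau_c=6.0), cond, mw)
        assert call.n_oligomer == 1 and call.label == "monomer"

    def test_ideal_rigid_dimer_scaling(self, cond):
        """Doubling the hydrodynamic volume turns a monomer call into a dimer.

        For an ideal sphere, a rigid dimer has tau_c x2 and D x2^(-1/3).
        """
        mono = HydroMeasurement("m", tau_c=6.0, D=154e-12)
        mono_mw = (
            rh_to_mw(tau_c_to_rh(6.0, cond)) + rh_to_mw(d_to_rh(154e-12, cond))
        ) / 2.0
        dimer = HydroMeasurement("d", tau_c=12.0, D=154e-12 * 2 ** (-1 / 3))
        assert classify_oligomer(mono, cond, mono_mw).n_oligomer == 1
        assert classify_oligomer(dimer, cond, mono_mw).n_oligomer == 2

    def test_requires_an_observable(self):
        with pytest.raises(ValueError, match="at least one"):
            HydroMeasurement("empty")

    def test_rounding_is_half_away_from_zero(self, cond):
        """A mean prediction of exactly 1.5 monomer masses rounds up to 2."""
        mw = rh_to_mw(tau_c_to_rh(6.0, cond))
        call = classify_oligomer(
            HydroMeasurement("x", tau_c=6.0), cond, mw / 1.5
        )
        assert call.n_oligomer == 2
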