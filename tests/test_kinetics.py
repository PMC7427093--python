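"""Deamidation and dimerization kinetics, gel fractions, LPR estimator."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from ddstate.kinetics import (
    ECOLI_GEOMETRY,
    CellGeometry,
    TimeCourse,
    fit_first_order,
    fit_second_order,
    gel_monomer_fraction,
    lpr_ecoli,
    round_to_one_sig_fig,
    second_order_monomer,
)
from ddstate.synthetic_data import NoiseSpec, gen_dimerization_course, gen_gel_table


class TestFirstOrder:
    def test_phosphate_rate_and_half_life(self):
        """Exact recovery of a noiseless decay at the phosphate-buffer rate."""
        t = np.array([0.0, 2, 4, 6, 9, 12, 16, 19])
        tc = TimeCourse(t, np.exp(-0.1406 * t), unit="days")
        fit = fit_first_order(tc)
        assert fit.k == pytest.approx(0.1406, rel=1e-9)
        assert fit.t_half == pytest.approx(4.93, abs=0.01)

    def test_hepes_half_life(self):
        t = np.array([0.0, 2, 4, 6, 9, 12, 16, 19])
        fit = fit_first_order(TimeCourse(t, np.exp(-0.0491 * t), unit="days"))
        assert fit.t_half == pytest.approx(14.1, abs=0.1)

    def test_half_life_identity(self):
        t = np.linspace(0, 10, 8)
        fit = fit_first_order(TimeCourse(t, np.exp(-0.3 * t)))
        assert fit.t_half * fit.k == pytest.approx(math.log(2), rel=1e-12)

    def test_constant_course_warns_degenerate(self):
        tc = TimeCourse([0.0, 1, 2, 3], [1.0, 1.0, 1.0, 1.0])
        with pytest.warns(UserWarning, match="degenerate"):
            fit_first_order(tc)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_first_order(TimeCourse([0.0, 1, 2, 3], [1.0, 0.5, 0.0, 0.1]))

    def test_weighted_fit_uses_errors(self):
        t = np.array([0.0, 2, 4, 6, 9, 12])
        y = np.exp(-0.1 * t)
        fit = fit_first_order(TimeCourse(t, y, errors=0.01 * y))
        assert fit.k == pytest.approx(0.1, rel=1e-9)
        assert fit.k_err > 0


class TestSecondOrder:
    def test_initial_condition(self):
        assert second_order_monomer(0.0, 1e-3, 1.08e-3) == pytest.approx(1e-3)

    def test_half_consumption_point(self):
        M0, k = 1e-3, 1.08e-3
        assert second_order_monomer(1.0 / (M0 * k), M0, k) == pytest.approx(M0 / 2)

    def test_matches_ode_integration(self):
        """Closed form vs numeric integration of d[M]/dt = -k [M]^2."""
        M0, k, t_end = 1e-3, 1.08e-3, 70 * 3600.0
        sol = solve_ivp(
            lambda t, m: -k * m**2, (0.0, t_end), [M0], rtol=1e-10, atol=1e-16
        )
        assert second_order_monomer(t_end, M0, k) == pytest.approx(
            sol.y[0, -1], rel=1e-6
        )

    @pytest.mark.parametrize("k_true", [1.08e-3, 9.65e-3])
    def test_noiseless_fit_exact(self, k_true):
        course = gen_dimerization_course(k_true, 1e-3, noise=NoiseSpec("none"))
        fit = fit_second_order(course, M0=1e-3)
        assert fit.k == pytest.approx(k_true, rel=1e-6)

    def test_zero_rate_indistinguishable_from_zero(self):
        course = gen_dimerization_course(0.0, 1e-3, noise=NoiseSpec("none"))
        fit = fit_second_order(course, M0=1e-3)
        # several orders of magnitude below any physical rate in this system
        assert fit.k == pytest.approx(0.0, abs=1e-8)

    def test_lipid_relative_units_are_lpr_invariant(self):
        """The same mole/mole rate constant is recovered at LPR 200 and 1000."""
        k_true = 1.08e-3
        for lpr in (200.0, 1000.0):
            course = gen_dimerization_course(k_true, 1.0 / lpr, noise=NoiseSpec("none"))
            fit = fit_second_order(course, M0=1.0 / lpr)
            assert fit.k == pytest.approx(k_true, rel=1e-6)

    def test_rate_ordering_across_seeds(self):
        """The activating-mutant rate always fits above the wild-type rate."""
        for seed in range(100):
            slow = fit_second_order(
                gen_dimerization_course(1.08e-3, 1e-3,
                                        noise=NoiseSpec("gaussian_relative", 0.03),
                                        seed=seed),
                M0=1e-3,
            )
            fast = fit_second_order(
                gen_dimerization_course(9.65e-3, 1e-3,
                                        noise=NoiseSpec("gaussian_relative", 0.03),
                                        seed=seed + 1000),
                M0=1e-3,
            )
            assert fast.k > slow.k

    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError, match="fractions"):
            fit_second_order(
                TimeCourse([0.0, 1, 2, 3], [1.2, 0.9, 0.8, 0.7], unit="hours"), M0=1e-3
            )


class TestGelFraction:
    @pytest.mark.parametrize(
        "lane, expected",
        [
            ({"monomer": 1.0, "dimer": 0.0, "higher": 0.0}, 1.0),
            ({"M": 1.0, "D": 1.0}, 0.5),
            ({"M": 2.0, "D": 1.0, "T": 1.0}, 0.5),
        ],
    )
    def test_mass_fraction(self, lane, expected):
        assert gel_monomer_fraction(lane) == pytest.approx(expected)

    def test_all_zero_lane_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            gel_monomer_fraction({"monomer": 0.0, "dimer": 0.0})

    def test_mass_conservation_in_simulated_lanes(self):
        course = gen_dimerization_course(
            9.65e-3, 1e-3, noise=NoiseSpec("gaussian_relative", 0.03), seed=4
        )
        for lane in gen_gel_table(course, higher_order_fraction=0.3):
            total = lane["monomer"] + lane["dimer"] + lane["tetramer"]
            assert total == pytest.approx(100.0, abs=1e-10)

    def test_monomer_plus_oligomer_mole_conservation(self):
        """monomer + 2 x dimer (mole/mole) is constant along any course."""
        M0, k = 1e-3, 9.65e-3
        t = np.linspace(0, 70 * 3600, 50)
        M = second_order_monomer(t, M0, k)
        dimer = (M0 - M) / 2.0
        assert np.allclose(M + 2 * dimer, M0, atol=1e-10)


class TestLpr:
    def test_membrane_lpr_estimate(self):
        res = lpr_ecoli()
        assert res.lpr == pytest.approx(191.0, abs=0.5)
        assert res.lpr_1sf == 200.0

    def test_lipids_per_cell(self):
        assert lpr_ecoli().n_lip == pytest.approx(1.333e7, rel=1e-3)

    def test_doubling_expression_halves_lpr(self):
        doubled = CellGeometry(
            S_cell=ECOLI_GEOMETRY.S_cell,
            S_lip=ECOLI_GEOMETRY.S_lip,
            C_prot=2 * ECOLI_GEOMETRY.C_prot,
            MW=ECOLI_GEOMETRY.MW,
            C_cell=ECOLI_GEOMETRY.C_cell,
            N_A_used=ECOLI_GEOMETRY.N_A_used,
        )
        assert lpr_ecoli(doubled).lpr == pytest.approx(lpr_ecoli().lpr / 2, rel=1e-12)

    @pytest.mark.parametrize("x, expected", [(191.0, 200.0), (0.0215, 0.02), (4.9, 5.0)])
    def test_one_sig_fig(self, x, expected):
        assert round_to_one_sig_fig(x) == pytest.approx(expected)

    def test_geometry_must_be_positive(self):
        with pytest.raises(ValueError, match="positive"):
            CellGeometry(S_cell=-4.0, S_lip=0.6e-6, C_prot=6e-3, MW=21486, C_cell=24e8)
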