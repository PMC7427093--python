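"""Relaxation-interference analysis: decay fits, forward model, inversion."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ddstate.constants import (
    DEFAULT_SPIN_PARAMS,
    GAMMA_H1,
    GAMMA_N15,
    H_PLANCK,
    MU_0,
)
from ddstate.hydro import Conditions
from ddstate.relaxation import (
    DecayCurve,
    TractResult,
    ensemble_difference,
    ensemble_tau_c,
    eta_xy_forward,
    fit_monoexponential,
    tract_from_decays,
    tract_tau_c,
)
from ddstate.synthetic_data import NoiseSpec, gen_tract_decays


def make_decay(R, delays=None, noise=0.0, seed=0, component="alpha"):
    rng = np.random.default_rng(seed)
    t = np.asarray(delays if delays is not None else np.linspace(0.004, 0.12, 12))
    y = np.exp(-R * t)
    if noise:
        y = y * (1 + rng.normal(0, noise, t.size))
    return DecayCurve(1, "X", component, t, y)


class TestMonoexponentialFit:
    def test_noiseless_exact(self):
        R, R_err, I0 = fit_monoexponential(make_decay(20.0))
        assert R == pytest.approx(20.0, rel=1e-9)
        assert I0 == pytest.approx(1.0, rel=1e-9)

    def test_noisy_within_three_stderr(self):
        R, R_err, _ = fit_monoexponential(make_decay(20.0, noise=0.02, seed=11))
        assert abs(R - 20.0) < 3 * R_err

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            DecayCurve(1, "X", "alpha", [0.0, 0.05], [1.0, 0.4])


class TestForwardModel:
    def test_monotone_in_tau_c(self, cond600):
        vals = [eta_xy_forward(t, cond600) for t in (4.0, 6.0, 8.0)]
        assert vals[0] < vals[1] < vals[2]

    def test_vanishes_at_short_tau_c(self, cond600):
        assert eta_xy_forward(1e-4, cond600) < 1e-3

    def test_monotone_scan_across_fields(self):
        """eta_xy(tau_c) strictly increases on [0.1, 100] ns at any field."""
        taus = np.linspace(0.1, 100.0, 500)
        for field in (400.0, 600.0, 800.0, 1000.0):
            cond = Conditions(field_MHz=field)
            vals = np.array([eta_xy_forward(t, cond) for t in taus])
            assert np.all(np.diff(vals) > 0)

    def test_matches_independent_evaluation(self, cond600):
        """Cross-check against the closed form written out from scratch."""
        tau = 6.0e-9
        gH, gN = GAMMA_H1, abs(GAMMA_N15)
        B0 = 2 * math.pi * 600e6 / gH
        p = MU_0 * H_PLANCK * gH * gN / (16 * math.pi**2 * math.sqrt(2) * (1.02e-10) ** 3)
        dN = gN * B0 * 160e-6 / (3 * math.sqrt(2))
        P2 = (3 * math.cos(math.radians(17.0)) ** 2 - 1) / 2

        def J(w):
            return 0.4 * tau / (1 + (w * tau) ** 2)

        expected = p * dN * P2 * (4 * J(0) + 3 * J(gN * B0))
        assert eta_xy_forward(6.0, cond600) == pytest.approx(expected, rel=1e-12)

    def test_requires_field(self, cond):
        with pytest.raises(ValueError, match="field_MHz"):
            eta_xy_forward(6.0, cond)


class TestInversion:
    @pytest.mark.parametrize("tau_true", [6.03, 10.3])
    def test_round_trip(self, cond600, tau_true):
        eta = eta_xy_forward(tau_true, cond600)
        tau, eta_back = tract_tau_c(10.0 - eta, 10.0 + eta, cond600)
        assert tau == pytest.approx(tau_true, rel=1e-4)
        assert eta_back == pytest.approx(eta, rel=1e-12)

    def test_grid_search_oracle(self, cond600):
        """Brent inversion agrees with a dense grid scan for random targets."""
        grid = np.linspace(0.5, 50.0, 10_000)
        forward = np.array([eta_xy_forward(t, cond600) for t in grid])
        rng = np.random.default_rng(42)
        for tau_true in rng.uniform(1.0, 40.0, 20):
            eta = eta_xy_forward(tau_true, cond600)
            tau_root, _ = tract_tau_c(10.0 - eta, 10.0 + eta, cond600)
            tau_grid = grid[np.argmin(np.abs(forward - eta))]
            assert abs(tau_root - tau_grid) <= grid[1] - grid[0]

    def test_rejects_inverted_rates(self, cond600):
        with pytest.raises(ValueError, match="R_beta > R_alpha"):
            tract_tau_c(10.0, 9.0, cond600)

    def test_out_of_bracket_suggests_range(self, cond600):
        big = eta_xy_forward(100.0, cond600) * 10
        with pytest.raises(ValueError, match="bracket"):
            tract_tau_c(10.0 - big, 10.0 + big, cond600)


class TestEnsemble:
    def _results(self, values):
        return [TractResult(i, 10, 12, 1.0, v, 0.1) for i, v in enumerate(values)]

    def test_identical_values(self):
        mean, sem = ensemble_tau_c(self._results([6.0] * 5))
        assert mean == 6.0 and sem == 0.0

    def test_hand_arithmetic(self):
        mean, _ = ensemble_tau_c(self._results([5.0, 6.0, 7.0]))
        assert mean == pytest.approx(6.0)

    def test_residue_window_selection(self):
        res = [TractResult(rid, 10, 12, 1.0, float(rid), 0.1) for rid in (1, 2, 50, 60)]
        mean, _ = ensemble_tau_c(res, residue_range=(40, 70))
        assert mean == pytest.approx(55.0)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="range"):
            ensemble_tau_c(self._results([6.0] * 5), residue_range=(100, 200))

    def test_monomer_dimer_decrement(self, cond600):
        """Synthetic monomer (5.78 ns) and dimer (6.83 ns) ensembles differ
        by the cross-linking decrement of ~1.05 ns."""
        mono = tract_from_decays(
            gen_tract_decays(5.78, range(339, 399), cond600,
                             NoiseSpec("gaussian_relative", 0.03), seed=1),
            cond600,
        )
        dim = tract_from_decays(
            gen_tract_decays(6.83, range(339, 399), cond600,
                             NoiseSpec("gaussian_relative", 0.03), seed=2),
            cond600,
        )
        diff, err = ensemble_difference(mono, dim)
        assert diff == pytest.approx(1.05, abs=0.25)


class TestRecovery:
    def test_median_recovery_within_two_percent(self, cond600):
        """100 synthetic residues at 6.0 ns with 3% decay noise."""
        curves = gen_tract_decays(
            6.0, range(1, 101), cond600, NoiseSpec("gaussian_relative", 0.03), seed=9
        )
        results = tract_from_decays(curves, cond600)
        assert len(results) == 100
        median = float(np.median([r.tau_c for r in results]))
        assert abs(median - 6.0) / 6.0 < 0.02

    @given(tau=st.floats(2.0, 20.0))
    def test_forward_inverse_consistency_any_tau(self, tau):
        cond = Conditions(field_MHz=800.0)
        eta = eta_xy_forward(tau, cond)
        tau_back, _ = tract_tau_c(12.0 - eta, 12.0 + eta, cond)
        assert tau_back == pytest.approx(tau, rel=1e-3)
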