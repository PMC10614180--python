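"""Iterative Boltzmann inversion: correction evaluation, regularized
updates, polynomial refits, fixed-point behavior."""

import numpy as np
import pytest

from fqcmd import units
from fqcmd.ibi import (CorrectedPotential, CorrectionPotential, PairTable,
                       evaluate_correction, inter_update_regularized,
                       intra_update_refit, masked_poly_refit,
                       regularization_scale, _poly_eval)
from fqcmd.distributions import IntraDistributions
from fqcmd.water_model import (Configuration, ConfigurationError,
                               SimulationCell, SystemTopology, WaterPotential)

from conftest import numerical_forces


def make_table(pair="OO", lo=4.0, hi=9.0, amp=1e-3, r_cut=9.0):
    grid = np.arange(lo, hi + 0.025, 0.05)
    vals = amp * np.exp(-((grid - 5.5) ** 2) / 0.5)
    return PairTable(pair, grid, vals, r_cut, presmoothed=True)


class TestCorrectionEvaluation:
    def test_zero_correction_gives_zero_energy_and_forces(self, params,
                                                          small_liquid):
        cfg, topo, cell = small_liquid
        corr = CorrectionPotential.zero(params)
        fe = evaluate_correction(corr, cfg, topo, cell)
        assert fe.energy == 0.0
        assert np.all(fe.forces == 0.0)
        assert corr.is_zero

    def test_table_node_energy_is_exact(self):
        table = make_table()
        # nodes away from the switch region interpolate exactly
        idx = 20
        assert table.energy(np.array([table.r_grid[idx]]))[0] == \
            pytest.approx(table.values[idx], rel=1e-12)

    def test_table_zero_at_and_beyond_cutoff(self):
        table = make_table()
        r = np.array([table.r_cut, table.r_cut + 1.0, 50.0])
        assert np.all(table.energy(r) == 0.0)
        assert np.all(table.dvdr(r) == 0.0)

    def test_below_inner_edge_extrapolates_linearly_and_counts(self):
        table = make_table()
        r = np.array([3.5, 3.9])
        e = table.energy(r)
        v0 = table.energy(np.array([table.r_inner]))[0]
        d0 = table.dvdr(np.array([table.r_inner]))[0]
        np.testing.assert_allclose(
            e, v0 + d0 * (r - table.r_inner), rtol=1e-10)
        assert table.n_below_inner >= 2

    def test_correction_forces_match_finite_differences(self, params,
                                                        small_liquid):
        cfg, topo, cell = small_liquid
        corr = CorrectionPotential.zero(params)
        corr.c_r = np.array([1e-3, 5e-4, -2e-4, 1e-4])
        corr.c_theta = np.array([2e-4, 1e-4])
        corr.r_window = (-0.3, 0.4)
        corr.theta_window = (-0.5, 0.5)
        corr.tables = {"OO": make_table("OO"), "OH": make_table("OH", 3.0),
                       "HH": None}

        class Wrap:
            masses = topo.masses

            def force_energy(self, x):
                fe = evaluate_correction(corr, Configuration(x), topo, cell)
                return fe.energy, fe.forces

        pot = Wrap()
        e, f = pot.force_energy(cfg.positions)
        num = numerical_forces(pot, cfg.positions)
        assert np.abs(f - num).max() / np.abs(f).max() < 1e-6

    def test_force_continuity_under_grid_refinement(self):
        """Max force jump across adjacent grid intervals shrinks as the
        table grid is refined (smooth-force requirement)."""
        jumps = []
        for step in (0.2, 0.1, 0.05):
            grid = np.arange(4.0, 9.0 + step / 2, step)
            vals = 1e-3 * np.sin(grid)
            table = PairTable("OO", grid, vals, 9.0, presmoothed=True)
            r = grid[3:-3]
            left = table.dvdr(r - 1e-9)
            right = table.dvdr(r + 1e-9)
            jumps.append(np.abs(left - right).max())
        assert jumps[-1] < 1e-10          # spline derivative is continuous
        assert jumps[0] < 1e-10

    def test_save_load_round_trip(self, params, tmp_path):
        corr = CorrectionPotential.zero(params)
        corr.c_r = np.array([1e-3, 0.0, -2e-4, 0.0])
        corr.r_window = (-0.2, 0.3)
        corr.tables = {"OO": make_table("OO"), "OH": None, "HH": None}
        corr.iteration = 7
        corr.epsilon = 1.0
        corr.save(tmp_path)
        back = CorrectionPotential.load(tmp_path)
        np.testing.assert_allclose(back.c_r, corr.c_r)
        assert back.r_window == pytest.approx(corr.r_window)
        assert back.iteration == 7
        r = np.linspace(4.0, 9.5, 200)
        np.testing.assert_allclose(back.tables["OO"].energy(r),
                                   corr.tables["OO"].energy(r), atol=1e-10)
        assert back.tables["OH"] is None


class TestRegularizedUpdate:
    def test_fixed_point_zero_update_for_all_epsilon(self):
        g = np.abs(np.sin(np.linspace(0, 3, 50))) * 2
        for eps in (0.0, 1.0, 5.0, 100.0):
            if eps == 0.0:
                g_pos = g + 0.1       # avoid 0/0 at eps = 0
                upd = inter_update_regularized(g_pos, g_pos, eps, 300.0)
            else:
                upd = inter_update_regularized(g, g, eps, 300.0)
            assert np.all(upd == 0.0)

    def test_single_bin_ratio_two_gives_kt_ln2(self):
        g_t = np.array([1.0, 2.0, 1.0])
        g_x = np.array([1.0, 1.0, 1.0])
        upd = inter_update_regularized(g_t, g_x, 0.0, 300.0)
        kT = units.KB_HARTREE * 300.0
        assert upd[1] == pytest.approx(kT * np.log(2.0), rel=1e-12)

    def test_update_magnitude_monotonically_damped_in_epsilon(self):
        rng = np.random.default_rng(0)
        g_x = np.abs(rng.uniform(0.1, 3.0, 40))
        g_t = g_x * rng.uniform(0.5, 2.0, 40)
        prev = None
        for eps in (0.0, 1.0, 5.0, 50.0, 500.0):
            upd = np.abs(inter_update_regularized(g_t, g_x, eps, 300.0))
            if prev is not None:
                assert np.all(upd <= prev + 1e-15)
            prev = upd
        # At the largest epsilon the update obeys the first-order bound.
        kT = units.KB_HARTREE * 300.0
        G = regularization_scale(g_t, g_x)
        assert np.all(prev <= kT * np.abs(g_t - g_x) / (500.0 * G) * 1.01)

    def test_zero_over_zero_raises_only_without_regularization(self):
        g = np.array([0.0, 1.0, 2.0])
        with pytest.raises(ConfigurationError):
            inter_update_regularized(g, g, 0.0, 300.0)
        assert inter_update_regularized(g, g, 1.0, 300.0)[0] == 0.0

    def test_noise_suppression_first_order_bound(self):
        """Where both distributions are far below eps*G, the update is
        bounded by kT |g_t - g_x| / (eps G)."""
        eps = 5.0
        g_x = np.array([3.0, 0.01, 0.02, 0.005])
        g_t = np.array([3.0, 0.02, 0.01, 0.012])
        G = regularization_scale(g_t, g_x)
        upd = inter_update_regularized(g_t, g_x, eps, 300.0)
        kT = units.KB_HARTREE * 300.0
        small = (g_x < eps * G / 10) & (g_t < eps * G / 10)
        bound = kT * np.abs(g_t - g_x)[small] / (eps * G)
        assert np.all(np.abs(upd[small]) <= bound * 1.12)

    def test_negative_epsilon_rejected(self):
        with pytest.raises(ValueError):
            inter_update_regularized(np.ones(3), np.ones(3), -1.0, 300.0)


def _intra_from_density(r_edges, rho_r, th_edges, rho_th):
    return IntraDistributions(r_edges=r_edges, rho_r=rho_r,
                              theta_edges=th_edges, rho_theta=rho_th)


def _boltzmann_density(v_func, centers, edges, beta):
    rho = np.exp(-beta * v_func(centers))
    return rho / (rho.sum() * np.diff(edges))


class TestIntraRefit:
    """1-D Boltzmann-density oracles: with analytic (noise-free) densities,
    kT ln(rho_trial/rho_target) equals the perturbation exactly, so the
    polynomial refit must recover it."""

    BETA = units.beta_from_temperature(300.0)
    KT = 1.0 / BETA

    def _setup(self, params, perturb_r, perturb_th=None):
        r_edges = np.arange(1.2, 2.6, 0.02)
        th_edges = np.arange(1.0, 2.8, 0.01)
        r_c = 0.5 * (r_edges[:-1] + r_edges[1:])
        th_c = 0.5 * (th_edges[:-1] + th_edges[1:])
        k_r, k_th = 0.5, 0.15
        v_r = lambda r: 0.5 * k_r * (r - params.r_eq) ** 2
        v_th = lambda t: 0.5 * k_th * (t - params.theta_eq) ** 2
        perturb_th = perturb_th or (lambda t: 0.0 * t)
        trial = _intra_from_density(
            r_edges, _boltzmann_density(v_r, r_c, r_edges, self.BETA),
            th_edges, _boltzmann_density(v_th, th_c, th_edges, self.BETA))
        target = _intra_from_density(
            r_edges, _boltzmann_density(lambda r: v_r(r) + perturb_r(r),
                                        r_c, r_edges, self.BETA),
            th_edges, _boltzmann_density(lambda t: v_th(t) + perturb_th(t),
                                         th_c, th_edges, self.BETA))
        return trial, target, r_c

    def test_trial_equals_target_changes_nothing(self, params):
        trial, _, _ = self._setup(params, lambda r: 0.0 * r)
        corr = CorrectionPotential.zero(params)
        new = intra_update_refit(corr, trial, trial, 300.0)
        np.testing.assert_allclose(new.c_r, 0.0, atol=1e-14)
        np.testing.assert_allclose(new.c_theta, 0.0, atol=1e-14)

    def test_known_quartic_perturbation_recovered(self, params):
        """Target generated with a known quartic perturbation: the first
        refit recovers its shape over the sampled region to <= 10% RMS of
        its range there."""
        c = np.array([-8e-3, 2e-2, 5e-2, -0.2])

        def w(r):
            d = r - params.r_eq
            return c[0] * d + c[1] * d**2 + c[2] * d**3 + c[3] * d**4

        trial, target, r_c = self._setup(params, w)
        corr = CorrectionPotential.zero(params)
        new = intra_update_refit(corr, trial, target, 300.0)
        mask = target.rho_r > 0.01 * target.rho_r.max()
        d = r_c[mask] - params.r_eq
        # refit convention: update = kT ln(rho_trial/rho_target) = +w + const
        fitted = _poly_eval(new.c_r, d)[0]
        truth = w(r_c[mask])
        fitted -= fitted.mean()
        truth -= truth.mean()
        rng_w = truth.max() - truth.min()
        rms = np.sqrt(np.mean((fitted - truth) ** 2))
        assert rms <= 0.10 * rng_w

    def test_masked_bins_have_exactly_zero_weight(self):
        """Values outside the mask cannot influence the fit at all."""
        x = np.linspace(-1, 1, 101)
        w = np.exp(-x**2 / 0.08)
        mask = w > 0.01 * w.max()
        y = 0.3 * x + 0.1 * x**2
        y_messed = y.copy()
        y_messed[~mask] = 1e6          # garbage outside the mask
        a = masked_poly_refit(y, x, w, mask, 4)
        b = masked_poly_refit(y_messed, x, w, mask, 4)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_too_few_usable_bins_raises(self):
        x = np.linspace(-1, 1, 10)
        w = np.ones(10)
        mask = np.zeros(10, bool)
        mask[:3] = True
        with pytest.raises(ConfigurationError):
            masked_poly_refit(x, x, w, mask, 4)


class TestCorrectedPotential:
    def test_energy_is_sum_of_base_and_correction(self, params, small_liquid):
        cfg, topo, cell = small_liquid
        base = WaterPotential(topo, cell, params)
        corr = CorrectionPotential.zero(params)
        corr.c_r = np.array([1e-3, 0, 0, 0])
        corr.r_window = (-0.3, 0.3)
        pot = CorrectedPotential(base, corr)
        e, f = pot.force_energy(cfg.positions)
        e0, f0 = base.force_energy(cfg.positions)
        fe = evaluate_correction(corr, cfg, topo, cell)
        assert e == pytest.approx(e0 + fe.energy, rel=1e-12)
        np.testing.assert_allclose(f, f0 + fe.forces, atol=1e-12)
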