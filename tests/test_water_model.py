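"""Water model: energies, analytic forces, electrostatics, dipole."""

import numpy as np
import pytest

from fqcmd import units
from fqcmd import water_model as wm
from fqcmd.fixtures import StructureSpec, build_liquid_box

from conftest import numerical_forces, perturbed


def _molecule(params, origin=(0.0, 0.0, 0.0), r1=None, r2=None, theta=None):
    r1 = params.r_eq if r1 is None else r1
    r2 = params.r_eq if r2 is None else r2
    theta = params.theta_eq if theta is None else theta
    o = np.asarray(origin, float)
    h1 = o + r1 * np.array([np.sin(theta / 2), 0, np.cos(theta / 2)])
    h2 = o + r2 * np.array([-np.sin(theta / 2), 0, np.cos(theta / 2)])
    return np.stack([o, h1, h2])


class TestIntramolecular:
    def test_equilibrium_geometry_has_zero_energy_and_forces(self, params):
        topo = wm.SystemTopology.for_water(3, params)
        pos = np.concatenate([_molecule(params, (0, 0, 0)),
                              _molecule(params, (8, 0, 0)),
                              _molecule(params, (0, 8, 0))])
        fe = wm.intramolecular_energy_forces(wm.Configuration(pos), topo, params)
        assert abs(fe.energy) < 1e-14
        assert np.abs(fe.forces).max() < 1e-12

    @pytest.mark.parametrize("delta", [-0.2, -0.05, 0.1, 0.3])
    def test_stretched_bond_matches_scalar_polynomial(self, params, delta):
        """One bond stretched by delta: energy equals the quartic Morse
        expansion evaluated independently as a scalar polynomial."""
        topo = wm.SystemTopology.for_water(1, params)
        pos = _molecule(params, r1=params.r_eq + delta)
        fe = wm.intramolecular_energy_forces(wm.Configuration(pos), topo, params)
        a, D = params.a_r, params.D_r
        expected = D * (a**2 * delta**2 - a**3 * delta**3
                        + 7.0 / 12.0 * a**4 * delta**4)
        assert fe.energy == pytest.approx(expected, rel=1e-12)

    def test_forces_match_finite_differences(self, params):
        topo = wm.SystemTopology.for_water(2, params)
        pos = np.concatenate([_molecule(params), _molecule(params, (6, 1, 0))])
        pos = pos + 0.08 * np.random.default_rng(3).standard_normal(pos.shape)
        cfg = wm.Configuration(pos)
        fe = wm.intramolecular_energy_forces(cfg, topo, params)

        class Intra:
            masses = topo.masses

            def force_energy(self, x):
                out = wm.intramolecular_energy_forces(
                    wm.Configuration(x), topo, params)
                return out.energy, out.forces

        num = numerical_forces(Intra(), pos)
        scale = np.abs(fe.forces).max()
        assert np.abs(fe.forces - num).max() / scale < 1e-8

    def test_nonfinite_coordinates_raise(self, params):
        topo = wm.SystemTopology.for_water(1, params)
        pos = _molecule(params)
        pos[1, 0] = np.nan
        with pytest.raises(wm.NumericError):
            wm.intramolecular_energy_forces(wm.Configuration(pos), topo, params)

    def test_mismatched_topology_raises(self, params):
        topo = wm.SystemTopology.for_water(2, params)
        with pytest.raises(wm.StructuralError):
            wm.intramolecular_energy_forces(
                wm.Configuration(_molecule(params)), topo, params)


class TestIntermolecular:
    def test_single_molecule_has_zero_intermolecular_energy(self, params):
        topo = wm.SystemTopology.for_water(1, params)
        cell = wm.SimulationCell([100.0] * 3)
        fe = wm.intermolecular_energy_forces(
            wm.Configuration(_molecule(params, (50, 50, 50))), cell, topo,
            params, coulomb="bare")
        assert fe.energy == 0.0
        assert np.all(fe.forces == 0.0)

    def test_dimer_coulomb_matches_direct_site_sum(self, params):
        """Water dimer in a huge box: Coulomb energy equals the direct sum
        over the 8 charge sites (2 H + M per molecule, 4 sites each, of
        which 3 are charged) to 1e-6 relative."""
        topo = wm.SystemTopology.for_water(2, params)
        cell = wm.SimulationCell([2000.0] * 3)
        pos = np.concatenate([_molecule(params, (1000, 1000, 1000)),
                              _molecule(params, (1005.5, 1001, 1000.5))])
        fe = wm.intermolecular_energy_forces(
            wm.Configuration(pos), cell, topo, params, coulomb="bare")
        sites = wm._site_positions(pos, topo, params)
        charges, _ = wm._site_layout(topo, params)
        e_coul = sum(charges[i] * charges[j]
                     / np.linalg.norm(sites[i] - sites[j])
                     for i in range(3) for j in range(3, 6))
        r_oo = np.linalg.norm(pos[0] - pos[3])
        sr6 = (params.sigma_OO / r_oo) ** 6
        e_lj = 4 * params.eps_OO * (sr6**2 - sr6)
        # subtract the (tiny) force-shift terms of the LJ truncation
        assert fe.energy - e_lj == pytest.approx(e_coul, rel=1e-6)

    @pytest.mark.parametrize("coulomb", ["dsf", "ewald"])
    def test_periodic_forces_match_finite_differences(self, params, coulomb,
                                                      small_liquid):
        cfg, topo, cell = small_liquid
        pot = wm.WaterPotential(topo, cell, params, coulomb=coulomb)
        pos = cfg.positions
        e, f = pot.force_energy(pos)
        num = numerical_forces(pot, pos)
        assert np.abs(f - num).max() / np.abs(f).max() < 1e-6

    def test_ewald_reproduces_madelung_constant(self, params):
        """Rock-salt +-1 charges: Ewald lattice energy per ion pair equals
        the Madelung constant 1.7475646 (independent literature value)."""
        n_side = 4
        L = float(n_side)
        pts = np.array([[x, y, z] for x in range(n_side)
                        for y in range(n_side) for z in range(n_side)], float)
        q = (-1.0) ** pts.sum(axis=1)
        cell = wm.SimulationCell([L, L, L])
        topo = wm.SystemTopology.for_water(2, params)
        pot = wm.WaterPotential(topo, cell, params, coulomb="ewald")
        pairs = pot.pairs

        class FakePairs:
            site_charges = q
            sp_i, sp_j = np.triu_indices(len(pts), k=1)
            qq = q[sp_i] * q[sp_j]
            intra_i = np.array([], dtype=int)
            intra_j = np.array([], dtype=int)
            intra_qq = np.array([])
            sp_scatter = wm._scatter_matrix(len(pts), sp_i, sp_j)
            intra_scatter = wm._scatter_matrix(len(pts), intra_i, intra_j)

        pot.pairs = FakePairs()
        pot.cell = cell
        pot.cutoff = L / 2
        e, _ = pot._ewald_single(pts)
        pot.pairs = pairs
        madelung = -e / (len(pts) / 2)
        assert madelung == pytest.approx(1.7475646, abs=2e-5)

    def test_cutoff_exceeding_half_box_raises(self, params):
        topo = wm.SystemTopology.for_water(1, params)
        cell = wm.SimulationCell([10.0] * 3)
        with pytest.raises(wm.ConfigurationError):
            wm.WaterPotential(topo, cell, params, cutoff=6.0)


class TestInvariants:
    def test_total_force_sums_to_zero(self, params, small_liquid):
        cfg, topo, cell = small_liquid
        pot = wm.WaterPotential(topo, cell, params)
        _, f = pot.force_energy(perturbed(cfg, 0.02).positions)
        assert np.abs(f.sum(axis=0)).max() < 1e-10

    def test_energy_invariant_under_lattice_translation(self, params,
                                                        small_liquid):
        cfg, topo, cell = small_liquid
        pot = wm.WaterPotential(topo, cell, params)
        e0, _ = pot.force_energy(cfg.positions)
        e1, _ = pot.force_energy(cfg.positions + cell.edges)
        assert e1 == pytest.approx(e0, rel=1e-10)


class TestDipole:
    def test_inversion_pair_has_zero_dipole(self, params):
        topo = wm.SystemTopology.for_water(2, params)
        center = np.array([10.0, 10.0, 10.0])
        mol = _molecule(params, (8, 9, 10))
        pos = np.concatenate([mol, 2 * center - mol])
        mu = wm.system_dipole(wm.Configuration(pos), topo, params)
        assert np.abs(mu).max() < 1e-12

    def test_dipole_invariant_under_rigid_translation(self, params,
                                                      small_liquid):
        cfg, topo, cell = small_liquid
        mu0 = wm.system_dipole(cfg, topo, params)
        shifted = wm.Configuration(cfg.positions + np.array([3.0, -2.0, 7.0]))
        mu1 = wm.system_dipole(shifted, topo, params)
        np.testing.assert_allclose(mu1, mu0, atol=1e-10)

    def test_monomer_dipole_along_bisector_matches_hand_sum(self, params):
        """Four-site hand computation: mu = q_H (r_H1 + r_H2) + q_M r_M with
        the O at the origin and the bisector along +z."""
        topo = wm.SystemTopology.for_water(1, params)
        pos = _molecule(params)
        mu = wm.system_dipole(wm.Configuration(pos), topo, params)
        assert abs(mu[0]) < 1e-14 and abs(mu[1]) < 1e-14
        g = params.gamma_M
        m_site = g * pos[0] + 0.5 * (1 - g) * (pos[1] + pos[2])
        hand = params.q_H * (pos[1] + pos[2]) + params.q_M * m_site
        assert mu[2] == pytest.approx(hand[2], rel=1e-12)
        assert mu[2] > 0  # points from O toward the hydrogens

    def test_dipole_derivative_matches_finite_difference_of_dipole(
            self, params, small_liquid):
        cfg, topo, cell = small_liquid
        rng = np.random.default_rng(4)
        v = rng.standard_normal(cfg.positions.shape) * 1e-3
        h = 1e-4
        mu_p = wm.system_dipole(
            wm.Configuration(cfg.positions + h * v), topo, params)
        mu_m = wm.system_dipole(
            wm.Configuration(cfg.positions - h * v), topo, params)
        mdot = wm.dipole_derivative(v, topo, params)
        np.testing.assert_allclose(mdot, (mu_p - mu_m) / (2 * h),
                                   rtol=1e-6, atol=1e-10)


class TestParams:
    def test_charge_neutrality(self, params):
        assert params.q_M == -2 * params.q_H

    @pytest.mark.parametrize("field,value", [
        ("D_r", -1.0), ("sigma_OO", 0.0), ("gamma_M", 1.5), ("k_theta", -2.0),
    ])
    def test_invalid_parameters_rejected(self, params, field, value):
        kwargs = {f: getattr(params, f) for f in (
            "r_eq", "D_r", "a_r", "k_theta", "theta_eq", "sigma_OO", "eps_OO",
            "q_H", "gamma_M", "m_O", "m_H")}
        kwargs[field] = value
        with pytest.raises(ValueError):
            wm.WaterModelParams(**kwargs)
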