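"""Quasi-centroid construction: curvilinear averages, optimal rotation,
placement invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fqcmd import water_model as wm
from fqcmd.pimd import RingPolymerState
from fqcmd.quasicentroid import (QuasiCentroidGeometry, bond_geometries,
                                 canonical_template, curvilinear_geometry,
                                 optimal_rotation, place_quasicentroids,
                                 _optimal_rotation_batched)
from fqcmd.water_model import SimulationCell, StructuralError, SystemTopology

MASSES = np.array([16.0, 1.0, 1.0])


def random_rotation(rng):
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y**2 + z**2), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x**2 + z**2), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x**2 + y**2)]])


def thermal_beads(params, n_mol, P, seed, spread=0.06):
    """Ring-polymer state of jittered equilibrium molecules in a box."""
    rng = np.random.default_rng(seed)
    cell = SimulationCell([25.0, 25.0, 25.0])
    half = params.theta_eq / 2
    mol = params.r_eq * np.array([[0, 0, 0],
                                  [np.sin(half), 0, np.cos(half)],
                                  [-np.sin(half), 0, np.cos(half)]])
    pos = []
    for i in range(n_mol):
        origin = rng.uniform(0, 25.0, 3)
        pos.append(mol @ random_rotation(rng).T + origin)
    pos = np.concatenate(pos)
    beads = pos[None] + spread * rng.standard_normal((P,) + pos.shape)
    return RingPolymerState(beads, np.zeros_like(beads), beta=1000.0), cell


class TestCurvilinearGeometry:
    def test_identical_beads_reproduce_geometry(self):
        g = curvilinear_geometry(np.tile([1.8, 1.75, 1.9], (8, 1, 1)))
        assert g.r1[0] == pytest.approx(1.8)
        assert g.r2[0] == pytest.approx(1.75)
        assert g.theta[0] == pytest.approx(1.9)

    def test_two_bead_arithmetic_mean(self):
        g = curvilinear_geometry(np.array([[[1.7, 1.7, 1.8]],
                                           [[1.9, 1.7, 1.8]]]))
        assert g.r1[0] == pytest.approx(1.8)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(2)
        beads = rng.uniform(1.5, 2.1, (32, 4, 3))
        g = curvilinear_geometry(beads)
        for mol in range(4):
            acc = np.zeros(3)
            for j in range(32):
                acc += beads[j, mol]
            acc /= 32
            assert abs(g.r1[mol] - acc[0]) < 1e-14
            assert abs(g.r2[mol] - acc[1]) < 1e-14
            assert abs(g.theta[mol] - acc[2]) < 1e-14

    def test_empty_bead_list_raises(self):
        with pytest.raises(StructuralError):
            curvilinear_geometry(np.zeros((0, 1, 3)))

    def test_invalid_geometry_rejected(self):
        with pytest.raises(StructuralError):
            QuasiCentroidGeometry(r1=[-1.0], r2=[1.8], theta=[1.9])
        with pytest.raises(StructuralError):
            QuasiCentroidGeometry(r1=[1.8], r2=[1.8], theta=[3.5])


class TestOptimalRotation:
    def test_identical_molecules_give_identity(self):
        rng = np.random.default_rng(0)
        mol = rng.standard_normal((3, 3))
        mol -= MASSES @ mol / MASSES.sum()
        U = optimal_rotation(mol, MASSES, mol)
        np.testing.assert_allclose(U, np.eye(3), atol=1e-10)

    def test_known_rotation_recovered(self):
        rng = np.random.default_rng(1)
        mol = rng.standard_normal((3, 3))
        mol -= MASSES @ mol / MASSES.sum()
        R = random_rotation(rng)
        U = optimal_rotation(mol @ R.T, MASSES, mol)
        np.testing.assert_allclose(U, R, atol=1e-10)

    def test_residual_beats_monte_carlo_rotations(self):
        """The quaternion solution's mass-weighted residual never exceeds
        the best of one million uniformly sampled rotations."""
        rng = np.random.default_rng(3)
        a = rng.standard_normal((3, 3))
        a -= MASSES @ a / MASSES.sum()
        b = rng.standard_normal((3, 3))
        b -= MASSES @ b / MASSES.sum()
        U = optimal_rotation(a, MASSES, b)
        res_opt = np.sum(MASSES[:, None] * (a - b @ U.T) ** 2)
        q = rng.standard_normal((1_000_000, 4))
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        w, x, y, z = q.T
        R = np.empty((len(q), 3, 3))
        R[:, 0, 0] = 1 - 2 * (y**2 + z**2)
        R[:, 0, 1] = 2 * (x * y - w * z)
        R[:, 0, 2] = 2 * (x * z + w * y)
        R[:, 1, 0] = 2 * (x * y + w * z)
        R[:, 1, 1] = 1 - 2 * (x**2 + z**2)
        R[:, 1, 2] = 2 * (y * z - w * x)
        R[:, 2, 0] = 2 * (x * z - w * y)
        R[:, 2, 1] = 2 * (y * z + w * x)
        R[:, 2, 2] = 1 - 2 * (x**2 + y**2)
        rot = np.einsum("nuv,av->nau", R, b)
        res = np.einsum("a,nad->n", MASSES, (a[None] - rot) ** 2)
        assert res_opt <= res.min() + 1e-12

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_rotation_is_proper_and_orthogonal(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal((3, 3))
        a -= MASSES @ a / MASSES.sum()
        b = rng.standard_normal((3, 3))
        b -= MASSES @ b / MASSES.sum()
        U = optimal_rotation(a, MASSES, b)
        assert np.linalg.det(U) == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(U @ U.T, np.eye(3), atol=1e-12)

    def test_collinear_molecule_falls_back_to_axis_alignment(self, caplog):
        a = np.array([[0.0, 0, -1], [0, 0, 0], [0, 0, 1]])
        b = np.array([[-1.0, 0, 0], [0, 0, 0], [1, 0, 0]])
        with caplog.at_level("WARNING"):
            U = optimal_rotation(a, np.array([1.0, 1, 1]), b)
        assert "collinear" in caplog.text
        np.testing.assert_allclose(U @ np.array([1.0, 0, 0]),
                                   np.array([0, 0, 1.0]), atol=1e-12)


class TestPlacement:
    def test_p1_returns_classical_configuration(self, params):
        state, cell = thermal_beads(params, 5, 1, seed=4, spread=0.0)
        topo = SystemTopology.for_water(5, params)
        frame = place_quasicentroids(state, topo, cell)
        np.testing.assert_allclose(frame.positions, state.positions[0],
                                   atol=1e-12)

    def test_rigidly_rotated_beads_keep_rigid_geometry(self, params):
        """Beads generated by rotating one molecule about its mass center:
        curvilinear averages equal the rigid molecule's geometry."""
        rng = np.random.default_rng(8)
        half = params.theta_eq / 2
        mol = params.r_eq * np.array([[0, 0, 0],
                                      [np.sin(half), 0, np.cos(half)],
                                      [-np.sin(half), 0, np.cos(half)]])
        masses = np.array([params.m_O, params.m_H, params.m_H])
        com = masses @ mol / masses.sum()
        beads = np.array([(mol - com) @ random_rotation(rng).T + com + 5.0
                          for _ in range(16)])
        state = RingPolymerState(beads, np.zeros_like(beads), beta=1000.0)
        topo = SystemTopology.for_water(1, params)
        cell = SimulationCell([50.0] * 3)
        frame = place_quasicentroids(state, topo, cell)
        r1, r2, theta = bond_geometries(frame.positions[None])
        assert r1[0, 0] == pytest.approx(params.r_eq, rel=1e-10)
        assert r2[0, 0] == pytest.approx(params.r_eq, rel=1e-10)
        assert theta[0, 0] == pytest.approx(params.theta_eq, rel=1e-10)

    def test_quasicentroid_bond_not_shorter_than_centroid_bond(self, params):
        """Mean of norms >= norm of mean, molecule by molecule."""
        state, cell = thermal_beads(params, 12, 16, seed=5, spread=0.08)
        topo = SystemTopology.for_water(12, params)
        frame = place_quasicentroids(state, topo, cell)
        qc_r1, qc_r2, _ = bond_geometries(frame.positions[None])
        cen = state.positions.mean(axis=0)
        c_r1, c_r2, _ = bond_geometries(cen[None])
        assert np.all(qc_r1[0] >= c_r1[0] - 1e-12)
        assert np.all(qc_r2[0] >= c_r2[0] - 1e-12)

    def test_placement_is_equivariant(self, params):
        """Rigidly rotating + translating all beads transforms the
        quasi-centroid frame identically."""
        state, cell = thermal_beads(params, 4, 8, seed=6)
        big_cell = SimulationCell([1e4] * 3)
        topo = SystemTopology.for_water(4, params)
        rng = np.random.default_rng(10)
        R = random_rotation(rng)
        shift = np.array([3.0, -1.0, 2.0])
        frame_a = place_quasicentroids(state, topo, big_cell)
        moved = RingPolymerState(state.positions @ R.T + shift,
                                 state.velocities, state.beta)
        frame_b = place_quasicentroids(moved, topo, big_cell)
        np.testing.assert_allclose(frame_b.positions,
                                   frame_a.positions @ R.T + shift,
                                   atol=1e-10)

    def test_mass_center_coincides_with_centroid_molecule(self, params):
        state, cell = thermal_beads(params, 6, 8, seed=7)
        topo = SystemTopology.for_water(6, params)
        frame = place_quasicentroids(state, topo, cell)
        masses = np.array([params.m_O, params.m_H, params.m_H])
        qc = frame.positions.reshape(6, 3, 3)
        cen = state.positions.mean(axis=0).reshape(6, 3, 3)
        com_qc = np.einsum("a,nad->nd", masses, qc) / masses.sum()
        com_c = np.einsum("a,nad->nd", masses, cen) / masses.sum()
        np.testing.assert_allclose(com_qc, com_c, atol=1e-10)

    def test_canonical_frame_choice_is_irrelevant(self, params):
        """Placing from a rotated canonical template yields identical
        coordinates: the optimal rotation absorbs the template frame."""
        state, cell = thermal_beads(params, 3, 8, seed=9)
        topo = SystemTopology.for_water(3, params)
        frame = place_quasicentroids(state, topo, cell)

        beads = state.positions
        from fqcmd.quasicentroid import unwrap_molecules
        beads = unwrap_molecules(beads, cell, 3)
        r1, r2, th = bond_geometries(beads)
        geom = curvilinear_geometry(np.stack([r1, r2, th], axis=-1))
        masses = np.array([params.m_O, params.m_H, params.m_H])
        template = canonical_template(geom, masses)
        R = random_rotation(np.random.default_rng(0))
        rotated_template = template @ R.T        # alternative canonical frame
        cen = beads.mean(axis=0).reshape(3, 3, 3)
        com = np.einsum("a,nad->nd", masses, cen) / masses.sum()
        U = _optimal_rotation_batched(cen - com[:, None], rotated_template,
                                      masses)
        placed = com[:, None] + np.einsum("nuv,nav->nau", U, rotated_template)
        np.testing.assert_allclose(placed.reshape(9, 3), frame.positions,
                                   atol=1e-9)

    def test_split_molecule_without_unwrapping_detected(self, params):
        state, cell = thermal_beads(params, 2, 4, seed=11)
        # Corrupt one hydrogen far away (an unwrappable, broken molecule).
        state.positions[:, 1, :] += np.array([10.0, 0, 0])
        topo = SystemTopology.for_water(2, params)
        with pytest.raises(StructuralError):
            place_quasicentroids(state, topo, cell)
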