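"""Quasi-centroid construction for water ring polymers.

The quasi-centroid of a molecule is defined by bead averages of curvilinear
internal coordinates: the two O-H bond lengths and the H-O-H angle, averaged
over the ring-polymer beads.  This rigid geometry is then placed in the cell
by translating its center of mass onto that of the Cartesian-centroid
molecule and rotating it, via a mass-weighted quaternion superposition, to
be as close as possible to the centroid molecule's orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .water_model import (Configuration, SimulationCell, StructuralError,
                          SystemTopology, WaterModelParams)

logger = logging.getLogger(__name__)

#: A bead O-H distance beyond this (a0) indicates a molecule split across a
#: periodic boundary that was not unwrapped.
BOND_SANITY_A0 = 3.0


@dataclass
class QuasiCentroidGeometry:
    """Per-molecule curvilinear averages: bond lengths (a0) and angle (rad)."""

    r1: np.ndarray
    r2: np.ndarray
    theta: np.ndarray

    def __post_init__(self):
        self.r1 = np.atleast_1d(np.asarray(self.r1, float))
        self.r2 = np.atleast_1d(np.asarray(self.r2, float))
        self.theta = np.atleast_1d(np.asarray(self.theta, float))
        if np.any(self.r1 <= 0) or np.any(self.r2 <= 0):
            raise StructuralError("quasi-centroid bond lengths must be positive")
        if np.any(self.theta <= 0) or np.any(self.theta >= np.pi):
            raise StructuralError("quasi-centroid angle must lie in (0, pi)")


@dataclass
class QuasiCentroidFrame:
    """Quasi-centroid atom positions (natoms, 3) for one sampled configuration."""

    positions: np.ndarray
    cell: SimulationCell


def bond_geometries(positions: np.ndarray, cell: SimulationCell | None = None):
    """(r1, r2, theta) per molecule from positions shaped (..., 3N, 3)."""
    o = positions[..., 0::3, :]
    h1 = positions[..., 1::3, :]
    h2 = positions[..., 2::3, :]
    b1 = h1 - o
    b2 = h2 - o
    if cell is not None:
        b1 = cell.minimum_image(b1)
        b2 = cell.minimum_image(b2)
    r1 = np.linalg.norm(b1, axis=-1)
    r2 = np.linalg.norm(b2, axis=-1)
    c = np.clip(np.sum(b1 * b2, axis=-1) / (r1 * r2), -1.0, 1.0)
    return r1, r2, np.arccos(c)


def curvilinear_geometry(bead_geometries) -> QuasiCentroidGeometry:
    """Average per-bead (r1, r2, theta) over the bead axis (axis 0).

    Accepts shape (P, 3) for one molecule or (P, nmol, 3) for many.
    """
    g = np.asarray(bead_geometries, float)
    if g.ndim == 2:
        g = g[:, None, :]
    if g.ndim != 3 or g.shape[-1] != 3 or g.shape[0] < 1:
        raise StructuralError(
            f"expected (P, nmol, 3) bead geometries, got shape {g.shape}")
    mean = g.mean(axis=0)
    return QuasiCentroidGeometry(r1=mean[:, 0], r2=mean[:, 1], theta=mean[:, 2])


# ---------------------------------------------------------------------------
# Mass-weighted optimal rotation (quaternion eigenproblem)
# ---------------------------------------------------------------------------

def _quaternion_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrices from unit quaternions (..., 4) -> (..., 3, 3)."""
    w, x, y, z = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    R = np.empty(q.shape[:-1] + (3, 3))
    R[..., 0, 0] = 1 - 2 * (y**2 + z**2)
    R[..., 0, 1] = 2 * (x * y - w * z)
    R[..., 0, 2] = 2 * (x * z + w * y)
    R[..., 1, 0] = 2 * (x * y + w * z)
    R[..., 1, 1] = 1 - 2 * (x**2 + z**2)
    R[..., 1, 2] = 2 * (y * z - w * x)
    R[..., 2, 0] = 2 * (x * z - w * y)
    R[..., 2, 1] = 2 * (y * z + w * x)
    R[..., 2, 2] = 1 - 2 * (x**2 + y**2)
    return R


def _optimal_rotation_batched(ref: np.ndarray, template: np.ndarray,
                              masses: np.ndarray) -> np.ndarray:
    """Proper rotations U minimizing sum_i m_i |ref_i - U template_i|^2.

    ``ref`` and ``template`` are (..., natoms, 3) and must already be
    expressed relative to their own mass centers.  Solved via the largest
    eigenvector of the 4x4 quaternion matrix (Horn's method); the quaternion
    sign ambiguity is resolved by taking a non-negative scalar part.
    """
    S = np.einsum("a,...au,...av->...uv", masses, template, ref)
    sxx, sxy, sxz = S[..., 0, 0], S[..., 0, 1], S[..., 0, 2]
    syx, syy, syz = S[..., 1, 0], S[..., 1, 1], S[..., 1, 2]
    szx, szy, szz = S[..., 2, 0], S[..., 2, 1], S[..., 2, 2]
    K = np.empty(S.shape[:-2] + (4, 4))
    K[..., 0, 0] = sxx + syy + szz
    K[..., 0, 1] = K[..., 1, 0] = syz - szy
    K[..., 0, 2] = K[..., 2, 0] = szx - sxz
    K[..., 0, 3] = K[..., 3, 0] = sxy - syx
    K[..., 1, 1] = sxx - syy - szz
    K[..., 1, 2] = K[..., 2, 1] = sxy + syx
    K[..., 1, 3] = K[..., 3, 1] = szx + sxz
    K[..., 2, 2] = -sxx + syy - szz
    K[..., 2, 3] = K[..., 3, 2] = syz + szy
    K[..., 3, 3] = -sxx - syy + szz
    w, v = np.linalg.eigh(K)
    q = v[..., :, -1]                       # eigenvector of largest eigenvalue
    sign = np.where(q[..., :1] < 0, -1.0, 1.0)
    return _quaternion_to_matrix(q * sign)


def optimal_rotation(centroid_molecule: np.ndarray, masses: np.ndarray,
                     template_molecule: np.ndarray) -> np.ndarray:
    """Optimal rotation aligning a template molecule onto a centroid molecule.

    Both molecules are (natoms, 3) arrays expressed relative to their own
    mass centers.  Falls back to a planar two-vector alignment for
    (numerically) collinear molecules, which defeat the quaternion method.
    """
    ref = np.asarray(centroid_molecule, float)
    tpl = np.asarray(template_molecule, float)
    masses = np.asarray(masses, float)
    cross_ref = np.cross(ref[1] - ref[0], ref[2] - ref[0])
    cross_tpl = np.cross(tpl[1] - tpl[0], tpl[2] - tpl[0])
    scale = max(np.abs(ref).max(), np.abs(tpl).max(), 1e-300)
    if (np.linalg.norm(cross_ref) < 1e-10 * scale**2
            or np.linalg.norm(cross_tpl) < 1e-10 * scale**2):
        logger.warning("collinear molecule: using two-vector axis alignment")
        return _align_axes(tpl[1] - tpl[0], ref[1] - ref[0])
    return _optimal_rotation_batched(ref[None], tpl[None], masses)[0]


def _align_axes(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking direction a to direction b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-14:
        if c > 0:
            return np.eye(3)
        # 180 degrees: rotate about any axis perpendicular to a.
        perp = np.eye(3)[np.argmin(np.abs(a))]
        axis = np.cross(a, perp)
        axis /= np.linalg.norm(axis)
        return 2 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1 + c)


# ---------------------------------------------------------------------------
# Placement
# ---------------------------------------------------------------------------

def canonical_template(geom: QuasiCentroidGeometry,
                       masses: np.ndarray) -> np.ndarray:
    """Rigid molecules (nmol, 3, 3) built in a canonical frame.

    The H-O-H bisector points along +z and the molecule lies in the xz
    plane; coordinates are relative to the molecular mass center.  The
    optimal rotation makes this choice irrelevant.
    """
    n = len(geom.r1)
    half = geom.theta / 2.0
    mol = np.zeros((n, 3, 3))
    mol[:, 1, 0] = geom.r1 * np.sin(half)
    mol[:, 1, 2] = geom.r1 * np.cos(half)
    mol[:, 2, 0] = -geom.r2 * np.sin(half)
    mol[:, 2, 2] = geom.r2 * np.cos(half)
    com = np.einsum("a,nad->nd", masses, mol) / masses.sum()
    return mol - com[:, None, :]


def unwrap_molecules(bead_positions: np.ndarray, cell: SimulationCell,
                     n_molecules: int) -> np.ndarray:
    """Make every molecule contiguous across periodic boundaries.

    Convention: minimum image of every bead atom relative to the O atom of
    the first bead of its molecule.  Input shape (P, 3N, 3) or (3N, 3).
    """
    pos = np.asarray(bead_positions, float)
    squeeze = pos.ndim == 2
    if squeeze:
        pos = pos[None]
    ref = pos[0, 0::3, :]                               # (nmol, 3)
    mol = pos.reshape(pos.shape[0], n_molecules, 3, 3)
    d = mol - ref[None, :, None, :]
    d = cell.minimum_image(d)
    out = (ref[None, :, None, :] + d).reshape(pos.shape)
    return out[0] if squeeze else out


def place_quasicentroids(rp_state, topo: SystemTopology,
                         cell: SimulationCell) -> QuasiCentroidFrame:
    """Quasi-centroid positions of every atom for one ring-polymer state.

    The ring-polymer beads are unwrapped molecule by molecule, the
    curvilinear averages and the Cartesian centroid molecule are formed, and
    the rigid quasi-centroid molecule is rotated/translated onto the
    centroid molecule (mass-weighted optimal superposition).
    """
    beads = np.asarray(rp_state.positions, float)
    if beads.ndim != 3:
        raise StructuralError("ring-polymer positions must be (P, natoms, 3)")
    n = topo.n_molecules
    beads = unwrap_molecules(beads, cell, n)

    r1, r2, theta = bond_geometries(beads)              # (P, nmol)
    if np.max(r1) > BOND_SANITY_A0 or np.max(r2) > BOND_SANITY_A0:
        raise StructuralError(
            "O-H bond exceeds sanity bound after unwrapping; molecule "
            "split across the periodic boundary?")
    geom = curvilinear_geometry(np.stack([r1, r2, theta], axis=-1))

    centroid = beads.mean(axis=0).reshape(n, 3, 3)      # centroid molecule
    masses = topo.masses[:3]
    com = np.einsum("a,nad->nd", masses, centroid) / masses.sum()
    ref = centroid - com[:, None, :]

    template = canonical_template(geom, masses)         # (nmol, 3, 3)
    U = _optimal_rotation_batched(ref, template, masses)
    placed = com[:, None, :] + np.einsum("nuv,nav->nau", U, template)
    return QuasiCentroidFrame(positions=placed.reshape(3 * n, 3), cell=cell)
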