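"""Deterministic structure generators: liquid water boxes, proton-disordered
hexagonal ice, the gas-phase monomer, and analytic toy systems.

Every generator is a pure function of its spec and seed.  The printed cell
dimensions reproduce the study conditions exactly: 216 molecules in a cubic
35.24 a0 box for the liquid (scaled at constant density for smaller counts)
and 96 molecules in a 25.62 x 29.58 x 27.89 a0 orthorhombic cell for ice Ih.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import units
from .water_model import (Configuration, ConfigurationError, SimulationCell,
                          SystemTopology, WaterModelParams)

#: Study-condition cells.
LIQUID_N = 216
LIQUID_EDGE_A0 = 35.24
ICE_N = 96
ICE_EDGES_A0 = (25.62, 29.58, 27.89)

#: Minimum O-O separation enforced by the liquid generator (a0).
MIN_OO_A0 = 4.5


@dataclass(frozen=True)
class StructureSpec:
    """What to build: phase, size, cell, temperature and seed."""

    phase: str                       # liquid | iceIh | monomer | toy
    n_molecules: int = LIQUID_N
    cell_edges: tuple | None = None  # a0; None -> phase default
    temperature: float = 300.0
    seed: int = 0

    def resolved_edges(self) -> np.ndarray:
        if self.cell_edges is not None:
            return np.asarray(self.cell_edges, float)
        if self.phase == "liquid":
            # Scale the printed cubic cell at constant number density.
            edge = LIQUID_EDGE_A0 * (self.n_molecules / LIQUID_N) ** (1 / 3)
            return np.array([edge, edge, edge])
        if self.phase == "iceIh":
            return np.asarray(ICE_EDGES_A0, float)
        raise ConfigurationError(f"no default cell for phase {self.phase!r}")


def maxwell_boltzmann_velocities(masses: np.ndarray, temperature: float,
                                 rng: np.random.Generator,
                                 zero_momentum: bool = True) -> np.ndarray:
    """Per-atom Gaussian velocities at T (a0 per atomic time unit)."""
    kT = units.KB_HARTREE * temperature
    v = np.sqrt(kT / masses)[:, None] * rng.standard_normal((len(masses), 3))
    if zero_momentum:
        p = (masses[:, None] * v).sum(axis=0)
        v -= p / masses.sum()
    return v


def _monomer_geometry(params: WaterModelParams) -> np.ndarray:
    """One molecule (O, H1, H2) at equilibrium, bisector along +z."""
    half = params.theta_eq / 2.0
    return np.array([
        [0.0, 0.0, 0.0],
        [params.r_eq * np.sin(half), 0.0, params.r_eq * np.cos(half)],
        [-params.r_eq * np.sin(half), 0.0, params.r_eq * np.cos(half)],
    ])


def _random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrices (n, 3, 3) via normalized quaternions."""
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    R = np.empty((n, 3, 3))
    R[:, 0, 0] = 1 - 2 * (y**2 + z**2)
    R[:, 0, 1] = 2 * (x * y - w * z)
    R[:, 0, 2] = 2 * (x * z + w * y)
    R[:, 1, 0] = 2 * (x * y + w * z)
    R[:, 1, 1] = 1 - 2 * (x**2 + z**2)
    R[:, 1, 2] = 2 * (y * z - w * x)
    R[:, 2, 0] = 2 * (x * z - w * y)
    R[:, 2, 1] = 2 * (y * z + w * x)
    R[:, 2, 2] = 1 - 2 * (x**2 + y**2)
    return R


def build_monomer(params: WaterModelParams, temperature: float = 300.0,
                  seed: int = 0, box_edge: float = 1000.0):
    """Gas-phase monomer in a huge box (use coulomb='bare' with it)."""
    rng = np.random.default_rng(seed)
    topo = SystemTopology.for_water(1, params)
    cell = SimulationCell([box_edge] * 3, periodic=[False, False, False])
    pos = _monomer_geometry(params) + box_edge / 2.0
    vel = maxwell_boltzmann_velocities(topo.masses, temperature, rng)
    return Configuration(pos, vel), topo, cell


def build_liquid_box(spec: StructureSpec, params: WaterModelParams):
    """Liquid water on a jittered lattice with random orientations.

    No O-O pair ends up closer than 4.5 a0; velocities are
    Maxwell-Boltzmann at the spec temperature.  Raises if the density is
    too high for the overlap criterion.
    """
    if spec.phase != "liquid":
        raise ConfigurationError("build_liquid_box needs a liquid spec")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_molecules
    edges = spec.resolved_edges()
    cell = SimulationCell(edges)
    topo = SystemTopology.for_water(n, params)

    n_side = int(np.ceil(n ** (1 / 3)))
    spacing = edges / n_side
    if np.min(spacing) <= MIN_OO_A0:
        raise ConfigurationError(
            f"lattice spacing {np.min(spacing):.2f} a0 below the "
            f"{MIN_OO_A0} a0 overlap criterion: density too high")
    sites = np.stack(np.meshgrid(*[np.arange(n_side)] * 3, indexing="ij"),
                     axis=-1).reshape(-1, 3)
    chosen = sites[rng.permutation(len(sites))[:n]]
    centers = (chosen + 0.5) * spacing
    jitter_amp = min(0.3, 0.4 * (np.min(spacing) - MIN_OO_A0))
    # Oxygens sit exactly on the jittered sites (molecules rotate about
    # their O), so the overlap criterion applies to the O-O distances
    # directly.
    pos = None
    for _ in range(50):
        trial = centers + jitter_amp * rng.uniform(-1, 1, centers.shape)
        d = cell.minimum_image(trial[:, None, :] - trial[None, :, :])
        r = np.linalg.norm(d, axis=-1) + np.eye(n) * 1e6
        if r.min() > MIN_OO_A0:
            mol = _monomer_geometry(params)           # O at the origin
            R = _random_rotations(n, rng)
            pos = (trial[:, None, :]
                   + np.einsum("nuv,av->nau", R, mol)).reshape(3 * n, 3)
            break
    if pos is None:
        raise ConfigurationError("could not place molecules without overlap")
    vel = maxwell_boltzmann_velocities(topo.masses, spec.temperature, rng)
    return Configuration(pos, vel), topo, cell


# ---------------------------------------------------------------------------
# Hexagonal ice
# ---------------------------------------------------------------------------

def _ice_oxygen_lattice(edges: np.ndarray) -> np.ndarray:
    """Oxygen positions of ice Ih: a 3x2x2 replication of the 8-molecule
    orthorhombic cell (ideal lonsdaleite fractional coordinates scaled to
    the requested edges)."""
    base = np.array([
        [0.0, 0.0, 0.0],
        [0.0, 1 / 3, 1 / 2],
        [0.0, 0.0, 3 / 8],
        [0.0, 1 / 3, 7 / 8],
        [1 / 2, 1 / 2, 0.0],
        [1 / 2, 5 / 6, 1 / 2],
        [1 / 2, 1 / 2, 3 / 8],
        [1 / 2, 5 / 6, 7 / 8],
    ])
    reps = (3, 2, 2)
    frac = []
    for ix in range(reps[0]):
        for iy in range(reps[1]):
            for iz in range(reps[2]):
                frac.append((base + [ix, iy, iz]) / reps)
    return np.concatenate(frac) * edges


def _ice_bond_graph(oxygens: np.ndarray, cell: SimulationCell):
    """Nearest-neighbor O-O edges (each O has exactly 4)."""
    n = len(oxygens)
    d = cell.minimum_image(oxygens[None, :, :] - oxygens[:, None, :])
    r = np.linalg.norm(d, axis=-1) + np.eye(n) * 1e6
    r_nn = r.min()
    i, j = np.nonzero(np.triu(r < 1.2 * r_nn, k=1))
    counts = np.bincount(np.concatenate([i, j]), minlength=n)
    if not np.all(counts == 4):
        raise ConfigurationError("oxygen lattice is not four-coordinated")
    return list(zip(i.tolist(), j.tolist()))


def build_ice_cell(spec: StructureSpec, params: WaterModelParams,
                   max_dipole: float = 0.5, max_tries: int = 200_000):
    """Proton-disordered hexagonal ice satisfying the Bernal-Fowler rules.

    Protons are assigned by a seeded Monte-Carlo repair (edge flips until
    every O donates exactly two H), followed by directed-loop reversals that
    reduce the net dipole below ``max_dipole`` (e*a0).  Raises, reporting
    the seed, if either stage exhausts its budget.
    """
    if spec.phase != "iceIh":
        raise ConfigurationError("build_ice_cell needs an iceIh spec")
    if spec.n_molecules != ICE_N:
        raise ConfigurationError(f"ice cell supports {ICE_N} molecules")
    rng = np.random.default_rng(spec.seed)
    edges = spec.resolved_edges()
    cell = SimulationCell(edges)
    topo = SystemTopology.for_water(ICE_N, params)
    oxy = _ice_oxygen_lattice(edges)
    bonds = _ice_bond_graph(oxy, cell)

    # Stage 1: ice rules.  donor[e] = 0 means bonds[e][0] donates the H.
    donor = rng.integers(0, 2, len(bonds))

    def out_degree():
        deg = np.zeros(ICE_N, int)
        for e, (a, b) in enumerate(bonds):
            deg[a if donor[e] == 0 else b] += 1
        return deg

    deg = out_degree()
    cost = int(np.sum((deg - 2) ** 2))
    for _ in range(max_tries):
        if cost == 0:
            break
        e = rng.integers(len(bonds))
        a, b = bonds[e]
        da, db = (a, b) if donor[e] == 0 else (b, a)
        # flipping moves one donation from da to db
        new_cost = cost - (deg[da] - 2) ** 2 - (deg[db] - 2) ** 2 \
            + (deg[da] - 3) ** 2 + (deg[db] - 1) ** 2
        if new_cost <= cost:
            donor[e] ^= 1
            deg[da] -= 1
            deg[db] += 1
            cost = new_cost
    if cost != 0:
        raise ConfigurationError(
            f"ice-rule assignment failed for seed {spec.seed}")

    # Stage 2: loop reversals to reduce the net dipole.
    neighbors = {k: [] for k in range(ICE_N)}
    for e, (a, b) in enumerate(bonds):
        neighbors[a].append((e, b))
        neighbors[b].append((e, a))

    def donated(o):
        out = []
        for e, nb in neighbors[o]:
            d_from = bonds[e][0] if donor[e] == 0 else bonds[e][1]
            if d_from == o:
                out.append((e, nb))
        return out

    def bond_unit(a, b):
        d = cell.minimum_image(oxy[b] - oxy[a])
        return d / np.linalg.norm(d)

    def net_dipole():
        mu = np.zeros(3)
        for e, (a, b) in enumerate(bonds):
            src, dst = (a, b) if donor[e] == 0 else (b, a)
            mu += bond_unit(src, dst)
        return mu

    mu = net_dipole()
    for _ in range(2000):
        if np.linalg.norm(mu) * params.q_H * params.r_eq < max_dipole:
            break
        # Random walk along donated edges until a node repeats -> cycle.
        start = int(rng.integers(ICE_N))
        path, edges_path, seen = [start], [], {start: 0}
        node = start
        while True:
            options = donated(node)
            e, nxt = options[rng.integers(len(options))]
            edges_path.append(e)
            if nxt in seen:
                k = seen[nxt]
                cyc_edges = edges_path[k:]
                break
            seen[nxt] = len(path)
            path.append(nxt)
            node = nxt
        delta = np.zeros(3)
        for e in cyc_edges:
            a, b = bonds[e]
            src, dst = (a, b) if donor[e] == 0 else (b, a)
            delta -= 2.0 * bond_unit(src, dst)
        if np.linalg.norm(mu + delta) < np.linalg.norm(mu):
            for e in cyc_edges:
                donor[e] ^= 1
            mu += delta
    else:
        raise ConfigurationError(
            f"dipole reduction failed for seed {spec.seed}")

    # Place covalent hydrogens along the donated O-O directions at r_eq.
    pos = np.zeros((3 * ICE_N, 3))
    pos[0::3] = oxy
    h_slot = np.zeros(ICE_N, int)
    for e, (a, b) in enumerate(bonds):
        src, dst = (a, b) if donor[e] == 0 else (b, a)
        u = bond_unit(src, dst)
        pos[3 * src + 1 + h_slot[src]] = oxy[src] + params.r_eq * u
        h_slot[src] += 1
    assert np.all(h_slot == 2)
    vel = maxwell_boltzmann_velocities(topo.masses, spec.temperature, rng)
    return Configuration(pos, vel), topo, cell


# ---------------------------------------------------------------------------
# Toy systems
# ---------------------------------------------------------------------------

class OscillatorPotential:
    """Separable anharmonic oscillator: sum over coordinates of
    m w^2 x^2 / 2 + c3 x^3 + c4 x^4 (atomic units)."""

    def __init__(self, mass: float = 1.0, omega: float = 0.01,
                 c3: float = 0.0, c4: float = 0.0):
        self.mass_value = mass
        self.omega = omega
        self.c3 = c3
        self.c4 = c4
        self.masses = np.array([mass])

    def force_energy(self, x):
        k = self.mass_value * self.omega**2
        e = np.sum(0.5 * k * x**2 + self.c3 * x**3 + self.c4 * x**4,
                   axis=(-2, -1))
        f = -(k * x + 3 * self.c3 * x**2 + 4 * self.c4 * x**3)
        return e, f

    def quantum_variance_harmonic(self, beta: float) -> float:
        """<x^2> of the harmonic part: (1/2mw) coth(beta w / 2)."""
        return 1.0 / (2 * self.mass_value * self.omega) \
            / np.tanh(beta * self.omega / 2)

    def quantum_position_distribution(self, beta: float, x_grid: np.ndarray
                                      ) -> np.ndarray:
        """Exact 1-D thermal position density by grid diagonalization."""
        dx = x_grid[1] - x_grid[0]
        n = len(x_grid)
        k = self.mass_value * self.omega**2
        V = 0.5 * k * x_grid**2 + self.c3 * x_grid**3 + self.c4 * x_grid**4
        H = np.diag(V + 1.0 / (self.mass_value * dx**2))
        off = -0.5 / (self.mass_value * dx**2)
        H += np.diag(np.full(n - 1, off), 1) + np.diag(np.full(n - 1, off), -1)
        w, v = np.linalg.eigh(H)
        pops = np.exp(-beta * (w - w[0]))
        pops /= pops.sum()
        rho = (v**2 * pops).sum(axis=1) / dx
        return rho


class PairPotentialSystem:
    """Single-species periodic fluid with an arbitrary pair interaction.

    ``pair_fn(r) -> (v, dvdr)`` must vanish smoothly at the cutoff.  Used as
    the substrate for inversion-recovery oracles.
    """

    def __init__(self, n: int, cell: SimulationCell, mass: float,
                 pair_fn, cutoff: float):
        self.n = n
        self.cell = cell
        self.pair_fn = pair_fn
        self.cutoff = cutoff
        self.masses = np.full(n, mass)
        self._i, self._j = np.triu_indices(n, k=1)

    def force_energy(self, x):
        d = self.cell.minimum_image(x[..., self._j, :] - x[..., self._i, :])
        r = np.linalg.norm(d, axis=-1)
        v, dv = self.pair_fn(r)
        mask = r < self.cutoff
        v = np.where(mask, v, 0.0)
        dv = np.where(mask, dv, 0.0)
        e = np.sum(v, axis=-1)
        fpair = -dv[..., None] * d / r[..., None]
        f = np.zeros_like(x)
        flat = fpair.reshape(-1, fpair.shape[-2], 3)
        fr = f.reshape(-1, f.shape[-2], 3)
        for b in range(flat.shape[0]):
            np.add.at(fr[b], self._j, flat[b])
            np.add.at(fr[b], self._i, -flat[b])
        return e, f


def lj_pair(sigma: float, eps: float, r_cut: float):
    """Force-shifted LJ pair function (smooth at the cutoff)."""
    sr6c = (sigma / r_cut) ** 6
    vc = 4 * eps * (sr6c**2 - sr6c)
    dvc = 4 * eps * (-12 * sr6c**2 + 6 * sr6c) / r_cut

    def fn(r):
        sr6 = (sigma / r) ** 6
        v = 4 * eps * (sr6**2 - sr6) - vc - (r - r_cut) * dvc
        dv = 4 * eps * (-12 * sr6**2 + 6 * sr6) / r - dvc
        return v, dv

    return fn


def gaussian_bump(amplitude: float, center: float, width: float):
    """Smooth localized pair perturbation A exp(-(r-r0)^2 / 2w^2)."""

    def fn(r):
        g = amplitude * np.exp(-((r - center) ** 2) / (2 * width**2))
        return g, -g * (r - center) / width**2

    return fn


def single_species_rdf(frames, cell: SimulationCell, edges: np.ndarray
                       ) -> np.ndarray:
    """g(r) of a one-component fluid (helper for toy-system oracles)."""
    hist = np.zeros(len(edges) - 1)
    n_frames = 0
    n = None
    for x in frames:
        n = len(x)
        i, j = np.triu_indices(n, k=1)
        d = cell.minimum_image(x[j] - x[i])
        hist += np.histogram(np.linalg.norm(d, axis=-1), bins=edges)[0]
        n_frames += 1
    shell = (4 * np.pi / 3) * np.diff(edges**3)
    ideal = (n * (n - 1) / 2) * shell / cell.volume
    return hist / (n_frames * ideal)


def build_toy_system(kind: str, seed: int = 0, n: int = 64,
                     temperature_red: float = 1.0, perturbation=None):
    """Self-contained toy bundles for oracle tests.

    ``kind`` is "1d-anharmonic-oscillator" (returns the potential and a
    single-particle configuration) or "pair-perturbed-lj-liquid" (returns
    base and perturbed LJ fluids on a lattice start).  Reduced units
    throughout the toy liquid (sigma = eps = mass = kB = 1).
    """
    rng = np.random.default_rng(seed)
    if kind == "1d-anharmonic-oscillator":
        pot = OscillatorPotential(mass=1.0, omega=0.01, c3=-2e-7, c4=5e-9)
        config = Configuration(np.zeros((1, 3)),
                               rng.standard_normal((1, 3)) * 0.01)
        return pot, config
    if kind == "pair-perturbed-lj-liquid":
        n_side = int(np.ceil(n ** (1 / 3)))
        # Moderate density, supercritical temperature: the pair-from-pair
        # inversion is well conditioned there (at liquid-like densities the
        # RDF is nearly blind to smooth "pressure-like" components of the
        # pair potential, a documented degeneracy of the method).
        rho = 0.4
        L = (n / rho) ** (1 / 3)
        cell = SimulationCell([L, L, L])
        cutoff = min(2.5, L / 2)
        base_fn = lj_pair(1.0, 1.0, cutoff)
        bump = perturbation or gaussian_bump(0.5, 1.3, 0.18)

        def perturbed_fn(r):
            v, dv = base_fn(r)
            g, dg = bump(r)
            return v + g, dv + dg

        sites = np.stack(np.meshgrid(*[np.arange(n_side)] * 3, indexing="ij"),
                         axis=-1).reshape(-1, 3)
        sites = sites[rng.permutation(len(sites))[:n]]
        pos = (sites + 0.5) * (L / n_side) \
            + 0.05 * rng.standard_normal((n, 3))
        vel = rng.standard_normal((n, 3)) * np.sqrt(temperature_red)
        base = PairPotentialSystem(n, cell, 1.0, base_fn, cutoff)
        pert = PairPotentialSystem(n, cell, 1.0, perturbed_fn, cutoff)
        return base, pert, Configuration(pos, vel), cell, bump
    raise ConfigurationError(f"unknown toy system {kind!r}")
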