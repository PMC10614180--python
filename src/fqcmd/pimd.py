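"""Path-integral molecular dynamics of the ring-polymer system.

The ring polymer is propagated in the "scaled" convention: the physical
potential enters with weight 1/P, the springs carry frequency sqrt(P)/beta
(hbar = 1), and the whole system is thermostatted at the physical
temperature, so bead marginals sample the exact quantum thermal
distribution.  Propagation uses an OBABO splitting: half-step per-normal-mode
Langevin thermostat (PILE), half-step velocity update from the physical
forces, exact free-ring-polymer normal-mode evolution, and the mirror
half-steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import units
from .distributions import DistributionAccumulator, DistributionSet
from .md_core import IntegratorSettings, PropagationError
from .quasicentroid import place_quasicentroids
from .water_model import Configuration, SimulationCell, SystemTopology


@dataclass
class RingPolymerState:
    """P replicas of all atomic positions/velocities plus beta (1/hartree)."""

    positions: np.ndarray        # (P, natoms, 3)
    velocities: np.ndarray       # (P, natoms, 3)
    beta: float

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float)
        self.velocities = np.asarray(self.velocities, float)
        if self.positions.ndim != 3 or self.positions.shape != self.velocities.shape:
            raise ValueError("ring-polymer arrays must be (P, natoms, 3)")
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def centroid(self) -> Configuration:
        return Configuration(self.positions.mean(axis=0),
                             self.velocities.mean(axis=0))

    def copy(self) -> "RingPolymerState":
        return RingPolymerState(self.positions.copy(), self.velocities.copy(),
                                self.beta)


# ---------------------------------------------------------------------------
# Normal modes
# ---------------------------------------------------------------------------

def _orthonormal_matrix(P: int) -> np.ndarray:
    """Real orthonormal Fourier matrix C with C[0] the uniform row."""
    C = np.empty((P, P))
    j = np.arange(P)
    C[0] = 1.0 / np.sqrt(P)
    for k in range(1, P // 2 + (P % 2)):
        C[k] = np.sqrt(2.0 / P) * np.cos(2 * np.pi * k * j / P)
        C[P - k] = np.sqrt(2.0 / P) * np.sin(2 * np.pi * k * j / P)
    if P % 2 == 0 and P > 1:
        C[P // 2] = (-1.0) ** j / np.sqrt(P)
    return C


class NormalModes:
    """Orthonormal bead <-> mode transform and free-ring-polymer frequencies."""

    def __init__(self, P: int, beta: float):
        self.P = P
        self.beta = beta
        self.C = _orthonormal_matrix(P)
        omega_tilde = np.sqrt(P) / beta            # spring frequency, a.u.
        k = np.arange(P)
        k_eff = np.minimum(k, P - k)
        self.omega = 2.0 * omega_tilde * np.sin(np.pi * k_eff / P)

    def to_modes(self, beads: np.ndarray) -> np.ndarray:
        return np.tensordot(self.C, beads, axes=(1, 0))

    def to_beads(self, modes: np.ndarray) -> np.ndarray:
        return np.tensordot(self.C.T, modes, axes=(1, 0))


def normal_mode_transform(coords: np.ndarray, direction: str = "to_modes",
                          beta: float = 1.0) -> np.ndarray:
    """Public bead <-> mode transform with mode 0 scaled to the bead mean.

    ``coords`` has the bead/mode index on axis 0.  The round trip is the
    identity and the mode-0 component equals the arithmetic bead mean.
    """
    x = np.asarray(coords, float)
    P = x.shape[0]
    nm = NormalModes(P, beta)
    if direction == "to_modes":
        modes = nm.to_modes(x)
        modes = modes / np.sqrt(P)
        return modes
    elif direction == "to_beads":
        return nm.to_beads(x * np.sqrt(P))
    raise ValueError(f"unknown direction {direction!r}")


# ---------------------------------------------------------------------------
# Propagation
# ---------------------------------------------------------------------------

class PIMDIntegrator:
    """OBABO ring-polymer propagator with a PILE thermostat.

    Mode k > 0 is thermostatted with friction 2 * omega_k (optimal for the
    free ring polymer); the centroid mode uses 1/tau with the settings' time
    constant (weak coupling).  Thermostat off means NVE ring-polymer
    dynamics (useful for tests; sampling runs keep it on).
    """

    def __init__(self, potential, settings: IntegratorSettings, beta: float,
                 P: int, rng: np.random.Generator | None = None):
        self.potential = potential
        self.settings = settings
        self.nm = NormalModes(P, beta)
        self.beta = beta
        self.P = P
        self.rng = rng if rng is not None else np.random.default_rng(settings.seed)
        dt = settings.dt_au
        m = potential.masses                        # (natoms,)
        omega = self.nm.omega
        # Exact free-RP evolution coefficients per mode.
        self._cos = np.cos(omega * dt)
        self._sin = np.sin(omega * dt)
        self._omega = omega
        self._masses = m
        if settings.thermostat == "langevin":
            gamma = np.where(omega > 0, 2.0 * omega, 1.0 / (settings.tau_fs
                                                            * units.FS_TO_AUT))
            c1 = np.exp(-gamma * dt / 2.0)
            kT = 1.0 / beta
            self._th_c1 = c1[:, None, None]
            self._th_c2 = np.sqrt((1.0 - c1[:, None]**2) * kT / m)[..., None]
        else:
            self._th_c1 = None

    def _thermostat_half(self, vmodes):
        if self._th_c1 is None:
            return vmodes
        noise = self.rng.standard_normal(vmodes.shape)
        return self._th_c1 * vmodes + self._th_c2 * noise

    def step(self, state: RingPolymerState, forces: np.ndarray | None = None):
        """One OBABO step; returns ``(new_state, new_forces)``.

        ``forces`` may carry the physical forces at the current positions
        (they are unchanged by the closing thermostat half-step of the
        previous call, so passing them back saves one evaluation per step).
        """
        dt = self.settings.dt_au
        m = self._masses[None, :, None]
        x, v = state.positions, state.velocities

        vm = self.nm.to_modes(v)
        vm = self._thermostat_half(vm)
        v = self.nm.to_beads(vm)

        if forces is None:
            _, forces = self.potential.force_energy(x)
        f = forces
        if not np.all(np.isfinite(f)):
            raise PropagationError("non-finite physical force")
        v = v + 0.5 * dt * f / (self.P * m)

        xm = self.nm.to_modes(x)
        vm = self.nm.to_modes(v)
        xm, vm = self._free_rp(xm, vm, dt)
        x = self.nm.to_beads(xm)
        v = self.nm.to_beads(vm)

        _, f = self.potential.force_energy(x)
        if not np.all(np.isfinite(f)):
            raise PropagationError("non-finite physical force")
        v = v + 0.5 * dt * f / (self.P * m)

        vm = self.nm.to_modes(v)
        vm = self._thermostat_half(vm)
        v = self.nm.to_beads(vm)
        return RingPolymerState(x, v, state.beta), f

    def _free_rp(self, xm, vm, dt):
        """Exact harmonic evolution of each normal mode (mode 0 drifts)."""
        cos = self._cos[:, None, None]
        sin = self._sin[:, None, None]
        omega = self._omega[:, None, None]
        free = self._omega == 0
        x_new = np.where(free[:, None, None], xm + vm * dt,
                         xm * cos + np.divide(vm, np.where(omega == 0, 1.0, omega))
                         * sin)
        v_new = np.where(free[:, None, None], vm, vm * cos - omega * xm * sin)
        return x_new, v_new


def pimd_step(state: RingPolymerState, settings: IntegratorSettings,
              potential, rng: np.random.Generator | None = None
              ) -> RingPolymerState:
    """Single OBABO step (convenience wrapper constructing the integrator)."""
    integ = PIMDIntegrator(potential, settings, state.beta, state.n_beads, rng)
    new_state, _ = integ.step(state)
    return new_state


def run_pimd(state: RingPolymerState, potential, settings: IntegratorSettings,
             n_steps: int, stride: int = 1, frame_hook=None,
             rng: np.random.Generator | None = None) -> RingPolymerState:
    """Propagate and call ``frame_hook(step, state)`` every ``stride`` steps."""
    integ = PIMDIntegrator(potential, settings, state.beta, state.n_beads, rng)
    f = None
    for step in range(1, n_steps + 1):
        state, f = integ.step(state, f)
        if frame_hook is not None and step % stride == 0:
            frame_hook(step, state)
    return state


# ---------------------------------------------------------------------------
# Estimators and sampling
# ---------------------------------------------------------------------------

def kinetic_energy_estimators(state: RingPolymerState, potential):
    """(primitive, virial) quantum kinetic-energy estimators (hartree).

    Their agreement on equilibrated trajectories is the standard internal
    consistency check of a PIMD implementation.
    """
    P = state.n_beads
    beta = state.beta
    m = potential.masses[None, :, None]
    x = state.positions
    n_dof = x.shape[1] * 3
    omega_tilde = np.sqrt(P) / beta
    springs = 0.5 * np.sum(m * omega_tilde**2
                           * (x - np.roll(x, -1, axis=0))**2)
    primitive = n_dof * P / (2.0 * beta) - springs
    _, f = potential.force_energy(x)
    xc = x.mean(axis=0)
    virial = n_dof / (2.0 * beta) - 0.5 / P * np.sum((x - xc) * f)
    return float(primitive), float(virial)


def sample_quasicentroid_ensemble(state: RingPolymerState, potential,
                                  settings: IntegratorSettings,
                                  topo: SystemTopology, cell: SimulationCell,
                                  n_steps: int, stride: int,
                                  temperature: float,
                                  accumulator: DistributionAccumulator | None = None,
                                  frame_callback=None,
                                  rng: np.random.Generator | None = None):
    """Sample quasi-centroid frames and accumulate all five distributions.

    Returns ``(final_state, DistributionSet)``.  ``frame_callback(frame)``
    receives every constructed QuasiCentroidFrame (e.g. for trajectory
    output).
    """
    if accumulator is None:
        accumulator = DistributionAccumulator(topo, cell, temperature)

    def hook(step, st):
        frame = place_quasicentroids(st, topo, cell)
        accumulator.add_frame(frame.positions)
        if frame_callback is not None:
            frame_callback(frame)

    state = run_pimd(state, potential, settings, n_steps, stride=stride,
                     frame_hook=hook, rng=rng)
    return state, accumulator.finalize()


def initialize_ring_polymer(config: Configuration, P: int, beta: float,
                            masses: np.ndarray,
                            rng: np.random.Generator,
                            spread: float = 0.0) -> RingPolymerState:
    """Replicate a classical configuration into P beads.

    Bead positions get an optional Gaussian spread (a0) to break the
    collapsed-ring start; velocities are Maxwell-Boltzmann at 1/beta.
    """
    pos = np.repeat(config.positions[None], P, axis=0)
    if spread > 0:
        pos = pos + spread * rng.standard_normal(pos.shape)
    kT = 1.0 / beta
    sigma = np.sqrt(kT / masses)[None, :, None]
    vel = sigma * rng.standard_normal(pos.shape)
    return RingPolymerState(pos, vel, beta)
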