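"""Classical propagation: velocity-Verlet NVE and Langevin NVT.

The Langevin integrator uses the BAOAB splitting, which reduces exactly to
velocity Verlet when the friction is switched off.  Spectra are computed
from NVE segments launched from thermostatted snapshots, so the thermostat
never touches the dynamics that enters a correlation function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import units
from .water_model import Configuration, ForceEnergy


class PropagationError(RuntimeError):
    pass


@dataclass
class IntegratorSettings:
    """Time step and thermostat parameters.

    ``dt_fs`` defaults to 0.25 fs, adequate for the O-H stretch at the
    masses of this model.  ``thermostat`` is either ``"none"`` (NVE) or
    ``"langevin"`` (local stochastic, friction 1/tau_fs).
    """

    dt_fs: float = 0.25
    thermostat: str = "none"
    tau_fs: float = 100.0
    temperature: float = 300.0
    seed: int = 0

    def __post_init__(self):
        if self.dt_fs <= 0:
            raise ValueError("time step must be positive")
        if self.thermostat not in ("none", "langevin"):
            raise ValueError(f"unknown thermostat {self.thermostat!r}")
        if self.thermostat == "langevin" and self.temperature <= 0:
            raise ValueError("thermostatted runs need a positive temperature")

    @property
    def dt_au(self) -> float:
        return self.dt_fs * units.FS_TO_AUT

    @property
    def friction_au(self) -> float:
        if self.thermostat == "none":
            return 0.0
        return 1.0 / (self.tau_fs * units.FS_TO_AUT)


@dataclass
class TrajectoryRecord:
    """Sampled times (fs) and observable streams at a fixed stride."""

    times_fs: np.ndarray
    observables: dict = field(default_factory=dict)
    final: Configuration | None = None

    def __post_init__(self):
        t = np.asarray(self.times_fs, float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("sample times must be strictly increasing")
        self.times_fs = t


def _check_forces(forces: np.ndarray):
    if not np.all(np.isfinite(forces)):
        bad = np.argwhere(~np.isfinite(forces))
        raise PropagationError(f"non-finite force on atom {bad[0][0]}")


def kinetic_energy(velocities: np.ndarray, masses: np.ndarray) -> float:
    return float(0.5 * np.sum(masses[..., None] * velocities**2))


def velocity_verlet_step(config: Configuration, forces: ForceEnergy,
                         settings: IntegratorSettings, potential):
    """One symplectic step; returns the new configuration and force/energy.

    Time-reversible: integrating forward and then backward with reversed
    momenta returns the starting state.
    """
    dt = settings.dt_au
    m = potential.masses[:, None]
    _check_forces(forces.forces)
    v = config.velocities + 0.5 * dt * forces.forces / m
    x = config.positions + dt * v
    e, f = potential.force_energy(x)
    _check_forces(f)
    v = v + 0.5 * dt * f / m
    return Configuration(x, v), ForceEnergy(float(e), f)


def run_md(initial: Configuration, potential, settings: IntegratorSettings,
           n_steps: int, stride: int = 1, hooks: dict | None = None,
           rng: np.random.Generator | None = None) -> TrajectoryRecord:
    """Propagate ``n_steps`` BAOAB steps, sampling observables every ``stride``.

    ``hooks`` maps names to callables ``f(positions, velocities) -> array``;
    kinetic, potential and total energies are always recorded.  All
    randomness comes from ``rng`` (or a generator seeded by settings.seed).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    hooks = hooks or {}
    dt = settings.dt_au
    m = potential.masses[:, None]
    gamma = settings.friction_au
    if gamma > 0:
        c1 = np.exp(-gamma * dt)
        kT = units.KB_HARTREE * settings.temperature
        c2 = np.sqrt((1.0 - c1**2) * kT / potential.masses)[:, None]

    x = initial.positions.copy()
    v = initial.velocities.copy()
    e, f = potential.force_energy(x)
    _check_forces(f)

    times, samples = [], {name: [] for name in hooks}
    energies = {"kinetic": [], "potential": [], "total": []}

    for step in range(1, n_steps + 1):
        v += 0.5 * dt * f / m                      # B
        x += 0.5 * dt * v                          # A
        if gamma > 0:                              # O
            v = c1 * v + c2 * rng.standard_normal(v.shape)
        x += 0.5 * dt * v                          # A
        e, f = potential.force_energy(x)
        _check_forces(f)
        v += 0.5 * dt * f / m                      # B
        if step % stride == 0:
            times.append(step * settings.dt_fs)
            ke = kinetic_energy(v, potential.masses)
            energies["kinetic"].append(ke)
            energies["potential"].append(float(e))
            energies["total"].append(ke + float(e))
            for name, hook in hooks.items():
                samples[name].append(hook(x, v))

    obs = {k: np.asarray(vv) for k, vv in energies.items()}
    obs.update({k: np.asarray(vv) for k, vv in samples.items()})
    return TrajectoryRecord(times_fs=np.asarray(times),
                            observables=obs,
                            final=Configuration(x, v))


def thermostatted_run(initial: Configuration, settings: IntegratorSettings,
                      potential, n_steps: int, sample_hooks: dict | None = None,
                      stride: int = 1,
                      rng: np.random.Generator | None = None) -> TrajectoryRecord:
    """Canonical (NVT) sampling run; a thin wrapper around :func:`run_md`."""
    if settings.thermostat == "none":
        raise ValueError("thermostatted_run requires a thermostat; "
                         "use run_md for NVE")
    return run_md(initial, potential, settings, n_steps, stride=stride,
                  hooks=sample_hooks, rng=rng)
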