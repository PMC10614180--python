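"""Shared fixtures: model parameters and small generated structures."""

import numpy as np
import pytest

from fqcmd import fixtures as fx
from fqcmd import water_model as wm


@pytest.fixture(scope="session")
def params():
    return wm.WaterModelParams.default()


@pytest.fixture(scope="session")
def monomer(params):
    """Single equilibrium molecule in a large non-periodic box."""
    return fx.build_monomer(params, temperature=300.0, seed=1)


@pytest.fixture(scope="session")
def small_liquid(params):
    """16-molecule liquid box at the printed density (cheap test substrate)."""
    spec = fx.StructureSpec(phase="liquid", n_molecules=16,
                            temperature=300.0, seed=7)
    return fx.build_liquid_box(spec, params)


def perturbed(config, scale, seed=0):
    """Configuration with Gaussian-perturbed positions."""
    rng = np.random.default_rng(seed)
    out = config.copy()
    out.positions = out.positions + scale * rng.standard_normal(
        out.positions.shape)
    return out


def numerical_forces(potential, positions, h=1e-5):
    """Central-difference gradient oracle for any batched potential."""
    num = np.zeros_like(positions)
    for i in range(positions.shape[0]):
        for d in range(3):
            pp = positions.copy()
            pp[i, d] += h
            ep, _ = potential.force_energy(pp)
            pm = positions.copy()
            pm[i, d] -= h
            em, _ = potential.force_energy(pm)
            num[i, d] = -(ep - em) / (2 * h)
    return num
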