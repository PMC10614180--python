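"""File I/O: extended-XYZ structures, CSV tables, HDF5 archival state."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .distributions import (DistributionSet, IntraDistributions,
                            RadialDistribution)
from .spectra import AbsorptionSpectrum
from .water_model import Configuration, SimulationCell


def write_extxyz(path, positions_a0: np.ndarray, cell: SimulationCell,
                 comment_fields: dict | None = None, append: bool = False,
                 symbols: list | None = None) -> None:
    """Write one frame of extended XYZ (positions in a0, O H H per molecule)."""
    pos = np.asarray(positions_a0, float)
    n = len(pos)
    if symbols is None:
        symbols = (["O", "H", "H"] * (n // 3))[:n]
    lattice = " ".join(f"{x:.10f}" for x in np.diag(cell.edges).ravel())
    extras = "".join(f" {k}={v}" for k, v in (comment_fields or {}).items())
    pbc = " ".join("T" if p else "F" for p in cell.periodic)
    lines = [f"{n}",
             f'Lattice="{lattice}" Properties=species:S:1:pos:R:3 '
             f'pbc="{pbc}"{extras}']
    for s, (x, y, z) in zip(symbols, pos):
        lines.append(f"{s} {x:.10f} {y:.10f} {z:.10f}")
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write("\n".join(lines) + "\n")


def read_extxyz(path):
    """Read the first frame of an extended-XYZ file -> (symbols, positions, cell)."""
    lines = Path(path).read_text().splitlines()
    n = int(lines[0])
    header = lines[1]
    lat = header.split('Lattice="')[1].split('"')[0].split()
    mat = np.array([float(x) for x in lat]).reshape(3, 3)
    cell = SimulationCell(np.diag(mat))
    symbols, pos = [], []
    for line in lines[2:2 + n]:
        parts = line.split()
        symbols.append(parts[0])
        pos.append([float(x) for x in parts[1:4]])
    return symbols, np.array(pos), cell


def write_spectrum_csv(path, spectrum: AbsorptionSpectrum,
                       metadata: dict | None = None) -> None:
    """Two-column CSV (cm^-1, intensity) with a metadata comment header."""
    meta = {"window_tau_fs": spectrum.window_tau_fs, **(metadata or {})}
    header = "".join(f"# {k} = {v}\n" for k, v in meta.items())
    body = pd.DataFrame({"frequency_cm1": spectrum.frequency_cm1,
                         "intensity": spectrum.intensity}).to_csv(index=False)
    Path(path).write_text(header + body)


def read_spectrum_csv(path) -> AbsorptionSpectrum:
    meta = {}
    for line in Path(path).read_text().splitlines():
        if not line.startswith("#"):
            break
        key, _, value = line[1:].partition("=")
        meta[key.strip()] = value.strip()
    df = pd.read_csv(path, comment="#")
    return AbsorptionSpectrum(frequency_cm1=df["frequency_cm1"].to_numpy(),
                              intensity=df["intensity"].to_numpy(),
                              window_tau_fs=float(meta.get("window_tau_fs", 0)))


# ---------------------------------------------------------------------------
# HDF5 archival state
# ---------------------------------------------------------------------------

def save_ring_polymer(path, state, cell: SimulationCell) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("positions", data=state.positions)
        fh.create_dataset("velocities", data=state.velocities)
        fh.attrs["beta"] = state.beta
        fh.create_dataset("cell_edges", data=cell.edges)


def load_ring_polymer(path):
    from .pimd import RingPolymerState
    with h5py.File(path, "r") as fh:
        state = RingPolymerState(fh["positions"][...], fh["velocities"][...],
                                 float(fh.attrs["beta"]))
        cell = SimulationCell(fh["cell_edges"][...])
    return state, cell


def _write_rdf(group, rdf: RadialDistribution):
    group.create_dataset("edges", data=rdf.edges)
    group.create_dataset("g", data=rdf.g)
    group.attrs.update({"pair": rdf.pair, "n_frames": rdf.n_frames,
                        "n_pairs": rdf.n_pairs})


def _read_rdf(group) -> RadialDistribution:
    return RadialDistribution(pair=str(group.attrs["pair"]),
                              edges=group["edges"][...], g=group["g"][...],
                              n_frames=int(group.attrs["n_frames"]),
                              n_pairs=int(group.attrs["n_pairs"]))


def save_distribution_set(path, ds: DistributionSet) -> None:
    with h5py.File(path, "w") as fh:
        for rdf in (ds.g_oo, ds.g_oh, ds.g_hh):
            _write_rdf(fh.create_group(f"g_{rdf.pair}"), rdf)
        gi = fh.create_group("intra")
        gi.create_dataset("r_edges", data=ds.intra.r_edges)
        gi.create_dataset("rho_r", data=ds.intra.rho_r)
        gi.create_dataset("theta_edges", data=ds.intra.theta_edges)
        gi.create_dataset("rho_theta", data=ds.intra.rho_theta)
        gi.attrs["n_out_of_range"] = ds.intra.n_out_of_range
        fh.attrs["n_frames"] = ds.n_frames
        fh.attrs["temperature"] = ds.temperature


def load_distribution_set(path) -> DistributionSet:
    with h5py.File(path, "r") as fh:
        intra = IntraDistributions(
            r_edges=fh["intra/r_edges"][...], rho_r=fh["intra/rho_r"][...],
            theta_edges=fh["intra/theta_edges"][...],
            rho_theta=fh["intra/rho_theta"][...],
            n_out_of_range=int(fh["intra"].attrs["n_out_of_range"]))
        return DistributionSet(
            g_oo=_read_rdf(fh["g_OO"]), g_oh=_read_rdf(fh["g_OH"]),
            g_hh=_read_rdf(fh["g_HH"]), intra=intra,
            n_frames=int(fh.attrs["n_frames"]),
            temperature=float(fh.attrs["temperature"]))


def save_ibi_checkpoint(path, state, directory_for_tables) -> None:
    """IBI restart data: correction (text tables) + MD configuration (HDF5)."""
    state.correction.save(directory_for_tables)
    with h5py.File(path, "w") as fh:
        fh.attrs["iteration"] = state.correction.iteration
        fh.attrs["epsilon"] = state.correction.epsilon
        if state.config is not None:
            fh.create_dataset("positions", data=state.config.positions)
            fh.create_dataset("velocities", data=state.config.velocities)
        hist = fh.create_group("history")
        for i, metric in enumerate(state.history):
            g = hist.create_group(str(i))
            g.attrs.update(metric)


def load_ibi_checkpoint(path, directory_for_tables, target) -> "object":
    from .ibi import CorrectionPotential, IBIState
    correction = CorrectionPotential.load(directory_for_tables)
    with h5py.File(path, "r") as fh:
        config = None
        if "positions" in fh:
            config = Configuration(fh["positions"][...], fh["velocities"][...])
        history = []
        if "history" in fh:
            for i in sorted(fh["history"], key=int):
                history.append(dict(fh["history"][i].attrs))
    return IBIState(target=target, correction=correction, config=config,
                    history=history)
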