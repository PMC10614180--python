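"""Accumulation of the five target distribution functions.

Three intermolecular radial distribution functions (g_OO, g_OH, g_HH) and
two intramolecular densities (rho_r over the O-H bond length, rho_theta over
the H-O-H angle).  The same accumulation code path serves classical
configurations and quasi-centroid frames: a quasi-centroid molecule's
internal geometry *is* the bead average of the curvilinear coordinates, so
histogramming the placed quasi-centroid positions directly yields the
quasi-centroid distribution functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .quasicentroid import QuasiCentroidGeometry, bond_geometries
from .water_model import (ConfigurationError, SimulationCell, SystemTopology,
                          _pair_arrays)

logger = logging.getLogger(__name__)

#: Default bin widths: statistical noise, not resolution, should limit the
#: inversion accuracy at these system sizes.
RDF_BIN_A0 = 0.05
RHO_R_BIN_A0 = 0.02
RHO_THETA_BIN_RAD = np.deg2rad(0.5)

RHO_R_RANGE_A0 = (1.2, 2.6)
RHO_THETA_RANGE_RAD = (np.deg2rad(60.0), np.deg2rad(160.0))


@dataclass
class RadialDistribution:
    """g_XY(r) on uniform bins, normalized so g -> 1 in a homogeneous liquid."""

    pair: str                  # "OO", "OH" or "HH"
    edges: np.ndarray          # bin edges, a0
    g: np.ndarray
    n_frames: int
    n_pairs: int               # distinct intermolecular pairs per frame

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class IntraDistributions:
    """rho_r and rho_theta histograms, each normalized to unit integral."""

    r_edges: np.ndarray
    rho_r: np.ndarray
    theta_edges: np.ndarray
    rho_theta: np.ndarray
    n_out_of_range: int = 0

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])

    @property
    def theta_centers(self) -> np.ndarray:
        return 0.5 * (self.theta_edges[:-1] + self.theta_edges[1:])


@dataclass
class DistributionSet:
    """The five functions accumulated from one frame stream."""

    g_oo: RadialDistribution
    g_oh: RadialDistribution
    g_hh: RadialDistribution
    intra: IntraDistributions
    n_frames: int
    temperature: float

    def radial(self, pair: str) -> RadialDistribution:
        return {"OO": self.g_oo, "OH": self.g_oh, "HH": self.g_hh}[pair]

    def to_csv(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for rdf in (self.g_oo, self.g_oh, self.g_hh):
            pd.DataFrame({"r_a0": rdf.centers, "g": rdf.g}).to_csv(
                directory / f"g_{rdf.pair}.csv", index=False)
        pd.DataFrame({"r_a0": self.intra.r_centers,
                      "rho_r": self.intra.rho_r}).to_csv(
            directory / "rho_r.csv", index=False)
        pd.DataFrame({"theta_rad": self.intra.theta_centers,
                      "rho_theta": self.intra.rho_theta}).to_csv(
            directory / "rho_theta.csv", index=False)


class DistributionAccumulator:
    """Histogram accumulator shared by PIMD quasi-centroid and classical runs.

    Call :meth:`add_frame` with per-atom positions (O,H,H per molecule) for
    each sampled configuration, then :meth:`finalize`.
    """

    def __init__(self, topo: SystemTopology, cell: SimulationCell,
                 temperature: float, r_max: float | None = None,
                 rdf_bin: float = RDF_BIN_A0,
                 rho_r_range=RHO_R_RANGE_A0, rho_r_bin: float = RHO_R_BIN_A0,
                 theta_range=RHO_THETA_RANGE_RAD,
                 theta_bin: float = RHO_THETA_BIN_RAD):
        self.topo = topo
        self.cell = cell
        self.temperature = temperature
        half = cell.half_min_edge
        if r_max is None:
            # Non-periodic cells have no natural range; 15 a0 spans the
            # structured part of every water RDF.
            self.r_max = half if np.isfinite(half) else 15.0
        else:
            self.r_max = float(r_max)
        if self.r_max > half * (1 + 1e-12):
            raise ConfigurationError(
                f"RDF range {self.r_max} exceeds half the smallest edge {half}")
        n_bins = int(np.floor(self.r_max / rdf_bin))
        self.rdf_edges = np.arange(n_bins + 1) * rdf_bin
        self.r_edges = np.arange(rho_r_range[0], rho_r_range[1] + rho_r_bin / 2,
                                 rho_r_bin)
        self.theta_edges = np.arange(theta_range[0], theta_range[1] + theta_bin / 2,
                                     theta_bin)

        n = topo.n_molecules
        mol_of_atom = np.repeat(np.arange(n), 3)
        species = np.tile([0, 1, 1], n)          # 0 = O, 1 = H
        i, j = _pair_arrays(topo.n_atoms, mol_of_atom)
        si, sj = species[i], species[j]
        self._pairs = {
            "OO": (i[(si == 0) & (sj == 0)], j[(si == 0) & (sj == 0)]),
            "OH": (i[si != sj], j[si != sj]),
            "HH": (i[(si == 1) & (sj == 1)], j[(si == 1) & (sj == 1)]),
        }
        self._hist = {k: np.zeros(n_bins) for k in self._pairs}
        self._hist_r = np.zeros(len(self.r_edges) - 1)
        self._hist_th = np.zeros(len(self.theta_edges) - 1)
        self._n_out = 0
        self.n_frames = 0

    def add_frame(self, positions: np.ndarray,
                  geometry: QuasiCentroidGeometry | None = None) -> None:
        """Accumulate one configuration.

        ``geometry`` may override the intramolecular values (normally they
        are recomputed from the positions, which is exact for both sources).
        """
        pos = np.asarray(positions, float)
        for pair, (i, j) in self._pairs.items():
            d = self.cell.minimum_image(pos[j] - pos[i])
            r = np.linalg.norm(d, axis=-1)
            self._hist[pair] += np.histogram(r, bins=self.rdf_edges)[0]
        if geometry is None:
            r1, r2, theta = bond_geometries(pos[None], self.cell)
            r1, r2, theta = r1[0], r2[0], theta[0]
        else:
            r1, r2, theta = geometry.r1, geometry.r2, geometry.theta
        rvals = np.concatenate([r1, r2])
        hist_r, _ = np.histogram(rvals, bins=self.r_edges)
        hist_th, _ = np.histogram(theta, bins=self.theta_edges)
        n_out = (len(rvals) - hist_r.sum()) + (len(theta) - hist_th.sum())
        if n_out:
            self._n_out += int(n_out)
            logger.warning("%d intramolecular values fell outside the grid",
                           n_out)
        self._hist_r += hist_r
        self._hist_th += hist_th
        self.n_frames += 1

    def finalize(self) -> DistributionSet:
        if self.n_frames == 0:
            raise ConfigurationError("no frames accumulated")
        V = self.cell.volume
        rdfs = {}
        shell = (4.0 * np.pi / 3.0) * np.diff(self.rdf_edges**3)
        for pair, (i, j) in self._pairs.items():
            n_pairs = len(i)
            if n_pairs == 0:                  # single molecule: no pairs
                g = np.zeros(len(shell))
            else:
                ideal = n_pairs * shell / V   # ideal-gas counts per frame
                g = self._hist[pair] / (self.n_frames * ideal)
            rdfs[pair] = RadialDistribution(
                pair=pair, edges=self.rdf_edges, g=g,
                n_frames=self.n_frames, n_pairs=n_pairs)
        intra = IntraDistributions(
            r_edges=self.r_edges,
            rho_r=_unit_integral(self._hist_r, self.r_edges),
            theta_edges=self.theta_edges,
            rho_theta=_unit_integral(self._hist_th, self.theta_edges),
            n_out_of_range=self._n_out)
        return DistributionSet(g_oo=rdfs["OO"], g_oh=rdfs["OH"],
                               g_hh=rdfs["HH"], intra=intra,
                               n_frames=self.n_frames,
                               temperature=self.temperature)


def _unit_integral(hist: np.ndarray, edges: np.ndarray) -> np.ndarray:
    total = hist.sum()
    if total == 0:
        return np.zeros_like(hist, dtype=float)
    return hist / (total * np.diff(edges))


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def accumulate_rdf(frames, pair: str, topo: SystemTopology,
                   cell: SimulationCell, r_max: float | None = None,
                   rdf_bin: float = RDF_BIN_A0,
                   temperature: float = 0.0) -> RadialDistribution:
    """Radial distribution function of one pair type from a frame stream."""
    acc = DistributionAccumulator(topo, cell, temperature, r_max=r_max,
                                  rdf_bin=rdf_bin)
    for frame in frames:
        acc.add_frame(frame)
    return acc.finalize().radial(pair)


def accumulate_intra(geometries, rho_r_range=RHO_R_RANGE_A0,
                     rho_r_bin: float = RHO_R_BIN_A0,
                     theta_range=RHO_THETA_RANGE_RAD,
                     theta_bin: float = RHO_THETA_BIN_RAD) -> IntraDistributions:
    """Intramolecular densities from a stream of QuasiCentroidGeometry."""
    r_edges = np.arange(rho_r_range[0], rho_r_range[1] + rho_r_bin / 2, rho_r_bin)
    th_edges = np.arange(theta_range[0], theta_range[1] + theta_bin / 2, theta_bin)
    hist_r = np.zeros(len(r_edges) - 1)
    hist_th = np.zeros(len(th_edges) - 1)
    n_out = 0
    n_geoms = 0
    for geom in geometries:
        rvals = np.concatenate([geom.r1, geom.r2])
        hr, _ = np.histogram(rvals, bins=r_edges)
        ht, _ = np.histogram(geom.theta, bins=th_edges)
        out = (len(rvals) - hr.sum()) + (len(geom.theta) - ht.sum())
        if out:
            n_out += int(out)
            logger.warning("%d intramolecular values outside the grid", out)
        hist_r += hr
        hist_th += ht
        n_geoms += 1
    if n_geoms == 0:
        raise ConfigurationError("empty geometry stream")
    return IntraDistributions(r_edges=r_edges,
                              rho_r=_unit_integral(hist_r, r_edges),
                              theta_edges=th_edges,
                              rho_theta=_unit_integral(hist_th, th_edges),
                              n_out_of_range=n_out)
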