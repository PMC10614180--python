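"""Quasi-centroid potential of mean force via regularized iterative Boltzmann
inversion.

The potential of mean force is represented as the classical potential plus a
separable intramolecular correction (polynomials in the bond displacement
and bend displacement, of the same degrees as the underlying model's stretch
and bend) and pairwise intermolecular corrections (smooth tabulated
functions of the O-O, O-H and H-H distances).

The corrections are fitted by iterating: run classical NVT on the current
corrected potential, histogram the trial distribution functions, and update

    dV_XY(r) <- dV_XY(r) + kT * ln[(g_trial + eps*G) / (g_target + eps*G)]

for the pair channels (G is the larger of the two peak heights; eps damps
noise-dominated regions) while the intramolecular polynomials are refit by
weighted least squares to kT * ln(rho_trial / rho_target) over the
well-sampled region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import savgol_filter

from . import units
from .distributions import DistributionAccumulator, DistributionSet, IntraDistributions
from .md_core import IntegratorSettings, TrajectoryRecord, run_md
from .quasicentroid import bond_geometries
from .water_model import (HAVE_NUMBA, Configuration, ConfigurationError,
                          ForceEnergy, SimulationCell, SystemTopology,
                          WaterModelParams, _pair_arrays, _scatter,
                          _scatter_matrix)

if HAVE_NUMBA:
    import math

    import numba

    @numba.njit(cache=True, fastmath=True)
    def _pair_table_kernel(pos, i_idx, j_idx, tab_of, L, per, x0s, hs,
                           coeffs, nints, r_inners, r_cuts, v_inners,
                           dv_inners):
        """Cubic-segment pair-table energy/forces over a fused pair list.

        All three channels are evaluated in one pass: ``tab_of[p]`` selects
        the table of pair p.  ``coeffs`` is (n_tables, 4, max_intervals):
        cubic spline coefficients on uniform grids starting at ``x0s`` with
        spacings ``hs``.  Below the inner edge a table continues with
        constant force; at and beyond its cutoff it is exactly zero.
        Returns (energy, forces, n_below_inner).
        """
        B = pos.shape[0]
        e = np.zeros(B)
        f = np.zeros_like(pos)
        n_below = 0
        for b in range(B):
            acc = 0.0
            for p in range(i_idx.shape[0]):
                tid = tab_of[p]
                i = i_idx[p]
                j = j_idx[p]
                dx = pos[b, j, 0] - pos[b, i, 0]
                dy = pos[b, j, 1] - pos[b, i, 1]
                dz = pos[b, j, 2] - pos[b, i, 2]
                if per[0]:
                    dx -= L[0] * round(dx / L[0])
                if per[1]:
                    dy -= L[1] * round(dy / L[1])
                if per[2]:
                    dz -= L[2] * round(dz / L[2])
                r2 = dx * dx + dy * dy + dz * dz
                rc = r_cuts[tid]
                if r2 >= rc * rc:
                    continue
                r = math.sqrt(r2)
                if r < r_inners[tid]:
                    n_below += 1
                    v = v_inners[tid] + dv_inners[tid] * (r - r_inners[tid])
                    dv = dv_inners[tid]
                else:
                    k = int((r - x0s[tid]) / hs[tid])
                    if k >= nints[tid]:
                        k = nints[tid] - 1
                    t = r - (x0s[tid] + k * hs[tid])
                    c0 = coeffs[tid, 0, k]
                    c1 = coeffs[tid, 1, k]
                    c2 = coeffs[tid, 2, k]
                    c3 = coeffs[tid, 3, k]
                    v = ((c0 * t + c1) * t + c2) * t + c3
                    dv = (3 * c0 * t + 2 * c1) * t + c2
                acc += v
                fmag = -dv / r
                f[b, j, 0] += fmag * dx
                f[b, j, 1] += fmag * dy
                f[b, j, 2] += fmag * dz
                f[b, i, 0] -= fmag * dx
                f[b, i, 1] -= fmag * dy
                f[b, i, 2] -= fmag * dz
            e[b] = acc
        return e, f, n_below

logger = logging.getLogger(__name__)

#: Fraction of the peak below which intramolecular bins are excluded from
#: the polynomial refit (only low-noise regions are used).
INTRA_MASK_FRACTION = 0.01

#: Threshold on the target g defining the inner edge of a pair table.
TABLE_INNER_THRESHOLD = 1e-4

#: Width (a0) of the quintic switch taking every pair table smoothly to zero
#: at its cutoff.
SWITCH_WIDTH_A0 = 1.0

#: Sup-norm threshold ("graphically indistinguishable") used both as the IBI
#: convergence criterion and in validation.
CONVERGENCE_SUP_NORM = 0.02


def _savgol(y: np.ndarray, window: int = 9, order: int = 3) -> np.ndarray:
    window = min(window, len(y) if len(y) % 2 == 1 else len(y) - 1)
    if window <= order:
        return y.copy()
    return savgol_filter(y, window, order)


def _quintic_switch(u: np.ndarray) -> np.ndarray:
    """C2 switch: 1 at u<=0, 0 at u>=1."""
    u = np.clip(u, 0.0, 1.0)
    return 1.0 - (10 * u**3 - 15 * u**4 + 6 * u**5)


# ---------------------------------------------------------------------------
# Correction potential representation
# ---------------------------------------------------------------------------

class PairTable:
    """Smooth tabulated pair correction dV_XY(r).

    Values live on a uniform grid; a cubic-spline interpolant provides
    energies and continuous forces.  The table is exactly zero at and beyond
    its cutoff (quintic switch over the last ``switch_width``) and is
    extended below the inner edge by linear-force (constant-force)
    extrapolation, counted but never raising mid-dynamics.
    """

    def __init__(self, pair: str, r_grid: np.ndarray, values: np.ndarray,
                 r_cut: float, switch_width: float = SWITCH_WIDTH_A0,
                 smooth_window: int = 9, presmoothed: bool = False):
        self.pair = pair
        self.r_grid = np.asarray(r_grid, float)
        self.r_cut = float(r_cut)
        self.switch_width = float(switch_width)
        raw = np.asarray(values, float)
        if not presmoothed:
            raw = _savgol(raw, smooth_window)
        # The quintic switch finishes two grid steps before the cutoff and
        # the remaining nodes are exactly zero, so the interpolant is
        # identically zero at the cutoff: pairs crossing r_cut during
        # dynamics see no force discontinuity at all.
        h = float(self.r_grid[1] - self.r_grid[0]) if len(self.r_grid) > 1 \
            else self.switch_width
        ramp = max(self.switch_width - 2 * h, h)
        u = (self.r_grid - (self.r_cut - self.switch_width)) / ramp
        self.values = raw * _quintic_switch(u)
        self.values[self.r_grid >= self.r_cut - 2 * h - 1e-12] = 0.0
        self._spline = CubicSpline(self.r_grid, self.values, bc_type="natural")
        self._dspline = self._spline.derivative()
        self.r_inner = float(self.r_grid[0])
        self._v_inner = float(self._spline(self.r_inner))
        self._dv_inner = float(self._dspline(self.r_inner))
        self.n_below_inner = 0
        # Uniform-grid fast path (cubic coefficients for direct lookup).
        steps = np.diff(self.r_grid)
        self._h = float(steps[0])
        self._uniform = bool(np.allclose(steps, self._h, rtol=1e-10))
        self._coeffs = np.ascontiguousarray(self._spline.c)

    def energy(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, float)
        below = r < self.r_inner
        n_below = int(np.count_nonzero(below))
        if n_below:
            self.n_below_inner += n_below
        inside = (~below) & (r < self.r_cut)
        out = np.zeros_like(r)
        out[inside] = self._spline(r[inside])
        out[below] = self._v_inner + self._dv_inner * (r[below] - self.r_inner)
        return out

    def dvdr(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, float)
        below = r < self.r_inner
        inside = (~below) & (r < self.r_cut)
        out = np.zeros_like(r)
        out[inside] = self._dspline(r[inside])
        out[below] = self._dv_inner
        return out

    def with_values(self, values: np.ndarray, presmoothed: bool = False
                    ) -> "PairTable":
        return PairTable(self.pair, self.r_grid, values, self.r_cut,
                         self.switch_width, presmoothed=presmoothed)


@dataclass
class CorrectionPotential:
    """dV_intra polynomial coefficients + tabulated pair corrections.

    ``c_r`` holds coefficients of (r - r_eq)^k for k = 1..4 (hartree/a0^k);
    ``c_theta`` of (theta - theta_eq)^k for k = 1..2.  ``tables`` maps pair
    labels to PairTable or None (zero correction).
    """

    r_eq: float
    theta_eq: float
    c_r: np.ndarray = field(default_factory=lambda: np.zeros(4))
    c_theta: np.ndarray = field(default_factory=lambda: np.zeros(2))
    tables: dict = field(default_factory=lambda: {"OO": None, "OH": None,
                                                  "HH": None})
    iteration: int = 0
    epsilon: float = 0.0
    #: Displacement windows over which the polynomials were fitted; outside,
    #: the correction continues linearly (constant force), since the
    #: polynomial is unconstrained by data there and a free quartic tail can
    #: destabilize the dynamics.  None means no windowing (raw polynomial).
    r_window: tuple | None = None
    theta_window: tuple | None = None

    @classmethod
    def zero(cls, params: WaterModelParams) -> "CorrectionPotential":
        return cls(r_eq=params.r_eq, theta_eq=params.theta_eq)

    @property
    def is_zero(self) -> bool:
        return (not np.any(self.c_r) and not np.any(self.c_theta)
                and all(t is None for t in self.tables.values()))

    # -- persistence -------------------------------------------------------

    def save(self, directory) -> None:
        """Plain-text tables: polynomial coefficients and (r, dV, dV') pairs."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        header = (f"# fqcmd correction potential v1\n"
                  f"# iteration {self.iteration} epsilon {self.epsilon}\n")
        lines = [header,
                 f"r_eq {float(self.r_eq)!r}\ntheta_eq {float(self.theta_eq)!r}\n",
                 "c_r " + " ".join(repr(float(c)) for c in self.c_r) + "\n",
                 "c_theta " + " ".join(repr(float(c)) for c in self.c_theta)
                 + "\n"]
        for name, win in (("r_window", self.r_window),
                          ("theta_window", self.theta_window)):
            if win is not None:
                lines.append(f"{name} {float(win[0])!r} {float(win[1])!r}\n")
        (directory / "intra.txt").write_text("".join(lines))
        for pair, table in self.tables.items():
            path = directory / f"pair_{pair}.txt"
            if table is None:
                path.write_text(header + "# zero correction\n")
                continue
            rows = "\n".join(
                f"{float(r)!r} {float(v)!r} {float(d)!r}" for r, v, d in
                zip(table.r_grid, table.values, table.dvdr(table.r_grid)))
            path.write_text(header + f"# r_cut {float(table.r_cut)!r}\n"
                            "# r[a0]  dV[hartree]  dV/dr[hartree/a0]\n"
                            + rows + "\n")

    @classmethod
    def load(cls, directory) -> "CorrectionPotential":
        directory = Path(directory)
        meta = {}
        iteration, epsilon = 0, 0.0
        for line in (directory / "intra.txt").read_text().splitlines():
            if line.startswith("# iteration"):
                parts = line.split()
                iteration, epsilon = int(parts[2]), float(parts[4])
            if line.startswith("#") or not line.strip():
                continue
            key, *vals = line.split()
            meta[key] = np.array([float(v) for v in vals])
        tables = {}
        for pair in ("OO", "OH", "HH"):
            text = (directory / f"pair_{pair}.txt").read_text()
            if "zero correction" in text:
                tables[pair] = None
                continue
            r_cut = None
            rows = []
            for line in text.splitlines():
                if line.startswith("# r_cut"):
                    r_cut = float(line.split()[2])
                if line.startswith("#") or not line.strip():
                    continue
                rows.append([float(x) for x in line.split()])
            data = np.array(rows)
            tables[pair] = PairTable(pair, data[:, 0], data[:, 1], r_cut,
                                     presmoothed=True)
        return cls(r_eq=float(meta["r_eq"][0]), theta_eq=float(meta["theta_eq"][0]),
                   c_r=meta["c_r"], c_theta=meta["c_theta"], tables=tables,
                   iteration=iteration, epsilon=epsilon,
                   r_window=tuple(meta["r_window"]) if "r_window" in meta else None,
                   theta_window=(tuple(meta["theta_window"])
                                 if "theta_window" in meta else None))


class _CorrectionPairLists:
    """Atom-pair index arrays for the three intermolecular channels."""

    def __init__(self, topo: SystemTopology):
        n = topo.n_molecules
        mol_of = np.repeat(np.arange(n), 3)
        species = np.tile([0, 1, 1], n)
        i, j = _pair_arrays(topo.n_atoms, mol_of)
        si, sj = species[i], species[j]
        self.pairs = {}
        self.scatter = {}
        for label, mask in (("OO", (si == 0) & (sj == 0)),
                            ("OH", si != sj),
                            ("HH", (si == 1) & (sj == 1))):
            self.pairs[label] = (i[mask], j[mask])
            self.scatter[label] = _scatter_matrix(topo.n_atoms, i[mask], j[mask])


def _poly_eval(coeffs: np.ndarray, x: np.ndarray, window: tuple | None = None):
    """Value and derivative of sum_k c_k x^k (k starting at 1).

    With a ``window = (lo, hi)`` the polynomial is continued linearly
    (constant force, C1) outside [lo, hi].
    """
    if window is not None:
        xc = np.clip(x, window[0], window[1])
        v, d = _poly_eval(coeffs, xc)
        return v + d * (x - xc), d
    v = np.zeros_like(x)
    d = np.zeros_like(x)
    for k, c in enumerate(coeffs, start=1):
        v += c * x**k
        d += k * c * x**(k - 1)
    return v, d


def correction_energy_forces(correction: CorrectionPotential,
                             positions: np.ndarray, topo: SystemTopology,
                             cell: SimulationCell,
                             pair_lists: _CorrectionPairLists | None = None):
    """Batched energy/forces of the correction terms, (..., natoms, 3) input."""
    pos = np.asarray(positions, float)
    energy = np.zeros(pos.shape[:-2])
    forces = np.zeros_like(pos)

    # Intramolecular polynomials (same geometry machinery as the model).
    if np.any(correction.c_r) or np.any(correction.c_theta):
        o = pos[..., 0::3, :]
        b1 = cell.minimum_image(pos[..., 1::3, :] - o)
        b2 = cell.minimum_image(pos[..., 2::3, :] - o)
        r1 = np.linalg.norm(b1, axis=-1)
        r2 = np.linalg.norm(b2, axis=-1)
        u1 = b1 / r1[..., None]
        u2 = b2 / r2[..., None]
        v1, d1 = _poly_eval(correction.c_r, r1 - correction.r_eq,
                            correction.r_window)
        v2, d2 = _poly_eval(correction.c_r, r2 - correction.r_eq,
                            correction.r_window)
        c = np.clip(np.sum(u1 * u2, axis=-1), -1.0, 1.0)
        theta = np.arccos(c)
        vth, dth = _poly_eval(correction.c_theta, theta - correction.theta_eq,
                              correction.theta_window)
        energy = energy + np.sum(v1 + v2 + vth, axis=-1)
        f1 = -d1[..., None] * u1
        f2 = -d2[..., None] * u2
        s = np.sqrt(np.maximum(1.0 - c**2, 1e-24))
        g1 = (c[..., None] * u1 - u2) / (r1 * s)[..., None]
        g2 = (c[..., None] * u2 - u1) / (r2 * s)[..., None]
        f1 = f1 - dth[..., None] * g1
        f2 = f2 - dth[..., None] * g2
        forces[..., 1::3, :] += f1
        forces[..., 2::3, :] += f2
        forces[..., 0::3, :] -= f1 + f2

    # Pairwise intermolecular tables.
    active = {p: t for p, t in correction.tables.items() if t is not None}
    if active:
        if pair_lists is None:
            pair_lists = _CorrectionPairLists(topo)
        if HAVE_NUMBA and all(t._uniform for t in active.values()):
            fused = _fused_table_arrays(active, pair_lists)
            lead = pos.shape[:-2]
            flat = np.ascontiguousarray(pos.reshape((-1,) + pos.shape[-2:]))
            e_t, f_t, n_below = _pair_table_kernel(
                flat, fused["i"], fused["j"], fused["tab_of"],
                cell.edges, cell.periodic, fused["x0"], fused["h"],
                fused["coeffs"], fused["nint"], fused["r_inner"],
                fused["r_cut"], fused["v_inner"], fused["dv_inner"])
            if n_below:
                next(iter(active.values())).n_below_inner += int(n_below)
            energy = energy + e_t.reshape(lead)
            forces += f_t.reshape(pos.shape)
        else:
            for pair, table in active.items():
                i, j = pair_lists.pairs[pair]
                d = cell.minimum_image(pos[..., j, :] - pos[..., i, :])
                r = np.linalg.norm(d, axis=-1)
                energy = energy + np.sum(table.energy(r), axis=-1)
                fpair = -(table.dvdr(r))[..., None] * d / r[..., None]
                forces += _scatter(pair_lists.scatter[pair], fpair)
    return energy, forces


def _fused_table_arrays(active: dict, pair_lists) -> dict:
    """Concatenated pair lists + padded coefficient arrays for the fused
    table kernel; cached on the pair-list object keyed by table identity."""
    key = tuple(sorted((p, id(t)) for p, t in active.items()))
    cached = getattr(pair_lists, "_fused_cache", None)
    if cached is not None and cached[0] == key:
        return cached[1]
    names = sorted(active)
    i_all, j_all, tab_of = [], [], []
    for tid, name in enumerate(names):
        i, j = pair_lists.pairs[name]
        i_all.append(i)
        j_all.append(j)
        tab_of.append(np.full(len(i), tid, dtype=np.int64))
    tables = [active[n] for n in names]
    max_int = max(t._coeffs.shape[1] for t in tables)
    coeffs = np.zeros((len(tables), 4, max_int))
    for tid, t in enumerate(tables):
        coeffs[tid, :, :t._coeffs.shape[1]] = t._coeffs
    fused = {
        "i": np.concatenate(i_all), "j": np.concatenate(j_all),
        "tab_of": np.concatenate(tab_of),
        "x0": np.array([t.r_inner for t in tables]),
        "h": np.array([t._h for t in tables]),
        "coeffs": coeffs,
        "nint": np.array([t._coeffs.shape[1] for t in tables]),
        "r_inner": np.array([t.r_inner for t in tables]),
        "r_cut": np.array([t.r_cut for t in tables]),
        "v_inner": np.array([t._v_inner for t in tables]),
        "dv_inner": np.array([t._dv_inner for t in tables]),
    }
    pair_lists._fused_cache = (key, fused)
    return fused


def evaluate_correction(correction: CorrectionPotential, config: Configuration,
                        topo: SystemTopology, cell: SimulationCell
                        ) -> ForceEnergy:
    """Correction energy and exact analytic forces for one configuration."""
    e, f = correction_energy_forces(correction, config.positions, topo, cell)
    return ForceEnergy(energy=float(e), forces=f)


class CorrectedPotential:
    """V_cl + dV_intra + dV_inter with the batched force/energy interface."""

    def __init__(self, base, correction: CorrectionPotential):
        self.base = base
        self.correction = correction
        self._pair_lists = _CorrectionPairLists(base.topo)

    @property
    def masses(self):
        return self.base.masses

    @property
    def topo(self):
        return self.base.topo

    @property
    def cell(self):
        return self.base.cell

    def force_energy(self, positions):
        e, f = self.base.force_energy(positions)
        if self.correction.is_zero:
            return e, f
        ec, fc = correction_energy_forces(self.correction, positions,
                                          self.base.topo, self.base.cell,
                                          self._pair_lists)
        return e + ec, f + fc


# ---------------------------------------------------------------------------
# Updates
# ---------------------------------------------------------------------------

def regularization_scale(g_trial: np.ndarray, g_target: np.ndarray) -> float:
    """G_XY: the larger of the maximum peak heights of the two RDFs."""
    G = max(float(np.max(g_trial)), float(np.max(g_target)))
    if G <= 0:
        raise ConfigurationError("both distributions identically zero")
    return G


def inter_update_regularized(g_trial: np.ndarray, g_target: np.ndarray,
                             epsilon: float, temperature: float) -> np.ndarray:
    """Pointwise regularized pair update kT ln[(g_i + eG)/(g_exact + eG)].

    With ``epsilon = 0`` any bin where both distributions vanish is 0/0 and
    raises; regularized updates are exactly zero there.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    g_trial = np.asarray(g_trial, float)
    g_target = np.asarray(g_target, float)
    kT = units.KB_HARTREE * temperature
    G = regularization_scale(g_trial, g_target)
    num = g_trial + epsilon * G
    den = g_target + epsilon * G
    if epsilon == 0 and np.any((num == 0) & (den == 0)):
        raise ConfigurationError(
            "0/0 in unregularized update; use epsilon > 0")
    out = np.zeros_like(num)
    both = (num > 0) & (den > 0)
    out[both] = kT * np.log(num[both] / den[both])
    # One-sided zeros with epsilon = 0: clamp to the largest finite update.
    only_num = (num == 0) & (den > 0)
    only_den = (den == 0) & (num > 0)
    if np.any(only_num) or np.any(only_den):
        big = kT * np.log(1e6)
        out[only_num] = -big
        out[only_den] = big
    return out


class _PolyFitBasis:
    """Weighted polynomial fitting over masked bins in a standardized
    coordinate u = (x - mean)/scale (mean and scale from the weights)."""

    def __init__(self, x: np.ndarray, weight: np.ndarray, mask: np.ndarray,
                 degree: int):
        n_used = int(np.count_nonzero(mask))
        if n_used < degree + 1:
            raise ConfigurationError(
                f"only {n_used} usable bins for a degree-{degree} refit")
        self.mask = mask
        self.degree = degree
        xm = x[mask]
        w = weight[mask] / weight[mask].sum()
        self.mean = float(np.sum(w * xm))
        scale = float(np.sqrt(np.sum(w * (xm - self.mean) ** 2)))
        self.scale = scale if scale > 0 else 1.0
        self.u = (xm - self.mean) / self.scale
        self.A = np.vander(self.u, degree + 1, increasing=True)
        self.sw = np.sqrt(w)

    def fit(self, y_masked: np.ndarray,
            columns: np.ndarray | None = None) -> np.ndarray:
        """Weighted LSQ coefficients in u-monomials (restricted columns
        optional; excluded columns return coefficient 0)."""
        cols = np.ones(self.degree + 1, bool) if columns is None else columns
        Aw = self.A[:, cols] * self.sw[:, None]
        coef, *_ = np.linalg.lstsq(Aw, y_masked * self.sw, rcond=None)
        out = np.zeros(self.degree + 1)
        out[cols] = coef
        return out

    def residual_sigma(self, y_masked: np.ndarray, cu: np.ndarray) -> float:
        resid = (y_masked - self.A @ cu) * self.sw
        dof = max(len(self.u) - (self.degree + 1), 1)
        return float(np.sqrt(np.sum(resid**2) / dof)
                     / np.sqrt(np.mean(self.sw**2)))

    def to_x_powers(self, cu: np.ndarray) -> np.ndarray:
        """Map u-monomial coefficients to x-monomials, dropping the constant
        (an arbitrary free-energy offset)."""
        pu = np.polynomial.Polynomial(cu)
        px = pu(np.polynomial.Polynomial([-self.mean / self.scale,
                                          1.0 / self.scale]))
        coef = np.zeros(self.degree + 1)
        coef[:len(px.coef)] = px.coef
        return coef[1:]


def masked_poly_refit(update: np.ndarray, x: np.ndarray, weight: np.ndarray,
                      mask: np.ndarray, degree: int,
                      threshold_sigma: float = 3.0,
                      block_updates: list | None = None,
                      always_keep: tuple = (1, 2)) -> np.ndarray:
    """Noise-thresholded weighted polynomial fit of ``update`` over masked bins.

    Bins outside ``mask`` carry exactly zero weight.  Components that are
    not statistically significant are zeroed and the remaining powers are
    refit: over the narrow sampled window the monomials are nearly
    collinear, so unconstrained coefficients acquire large mutually
    canceling values driven purely by sampling noise and random-walk from
    iteration to iteration (with disastrous effects on the curvature of the
    corrected potential).

    The low powers in ``always_keep`` (by default linear and quadratic,
    which track the well-determined mean and width of the distribution)
    are always fit.  Higher powers are judged per u-monomial component
    against their standard errors.  When ``block_updates`` (the same
    update evaluated on independent time blocks of the trajectory) is
    provided, the standard errors come from the block-to-block scatter —
    the honest estimate when sampling noise is time-correlated and
    therefore *smooth* across bins, which a residual-based estimate badly
    underestimates.  Without blocks, the weighted-residual noise level is
    used as a fallback.

    Returns coefficients for powers 1..degree of x.
    """
    basis = _PolyFitBasis(x, weight, mask, degree)
    y = update[mask]
    c_full = basis.fit(y)
    if block_updates:
        blocks = np.array([basis.fit(b[mask]) for b in block_updates])
        se = blocks.std(axis=0, ddof=1) / np.sqrt(len(block_updates))
    else:
        sigma = basis.residual_sigma(y, c_full)
        # Diagonal of the LSQ covariance in u-monomial space.
        cov = np.linalg.inv(basis.A.T @ (basis.sw[:, None]**2 * basis.A))
        se = sigma * np.sqrt(np.diag(cov) * np.mean(basis.sw**2))
    keep = np.abs(c_full) > threshold_sigma * se
    keep[0] = True                     # constant: always fit, always dropped
    for k in always_keep:
        if k <= degree:
            keep[k] = True
    c_kept = basis.fit(y, columns=keep)
    return basis.to_x_powers(c_kept)


def _block_densities(samples: np.ndarray, edges: np.ndarray,
                     n_blocks: int) -> list:
    """Unit-integral densities of ``n_blocks`` contiguous frame blocks.

    ``samples`` is (n_frames, m); empty bins get half a count so block
    log-ratios stay finite (such bins carry negligible fit weight anyway).
    """
    out = []
    frames = np.array_split(np.arange(samples.shape[0]), n_blocks)
    width = np.diff(edges)
    for idx in frames:
        hist, _ = np.histogram(samples[idx].ravel(), bins=edges)
        hist = np.maximum(hist.astype(float), 0.5)
        out.append(hist / (hist.sum() * width))
    return out


def intra_update_refit(correction: CorrectionPotential,
                       trial: IntraDistributions, target: IntraDistributions,
                       temperature: float, trial_samples: dict | None = None,
                       n_blocks: int = 6) -> CorrectionPotential:
    """Refit dV_r and dV_theta polynomials from the intramolecular update.

    The pointwise update kT ln(rho_trial/rho_target) is evaluated on bins
    where both densities exceed 1% of their maxima (low statistical noise),
    fit by target-density-weighted least squares with per-component
    significance thresholding, and added to the current coefficients.
    ``trial_samples`` (raw per-frame bond lengths under "r" and angles
    under "theta") enables block-scatter standard errors for the
    thresholding.
    """
    kT = units.KB_HARTREE * temperature
    new = CorrectionPotential(r_eq=correction.r_eq, theta_eq=correction.theta_eq,
                              c_r=correction.c_r.copy(),
                              c_theta=correction.c_theta.copy(),
                              tables=dict(correction.tables),
                              iteration=correction.iteration,
                              epsilon=correction.epsilon,
                              r_window=correction.r_window,
                              theta_window=correction.theta_window)
    for kind in ("r", "theta"):
        if kind == "r":
            rho_t, rho_x = trial.rho_r, target.rho_r
            x = trial.r_centers - correction.r_eq
            edges = trial.r_edges
            offset = correction.r_eq
            degree = len(correction.c_r)
        else:
            rho_t, rho_x = trial.rho_theta, target.rho_theta
            x = trial.theta_centers - correction.theta_eq
            edges = trial.theta_edges
            offset = correction.theta_eq
            degree = len(correction.c_theta)
        block_updates = None
        if trial_samples is not None and kind in trial_samples:
            # Recompute the trial density from the full per-step samples so
            # the update, mask and block errors share one estimator.
            samples = np.asarray(trial_samples[kind]) - offset
            hist, _ = np.histogram(samples.ravel(), bins=edges - offset)
            total = max(hist.sum(), 1)
            rho_t = hist / (total * np.diff(edges))
        mask = ((rho_t > INTRA_MASK_FRACTION * rho_t.max())
                & (rho_x > INTRA_MASK_FRACTION * rho_x.max()))
        update = np.zeros_like(rho_t)
        update[mask] = kT * np.log(rho_t[mask] / rho_x[mask])
        if trial_samples is not None and kind in trial_samples:
            block_updates = []
            for rho_b in _block_densities(samples, edges - offset, n_blocks):
                yb = np.zeros_like(update)
                yb[mask] = kT * np.log(rho_b[mask] / rho_x[mask])
                block_updates.append(yb)
        delta = masked_poly_refit(update, x, rho_x, mask, degree,
                                  block_updates=block_updates)
        window = (float(x[mask].min()), float(x[mask].max()))
        if kind == "r":
            new.c_r = new.c_r + delta
            new.r_window = window
        else:
            new.c_theta = new.c_theta + delta
            new.theta_window = window
    return new


# ---------------------------------------------------------------------------
# The full iteration
# ---------------------------------------------------------------------------

def distribution_metric(trial: DistributionSet, target: DistributionSet) -> dict:
    """Per-channel sup-norm differences; RDF differences are lightly smoothed
    (the comparison mirrors overlaid plotted curves), intramolecular
    densities are compared after peak normalization."""
    out = {}
    for pair in ("OO", "OH", "HH"):
        diff = trial.radial(pair).g - target.radial(pair).g
        out[f"g_{pair}"] = float(np.max(np.abs(_savgol(diff))))
    for name, (t, x) in {
            "rho_r": (trial.intra.rho_r, target.intra.rho_r),
            "rho_theta": (trial.intra.rho_theta, target.intra.rho_theta)}.items():
        scale = max(x.max(), 1e-300)
        out[name] = float(np.max(np.abs(_savgol(t - x))) / scale)
    out["total"] = max(v for k, v in out.items())
    return out


def average_corrections(corrections: list) -> CorrectionPotential:
    """Average a list of CorrectionPotential objects (tail averaging).

    Near its fixed point the IBI iteration is a mean-reverting stochastic
    process: each iteration's correction carries fresh trial-sampling noise
    of roughly stationary magnitude.  Averaging the last few iterations'
    corrections reduces that noise without biasing the fixed point.  Tables
    are averaged on the first correction's grid; polynomial windows use the
    widest span.
    """
    if not corrections:
        raise ConfigurationError("nothing to average")
    first = corrections[-1]
    c_r = np.mean([c.c_r for c in corrections], axis=0)
    c_theta = np.mean([c.c_theta for c in corrections], axis=0)
    windows = {}
    for name in ("r_window", "theta_window"):
        spans = [getattr(c, name) for c in corrections
                 if getattr(c, name) is not None]
        windows[name] = ((min(s[0] for s in spans), max(s[1] for s in spans))
                         if spans else None)
    tables = {}
    for pair, ref in first.tables.items():
        live = [c.tables[pair] for c in corrections
                if c.tables.get(pair) is not None]
        if not live:
            tables[pair] = None
            continue
        grid = live[-1].r_grid
        vals = np.mean([t.energy(grid) for t in live], axis=0)
        tables[pair] = PairTable(pair, grid, vals, live[-1].r_cut,
                                 live[-1].switch_width, presmoothed=True)
    return CorrectionPotential(
        r_eq=first.r_eq, theta_eq=first.theta_eq, c_r=c_r, c_theta=c_theta,
        tables=tables, iteration=first.iteration, epsilon=first.epsilon,
        r_window=windows["r_window"], theta_window=windows["theta_window"])


@dataclass
class IBIState:
    """Fixed target, current corrections, latest trial, convergence history."""

    target: DistributionSet
    correction: CorrectionPotential
    trial: DistributionSet | None = None
    history: list = field(default_factory=list)   # append-only metric dicts
    corrections: list = field(default_factory=list)
    config: Configuration | None = None           # last MD configuration


def _table_grid(target_rdf, r_cut: float):
    """Uniform table grid from the first populated RDF bin to >= r_cut."""
    centers = target_rdf.centers
    above = np.nonzero(target_rdf.g > TABLE_INNER_THRESHOLD)[0]
    if len(above) == 0:
        raise ConfigurationError(f"target g_{target_rdf.pair} is empty")
    grid = centers[above[0]:]
    h = grid[1] - grid[0]
    while grid[-1] < r_cut:
        grid = np.append(grid, grid[-1] + h)
    return grid


def run_ibi(target: DistributionSet, base_potential, initial: Configuration,
            n_iterations: int, epsilon: float, temperature: float,
            md_steps: int, equil_steps: int, stride: int = 5,
            seed: int = 0, dt_fs: float = 0.25, tau_fs: float = 100.0,
            callback=None, start_state: IBIState | None = None) -> IBIState:
    """Fit the correction potential by regularized IBI.

    Each iteration runs classical NVT on the current corrected potential
    (``equil_steps`` discarded, ``md_steps`` sampled every ``stride``),
    accumulates trial distributions on the target's grids, refits the
    intramolecular polynomials and applies the regularized pair updates.
    Aborts, recommending a larger epsilon, if the convergence metric grows
    for five consecutive iterations.
    """
    topo = base_potential.topo
    cell = base_potential.cell
    params = base_potential.params
    r_cut = float(target.g_oo.edges[-1])

    if start_state is None:
        correction = CorrectionPotential.zero(params)
        correction.epsilon = epsilon
        state = IBIState(target=target, correction=correction)
        start_iter = 0
    else:
        state = start_state
        start_iter = state.correction.iteration

    config = (state.config or initial).copy()
    grow = 0
    for it in range(start_iter + 1, n_iterations + 1):
        rng = np.random.default_rng(np.random.SeedSequence([seed, it]))
        settings = IntegratorSettings(dt_fs=dt_fs, thermostat="langevin",
                                      tau_fs=tau_fs, temperature=temperature,
                                      seed=seed)
        pot = CorrectedPotential(base_potential, state.correction)
        rec = run_md(config, pot, settings, equil_steps, stride=equil_steps,
                     rng=rng)
        config = rec.final
        acc = DistributionAccumulator(
            topo, cell, temperature,
            r_max=r_cut, rdf_bin=float(np.diff(target.g_oo.edges[:2])[0]),
            rho_r_range=(target.intra.r_edges[0], target.intra.r_edges[-1]),
            rho_r_bin=float(np.diff(target.intra.r_edges[:2])[0]),
            theta_range=(target.intra.theta_edges[0],
                         target.intra.theta_edges[-1]),
            theta_bin=float(np.diff(target.intra.theta_edges[:2])[0]))
        # Intramolecular geometry is cheap to record, so it is sampled
        # every step; the RDF histograms (the expensive part) keep the
        # coarser stride.
        r_samples, th_samples = [], []
        counter = {"n": 0}

        def sample_hook(x, v):
            counter["n"] += 1
            if counter["n"] % stride == 0:
                acc.add_frame(x)
            # MD never wraps coordinates, so molecules stay contiguous and
            # the geometry needs no minimum imaging here.
            r1, r2, th = bond_geometries(x[None])
            r_samples.append(np.concatenate([r1[0], r2[0]]))
            th_samples.append(th[0])
            return 0.0

        rec = run_md(config, pot, settings, md_steps, stride=1,
                     hooks={"_": sample_hook}, rng=rng)
        config = rec.final
        trial = acc.finalize()
        trial_samples = {"r": np.array(r_samples), "theta": np.array(th_samples)}

        metric = distribution_metric(trial, target)
        metric["iteration"] = it
        state.history.append(metric)
        state.trial = trial
        state.config = config
        grow = grow + 1 if (len(state.history) > 1 and metric["total"]
                            > state.history[-2]["total"]) else 0
        if grow >= 5:
            raise RuntimeError(
                "IBI metric diverged for 5 consecutive iterations; "
                "increase the regularization parameter epsilon")

        # Intramolecular polynomial refit.
        new_corr = intra_update_refit(state.correction, trial.intra,
                                      target.intra, temperature,
                                      trial_samples=trial_samples)
        # Regularized pair updates.
        tables = {}
        for pair in ("OO", "OH", "HH"):
            t_rdf = trial.radial(pair)
            x_rdf = target.radial(pair)
            if x_rdf.n_pairs == 0 or not np.any(
                    x_rdf.g > TABLE_INNER_THRESHOLD):
                tables[pair] = None       # no intermolecular pairs (monomer)
                continue
            grid = _table_grid(x_rdf, r_cut)
            update = inter_update_regularized(t_rdf.g, x_rdf.g, epsilon,
                                              temperature)
            centers = x_rdf.centers
            upd_on_grid = np.interp(grid, centers, update)
            old = state.correction.tables[pair]
            base_vals = old.energy(grid) if old is not None else np.zeros_like(grid)
            tables[pair] = PairTable(pair, grid, base_vals + upd_on_grid, r_cut)
        new_corr.tables = tables
        new_corr.iteration = it
        new_corr.epsilon = epsilon
        state.correction = new_corr
        state.corrections.append(new_corr)
        if callback is not None:
            callback(state)
    return state
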