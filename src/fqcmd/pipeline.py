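"""End-to-end orchestration of the three stages:

(i) PIMD sampling of the quasi-centroid distribution functions,
(ii) regularized IBI fit of the correction potential, and
(iii) classical spectra on the corrected potential, side by side with the
plain classical reference.

Stages communicate through files in the output directory; each stage writes
a manifest (config hash, seed, input checksums, package version) so a rerun
with the same configuration is reproducible and verifiable.
"""

from __future__ import annotations

import configparser
import hashlib
import io as _io
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io, units
from .distributions import DistributionAccumulator
from .fixtures import StructureSpec, build_ice_cell, build_liquid_box, build_monomer
from .ibi import CorrectedPotential, CorrectionPotential, run_ibi
from .md_core import IntegratorSettings, run_md
from .pimd import initialize_ring_polymer, run_pimd, sample_quasicentroid_ensemble
from .spectra import AbsorptionSpectrum, find_band_peak, spectrum_from_segments
from .water_model import (Configuration, ConfigurationError, WaterModelParams,
                          WaterPotential, dipole_derivative)

logger = logging.getLogger(__name__)

STAGES = ("pimd-targets", "ibi-fit", "spectra")

_DEFAULTS = {
    "structure": {"phase": "liquid", "n_molecules": "216",
                  "temperature": "300", "cell_edges": ""},
    "model": {"params": "default", "coulomb": "dsf"},
    "md": {"dt_fs": "0.25", "tau_fs": "100"},
    "pimd": {"n_beads": "32", "classical_equil_fs": "20000",
             "equil_fs": "1000", "sample_fs": "4000", "stride": "5"},
    "ibi": {"n_iterations": "30", "epsilon": "1.0", "equil_fs": "250",
            "sample_fs": "2000", "stride": "5", "tail_average": "1"},
    "spectra": {"n_segments": "4", "segment_fs": "5000", "gap_fs": "500",
                "equil_fs": "2000", "window_tau_fs": "600",
                "bands": "libration:300-1000,bend:1300-1900,stretch:3000-4000"},
    "output": {"directory": "fqcmd_out"},
    "seed": {"master": "1"},
}


@dataclass
class PipelineConfig:
    """Flat key-value configuration, one block per stage."""

    sections: dict

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        parser = configparser.ConfigParser()
        parser.read_dict(_DEFAULTS)
        parser.read(path)
        return cls({s: dict(parser[s]) for s in parser.sections()})

    @classmethod
    def from_dict(cls, overrides: dict) -> "PipelineConfig":
        parser = configparser.ConfigParser()
        parser.read_dict(_DEFAULTS)
        parser.read_dict(overrides)
        return cls({s: dict(parser[s]) for s in parser.sections()})

    def get(self, section: str, key: str) -> str:
        return self.sections[section][key]

    def getfloat(self, section: str, key: str) -> float:
        return float(self.get(section, key))

    def getint(self, section: str, key: str) -> int:
        return int(self.get(section, key))

    def to_text(self) -> str:
        parser = configparser.ConfigParser()
        parser.read_dict(self.sections)
        buf = _io.StringIO()
        parser.write(buf)
        return buf.getvalue()

    @property
    def hash(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:16]

    @property
    def seed(self) -> int:
        return self.getint("seed", "master")

    @property
    def outdir(self) -> Path:
        return Path(self.get("output", "directory"))

    # -- derived objects ---------------------------------------------------

    def model_params(self) -> WaterModelParams:
        spec = self.get("model", "params")
        if spec == "default":
            return WaterModelParams.default()
        return WaterModelParams.from_file(spec)

    def structure_spec(self) -> StructureSpec:
        edges = self.get("structure", "cell_edges").strip()
        return StructureSpec(
            phase=self.get("structure", "phase"),
            n_molecules=self.getint("structure", "n_molecules"),
            cell_edges=tuple(float(x) for x in edges.split(",")) if edges else None,
            temperature=self.getfloat("structure", "temperature"),
            seed=self.seed)

    def build_structure(self, params: WaterModelParams):
        spec = self.structure_spec()
        if spec.phase == "liquid":
            return build_liquid_box(spec, params)
        if spec.phase == "iceIh":
            return build_ice_cell(spec, params)
        if spec.phase == "monomer":
            return build_monomer(params, spec.temperature, spec.seed)
        raise ConfigurationError(f"unknown phase {spec.phase!r}")

    def base_potential(self, topo, cell, params) -> WaterPotential:
        coulomb = self.get("model", "coulomb")
        if not cell.periodic.any():
            coulomb = "bare"            # gas-phase molecules and clusters
        return WaterPotential(topo, cell, params, coulomb=coulomb)

    def integrator(self, thermostat: str, seed: int) -> IntegratorSettings:
        return IntegratorSettings(
            dt_fs=self.getfloat("md", "dt_fs"), thermostat=thermostat,
            tau_fs=self.getfloat("md", "tau_fs"),
            temperature=self.getfloat("structure", "temperature"), seed=seed)

    def bands(self) -> dict:
        out = {}
        for item in self.get("spectra", "bands").split(","):
            name, _, rng = item.strip().partition(":")
            lo, _, hi = rng.partition("-")
            out[name] = (float(lo), float(hi))
        return out


def _steps(config: PipelineConfig, section: str, key: str) -> int:
    return int(round(config.getfloat(section, key)
                     / config.getfloat("md", "dt_fs")))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_manifest(stage_dir: Path, config: PipelineConfig, stage: str,
                    inputs: list, outputs: list) -> Path:
    manifest = {
        "stage": stage,
        "config_hash": config.hash,
        "seed": config.seed,
        "version": __version__,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
        "outputs": sorted(str(p) for p in outputs),
    }
    path = stage_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _rng_for(config: PipelineConfig, *stream) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, *stream]))


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _stage_pimd_targets(config: PipelineConfig, stage_dir: Path) -> list:
    params = config.model_params()
    cfg, topo, cell = config.build_structure(params)
    temperature = config.getfloat("structure", "temperature")
    beta = units.beta_from_temperature(temperature)
    pot = config.base_potential(topo, cell, params)

    # Classical pre-equilibration.
    rng = _rng_for(config, 0)
    settings = config.integrator("langevin", config.seed)
    n_eq = _steps(config, "pimd", "classical_equil_fs")
    if n_eq:
        rec = run_md(cfg, pot, settings, n_eq, stride=n_eq, rng=rng)
        cfg = rec.final

    P = config.getint("pimd", "n_beads")
    state = initialize_ring_polymer(cfg, P, beta, topo.masses, rng, spread=0.05)
    state = run_pimd(state, pot, settings, _steps(config, "pimd", "equil_fs"),
                     rng=rng)
    acc = DistributionAccumulator(topo, cell, temperature)
    state, targets = sample_quasicentroid_ensemble(
        state, pot, settings, topo, cell,
        n_steps=_steps(config, "pimd", "sample_fs"),
        stride=config.getint("pimd", "stride"),
        temperature=temperature, accumulator=acc, rng=rng)

    targets_h5 = stage_dir / "targets.h5"
    io.save_distribution_set(targets_h5, targets)
    targets.to_csv(stage_dir / "targets_csv")
    rp_h5 = stage_dir / "ring_polymer.h5"
    io.save_ring_polymer(rp_h5, state, cell)
    io.write_extxyz(stage_dir / "structure.xyz", cfg.positions, cell,
                    {"stage": "pimd-targets", "seed": config.seed})
    return [targets_h5, rp_h5, stage_dir / "structure.xyz"]


def _stage_ibi_fit(config: PipelineConfig, stage_dir: Path, resume: bool,
                   stop_after: int | None = None) -> list:
    params = config.model_params()
    cfg, topo, cell = config.build_structure(params)
    pot = config.base_potential(topo, cell, params)
    targets_h5 = config.outdir / "pimd-targets" / "targets.h5"
    if not targets_h5.exists():
        raise ConfigurationError(
            "missing PIMD targets; run stage 'pimd-targets' first")
    target = io.load_distribution_set(targets_h5)

    ckpt = stage_dir / "checkpoint.h5"
    tables_dir = stage_dir / "correction"
    start_state = None
    if resume and ckpt.exists():
        start_state = io.load_ibi_checkpoint(ckpt, tables_dir, target)
        logger.info("resuming IBI from iteration %d",
                    start_state.correction.iteration)

    n_iter = config.getint("ibi", "n_iterations")
    if stop_after is not None:
        n_iter = min(n_iter, stop_after)

    def checkpoint(state):
        io.save_ibi_checkpoint(ckpt, state, tables_dir)

    state = run_ibi(
        target, pot, cfg,
        n_iterations=n_iter,
        epsilon=config.getfloat("ibi", "epsilon"),
        temperature=config.getfloat("structure", "temperature"),
        md_steps=_steps(config, "ibi", "sample_fs"),
        equil_steps=_steps(config, "ibi", "equil_fs"),
        stride=config.getint("ibi", "stride"),
        seed=config.seed, dt_fs=config.getfloat("md", "dt_fs"),
        tau_fs=config.getfloat("md", "tau_fs"),
        callback=checkpoint, start_state=start_state)

    tail = config.getint("ibi", "tail_average")
    if tail > 1 and len(state.corrections) >= 2:
        from .ibi import average_corrections
        state.correction = average_corrections(state.corrections[-tail:])
        state.correction.save(tables_dir)

    pd.DataFrame(state.history).to_csv(stage_dir / "convergence.csv",
                                       index=False)
    outputs = [ckpt, stage_dir / "convergence.csv"]
    outputs += sorted(tables_dir.glob("*.txt"))
    return outputs


def dipole_spectrum(base_potential, params, config: Configuration,
                    temperature: float, dt_fs: float, tau_fs: float,
                    n_segments: int, segment_fs: float, gap_fs: float,
                    equil_fs: float, window_tau_fs: float, seed: int,
                    thermostat_tau_fs: float = 100.0):
    """Classical dipole absorption spectrum from NVE segments.

    NVT equilibration, then ``n_segments`` NVE runs launched from
    thermostatted snapshots separated by ``gap_fs``; the dipole derivative
    is recorded every step and the segments are autocorrelated jointly.
    """
    topo = base_potential.topo
    rng = np.random.default_rng(np.random.SeedSequence([seed, 97]))
    nvt = IntegratorSettings(dt_fs=dt_fs, thermostat="langevin",
                             tau_fs=thermostat_tau_fs,
                             temperature=temperature, seed=seed)
    nve = IntegratorSettings(dt_fs=dt_fs, thermostat="none",
                             temperature=temperature, seed=seed)
    n_equil = int(round(equil_fs / dt_fs))
    state = config
    if n_equil > 0:
        rec = run_md(config, base_potential, nvt, n_equil, stride=n_equil,
                     rng=rng)
        state = rec.final
    segments = []
    hook = {"mdot": lambda x, v: dipole_derivative(v, topo, params)}
    n_gap = max(1, int(round(gap_fs / dt_fs)))
    for _ in range(n_segments):
        rec = run_md(state, base_potential, nvt, n_gap, stride=n_gap,
                     rng=rng)
        state = rec.final
        seg = run_md(state, base_potential, nve,
                     int(round(segment_fs / dt_fs)), stride=1, hooks=hook,
                     rng=rng)
        segments.append(seg.observables["mdot"])
    spectrum = spectrum_from_segments(segments, dt_fs, window_tau_fs)
    return spectrum, segments


def _stage_spectra(config: PipelineConfig, stage_dir: Path) -> list:
    params = config.model_params()
    cfg, topo, cell = config.build_structure(params)
    pot = config.base_potential(topo, cell, params)
    temperature = config.getfloat("structure", "temperature")

    corr_dir = config.outdir / "ibi-fit" / "correction"
    if not corr_dir.exists():
        raise ConfigurationError(
            "missing correction potential; run stage 'ibi-fit' first")
    correction = CorrectionPotential.load(corr_dir)
    qc_pot = CorrectedPotential(pot, correction)

    kwargs = dict(
        params=params, config=cfg, temperature=temperature,
        dt_fs=config.getfloat("md", "dt_fs"),
        tau_fs=config.getfloat("md", "tau_fs"),
        n_segments=config.getint("spectra", "n_segments"),
        segment_fs=config.getfloat("spectra", "segment_fs"),
        gap_fs=config.getfloat("spectra", "gap_fs"),
        equil_fs=config.getfloat("spectra", "equil_fs"),
        window_tau_fs=config.getfloat("spectra", "window_tau_fs"),
        seed=config.seed)
    classical, _ = dipole_spectrum(pot, **kwargs)
    fqcmd_spec, _ = dipole_spectrum(qc_pot, **kwargs)

    meta = {"temperature": temperature, "seed": config.seed,
            "n_segments": config.getint("spectra", "n_segments")}
    out_cl = stage_dir / "classical.csv"
    out_qc = stage_dir / "fqcmd.csv"
    io.write_spectrum_csv(out_cl, classical, {**meta, "potential": "classical"})
    io.write_spectrum_csv(out_qc, fqcmd_spec, {**meta, "potential": "fqcmd"})
    table = compare_spectra(classical, fqcmd_spec, config.bands())
    out_tab = stage_dir / "bands.csv"
    table.to_csv(out_tab, index=False)
    return [out_cl, out_qc, out_tab]


def run_stage(config: PipelineConfig, stage: str, resume: bool = False,
              stop_after: int | None = None) -> Path:
    """Run one pipeline stage; returns the stage directory.

    Outputs land in ``<output.directory>/<stage>/`` together with a
    manifest recording the config hash, seed, inputs and package version.
    """
    if stage not in STAGES:
        raise ConfigurationError(f"unknown stage {stage!r}; one of {STAGES}")
    stage_dir = config.outdir / stage
    stage_dir.mkdir(parents=True, exist_ok=True)
    (stage_dir / "config.ini").write_text(config.to_text())

    inputs = []
    if stage == "pimd-targets":
        outputs = _stage_pimd_targets(config, stage_dir)
    elif stage == "ibi-fit":
        inputs = [config.outdir / "pimd-targets" / "targets.h5"]
        if not inputs[0].exists():
            raise ConfigurationError(
                "missing PIMD targets; run stage 'pimd-targets' first")
        outputs = _stage_ibi_fit(config, stage_dir, resume, stop_after)
    else:
        inputs = sorted((config.outdir / "ibi-fit" / "correction").glob("*.txt"))
        outputs = _stage_spectra(config, stage_dir)
    outputs = list(outputs) + [stage_dir / "config.ini"]
    _write_manifest(stage_dir, config, stage, inputs, outputs)
    return stage_dir


def compare_spectra(spectrum_a: AbsorptionSpectrum,
                    spectrum_b: AbsorptionSpectrum,
                    bands: dict) -> pd.DataFrame:
    """Per-band peak positions and signed shifts (a minus b, cm^-1)."""
    fa, fb = spectrum_a.frequency_cm1, spectrum_b.frequency_cm1
    lo = max(fa.min(), fb.min())
    hi = min(fa.max(), fb.max())
    if hi <= lo:
        raise ConfigurationError("spectra have non-overlapping frequency grids")
    rows = []
    for name, (b_lo, b_hi) in bands.items():
        peak_a = find_band_peak(spectrum_a, (b_lo, b_hi))
        peak_b = find_band_peak(spectrum_b, (b_lo, b_hi))
        rows.append({"band": name, "range_lo_cm1": b_lo, "range_hi_cm1": b_hi,
                     "peak_a_cm1": peak_a, "peak_b_cm1": peak_b,
                     "shift_cm1": peak_a - peak_b})
    return pd.DataFrame(rows)
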