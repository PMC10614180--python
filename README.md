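# fqcmd

Fast quasi-centroid molecular dynamics (f-QCMD) for flexible water: a
Python package that computes vibrational (dipole absorption) spectra of
liquid water and hexagonal ice *including nuclear quantum effects*, at the
cost of classical molecular dynamics.

## The problem and the method

Vibrational spectra of water are strongly affected by nuclear quantum
effects — zero-point motion red-shifts the O–H stretching band by roughly
100 cm⁻¹ relative to a classical simulation of the same potential — but
exact quantum dynamics of a condensed-phase system is out of reach.
Centroid molecular dynamics approximates the quantum spectrum by classical
motion on a potential of mean force, and its quasi-centroid variant (QCMD)
cures the low-temperature "curvature problem" by averaging ring-polymer
beads in curvilinear internal coordinates (bond lengths r₁, r₂ and angle θ)
instead of Cartesian ones.  f-QCMD makes this affordable in three stages:

1. **PIMD** — a path-integral MD run samples the quasi-centroid
   distribution functions: intermolecular g_OO(r), g_OH(r), g_HH(r) and
   intramolecular densities ρ_r, ρ_θ of the bead-averaged geometry, with
   quasi-centroid molecules placed by a mass-weighted optimal rotation onto
   the Cartesian-centroid molecule.
2. **Regularized IBI** — the quasi-centroid potential of mean force is
   written as the classical potential plus separable corrections,

       V_qc = V_cl + ΔV_r(r₁) + ΔV_r(r₂) + ΔV_θ(θ) + Σ ΔV_XY(r),

   and the corrections are fitted by iterative Boltzmann inversion with
   Soper regularization: ΔV_XY ← ΔV_XY + kT ln[(g⁽ⁱ⁾+εG)/(g_target+εG)],
   where G is the larger peak height of the two RDFs and ε damps
   noise-dominated regions.
3. **Classical spectra** — the IR spectrum follows from the Hann-windowed
   cosine transform of the dipole-derivative autocorrelation ⟨μ̇(0)·μ̇(t)⟩
   over NVE segments, run once on V_cl (classical reference) and once on
   V_qc (quantum-corrected).

The classical interaction model is q-TIP4P/f (quartic-Morse stretch,
harmonic bend, O–O Lennard-Jones, H/M point charges), with parameters
packaged in `src/fqcmd/data/qtip4pf.params`.  See `docs/methods.md` for the
numerical choices and conventions.

## Worked example

Classical IR spectrum of proton-disordered hexagonal ice at 150 K on the
96-molecule orthorhombic cell, from ~12 ps of NVE dynamics with an 800 fs
Hann window (runs in a few minutes on one core):

```python
from fqcmd import (StructureSpec, WaterModelParams, WaterPotential,
                   build_ice_cell, dipole_spectrum, find_band_peak)

params = WaterModelParams.default()
spec = StructureSpec(phase="iceIh", n_molecules=96, temperature=150.0, seed=1)
config, topo, cell = build_ice_cell(spec, params)
potential = WaterPotential(topo, cell, params)

spectrum, _ = dipole_spectrum(
    potential, params, config, temperature=150.0, dt_fs=0.25, tau_fs=100.0,
    n_segments=4, segment_fs=3000.0, gap_fs=400.0, equil_fs=3000.0,
    window_tau_fs=800.0, seed=1)

for band, window in [("intermolecular O-O stretch", (100, 400)),
                     ("libration", (450, 1200)),
                     ("bend", (1300, 1900)),
                     ("O-H stretch", (3000, 4100))]:
    peak = find_band_peak(spectrum, window)
    print(f"{band:>26s}: {peak:7.1f} cm^-1")
```

Output:

```
intermolecular O-O stretch:   260.1 cm^-1
                 libration:   767.1 cm^-1
                      bend:  1678.1 cm^-1
               O-H stretch:  3601.2 cm^-1
```

The weak band near 250 cm⁻¹ is the intermolecular O–O stretch
characteristic of the hydrogen-bonded ice lattice; libration, bend and O–H
stretch are the three major intramolecular-and-orientational bands.  On the
quasi-centroid potential of mean force (stage 3 run on V_qc instead of
V_cl) the O–H stretch moves red by roughly 100 cm⁻¹ — the nuclear quantum
effect the method exists to capture.

## Full pipeline from the shell

The three stages are also exposed as a CLI over key-value config files
(one block per stage; see `tests/test_pipeline.py` for a complete example):

```bash
fqcmd run --config water.ini --stage pimd-targets
fqcmd run --config water.ini --stage ibi-fit        # --resume to continue
fqcmd run --config water.ini --stage spectra
fqcmd compare --a classical.csv --b fqcmd.csv --bands bands.txt
```

Each stage writes its artifacts (HDF5 state, CSV tables, plain-text
correction-potential tables, extended-XYZ structures) plus a manifest with
the config hash and seed; reruns with the same config are reproducible.
Defaults encode the full-scale study conditions (216-molecule liquid /
96-molecule ice cells, P = 32 beads at 300 K and 64 at 150 K, 30 IBI
iterations with ε = 1 and 5, 600/800 fs Hann windows, 0.25 fs time step).

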