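# Methods

`fqcmd` computes vibrational (dipole absorption) spectra of liquid water and
hexagonal ice that include the leading nuclear quantum effects, at the cost
of a classical molecular dynamics simulation.  The route is fast
quasi-centroid molecular dynamics (f-QCMD): the quasi-centroid potential of
mean force is precomputed as a correction to the classical potential by
inverting quasi-centroid distribution functions from a path-integral
simulation, and the spectrum is then obtained from purely classical dynamics
on the corrected potential.

## The model

All simulations use a flexible four-site point-charge water model of the
q-TIP4P/f form: a quartic expansion of a Morse O–H stretch,

    V_str(r) = D_r [ a_r²Δr² − a_r³Δr³ + (7/12) a_r⁴Δr⁴ ],   Δr = r − r_eq,

a harmonic H–O–H bend ½ k_θ (θ − θ_eq)², an O–O Lennard-Jones interaction,
and Coulomb interactions among the two hydrogen charges q_H and a massless
M site at γ r_O + ½(1−γ)(r_H1 + r_H2) carrying −2 q_H.  The parameter file
`src/fqcmd/data/qtip4pf.params` holds the published values in their original
units; everything internal is in Hartree atomic units (a0, hartree, electron
masses), with femtoseconds and cm⁻¹ appearing only at I/O boundaries.

Electrostatics defaults to a damped-shifted-force (DSF) real-space sum with
cutoff at half the smallest box edge and damping α = 3/r_c; both the energy
and the force go continuously to zero at the cutoff, which is what the NVE
energy-conservation budget (drift ≤ 1e−5 relative over 10 ps at dt = 0.25
fs) requires.  A conventional Ewald sum (tinfoil boundaries) is available
behind the `model.coulomb` switch and is validated against the rock-salt
Madelung constant; band positions at the system sizes treated here are
insensitive to the choice.  A `bare` 1/r mode serves gas-phase molecules
and clusters.  Nonbonded evaluation is an O(N²) minimum-image pair loop
(numba-compiled on the hot paths, with an equivalent vectorized numpy
fallback); at 96–648 atoms a cell list would gain nothing.

## Stage (i): PIMD and quasi-centroid distributions

The ring polymer is propagated in the "scaled" convention — the physical
potential enters with weight 1/P, springs at frequency √P/β — so bead
marginals sample the exact quantum thermal distribution at the physical
temperature.  Propagation is an OBABO splitting: per-normal-mode Langevin
(PILE) half-steps with friction 2ω_k (centroid mode weakly coupled at
1/τ, τ = 100 fs), velocity half-steps from the physical forces, and exact
free-ring-polymer evolution in normal modes.  P = 32 at 300 K and P = 64 at
150 K reproduce the study conditions; desk-scale presets use P = 16, which
on a one-dimensional stretch oscillator reproduces the bead-averaged bond
distribution's mean shift to within ~10 % of its P → ∞ value.

For every sampled configuration each molecule's quasi-centroid is built
from curvilinear bead averages — the two mean O–H bond lengths r̄₁, r̄₂ and
the mean angle θ̄ — and placed by setting its mass center to that of the
Cartesian-centroid molecule and rotating it, via the quaternion-eigenproblem
solution of the mass-weighted superposition problem, as close as possible to
the centroid molecule's orientation.  Molecules are made contiguous across
periodic boundaries by minimum-imaging every bead atom relative to the O of
the first bead; a bond longer than 3 a0 after unwrapping raises.  The
template orientation is irrelevant (asserted in the tests) and the
quaternion sign is fixed by a non-negative scalar part.

Five distribution functions are accumulated with one code path shared by
quasi-centroid frames and classical configurations (a placed quasi-centroid
molecule's internal geometry *is* the curvilinear average, so histogramming
positions is exact for both sources): intermolecular g_OO, g_OH, g_HH
(0.05 a0 bins, range = half the smallest edge, ideal-gas-shell normalized
with exact shell volumes so g → 1), and intramolecular densities ρ_r
(0.02 a0 bins) and ρ_θ (0.5° bins), each normalized to unit integral.  ρ_θ
is a plain histogram without a sin θ Jacobian: targets and trials use the
identical estimator, so any smooth Jacobian cancels from the inversion's
fixed point.

## Stage (ii): regularized iterative Boltzmann inversion

The quasi-centroid potential of mean force is written as

    V_qc = V_cl + ΔV_r(r₁) + ΔV_r(r₂) + ΔV_θ(θ) + Σ_pairs ΔV_XY(r),

with ΔV_r a quartic and ΔV_θ a quadratic polynomial in the displacement
from equilibrium (the same degrees as the model's own intramolecular terms)
and ΔV_XY smooth tabulated pair corrections for XY ∈ {OO, OH, HH}.  Starting
from zero corrections, each iteration runs classical NVT on the current
corrected potential, accumulates trial distributions on the target grids,
and updates:

- pair channels, with Soper-style regularization:
  ΔV_XY ← ΔV_XY + kT ln[(g⁽ⁱ⁾ + εG_XY)/(g_target + εG_XY)], where G_XY is
  the larger of the two maximum peak heights, recomputed every iteration.
  ε = 1 at 300 K and ε = 5 at 150 K by default.  The update is interpolated
  onto the table grid, lightly smoothed (Savitzky–Golay, window 9, order 3)
  and re-switched to zero at the cutoff.
- intramolecular channels: the pointwise update kT ln(ρ⁽ⁱ⁾/ρ_target) is
  evaluated on bins where both densities exceed 1 % of their maxima and fit
  by target-density-weighted least squares (the weighting makes the
  weighted-metric noise homoscedastic, since bin noise scales as 1/√ρ); the
  constant (a free-energy offset) is discarded and the fitted increment is
  added to the current coefficients.

Pair tables are natural cubic splines on a uniform grid running from the
first radius where the target g exceeds 1e−4 out to the cutoff, taken
smoothly to zero by a quintic switch over the last 1 a0.  The switch
finishes two grid points *before* the cutoff and the remaining nodes are
exactly zero, so pairs crossing the cutoff during dynamics see no force
discontinuity at all; without this, the residual spline slope at the cutoff
produces a measurable NVE energy drift.  Below the inner edge the table
continues with constant force (counted, never raising mid-run).

Three further numerical choices matter at desk scale and are worth stating
plainly:

1. **Windowed polynomials.** The fitted ΔV_r and ΔV_θ are trusted only on
   the displacement window actually covered by the 1 %-masked bins; outside
   it they continue linearly (constant force).  A free quartic tail fitted
   from a narrow window can turn over and unbind the O–H stretch within a
   few hundred steps.
2. **Significance-gated refit.** Over a window a few σ wide the monomials
   x, x², x³, x⁴ are nearly collinear, so unconstrained coefficients take
   large mutually canceling values driven by sampling noise and random-walk
   from iteration to iteration — with direct (tens of cm⁻¹) consequences
   for the curvature at the minimum.  The linear and quadratic components,
   which track the well-determined mean and width of the distribution, are
   always fit; cubic and quartic components are kept only when they exceed
   three standard errors.  Standard errors come from the scatter of fits to
   independent time blocks of the trial trajectory (six blocks): sampling
   noise is time-correlated and therefore smooth across bins, which makes
   residual-based error estimates badly optimistic.  At the fixed point the
   update is statistically zero, so gated refits stop moving.
3. **Tail averaging.** Near its fixed point the iteration is a
   mean-reverting stochastic process whose per-iteration corrections carry
   fresh trial-sampling noise; the final correction can optionally be the
   average of the last few iterations (`ibi.tail_average`), which reduces
   that noise without biasing the fixed point.  Full-scale runs with long
   trial trajectories do not need it; desk-scale presets average the last
   four.

Convergence is tracked per channel as a sup-norm difference (RDF
differences lightly smoothed before taking the sup — the comparison mirrors
overlaid plotted curves; intramolecular densities compared after peak
normalization), with 0.02 as the "graphically indistinguishable" bar.  A
metric growing for five consecutive iterations aborts with the suggestion
to raise ε, which is the method's documented instability mode.  Because the
solution of the inversion need not be unique, the ε-dependence of the
converged correction is a diagnostic, not an error; the claim defended by
the tests is that spectra are insensitive within the convergent range.

## Stage (iii): spectra

Spectra come from the dipole-derivative autocorrelation
C(t) = ⟨μ̇(0)·μ̇(t)⟩ of purely classical dynamics: NVE segments launched
from snapshots of a thermostatted run (so the thermostat cannot distort
line shapes), with μ̇ = Σ q v including the M-site chain rule.  C(t) is
origin-averaged without bias (FFT-based, each lag normalized by its own
origin count), damped by a Hann window cos²(πt/2τ) that reaches zero at
t = τ (τ = 600 fs for the liquid, 800 fs for ice), zero-padded and
cosine-transformed.  Intensities are reported peak-normalized and the
thermal/frequency prefactor of the absorption cross section is omitted: it
varies slowly across a band and does not move maxima, which are the
observables of interest.  Tiny negative transform values (window sidelobes)
are clipped.  Band maxima are refined by three-point parabolic
interpolation.

## Structure generators

- **Liquid**: jittered-lattice placement (oxygens exactly on the jittered
  sites, molecules randomly oriented about them; no O–O pair closer than
  4.5 a0) at the printed density — 216 molecules in a cubic 35.24 a0 box,
  scaled at constant density for smaller counts — with Maxwell–Boltzmann
  velocities.  Pre-equilibration is left to the pipeline stages (default
  20 ps of classical NVT for the liquid; ice configs typically use 40 ps;
  desk-scale tests use 5 ps, enough for the hydrogen-bond network to
  develop from the lattice start).  The generators themselves stay pure
  functions of spec and seed.
- **Ice Ih**: oxygens on the ideal lonsdaleite lattice filling the printed
  25.62 × 29.58 × 27.89 a0 orthorhombic cell (a 3 × 2 × 2 replication of
  the 8-molecule orthorhombic cell); protons assigned by a seeded
  Monte-Carlo repair until the Bernal–Fowler rules hold (every O donates
  exactly two H, one H per hydrogen bond), followed by directed-loop
  reversals until the net dipole falls below 0.5 e·a0.  Covalent hydrogens
  sit at r_eq along the donated O–O directions; the ~2° strain against
  θ_eq relaxes in equilibration.  The proton topology realization is
  seed-dependent by design; band positions are insensitive to it.
- **Toys**: a separable anharmonic oscillator with closed-form/matrix-method
  quantum reference distributions, and a pair-perturbed Lennard-Jones fluid
  for inversion-recovery oracles.  The toy fluid runs at reduced density
  0.4 and supercritical temperature, where pair-from-pair inversion is well
  conditioned; at liquid-like densities the RDF is nearly blind to smooth
  "pressure-like" components of the pair potential, and recovery of such
  modes is hopeless at any reasonable statistics.

## Problem sizes used by the test suite and acceptance script

The packaged tests reproduce the study's observables at reduced scale,
chosen so the full suite runs on a single CPU core in well under half an
hour: 64-molecule liquid boxes at the printed density with P = 16 beads,
10 regularized IBI iterations at ε = 1 (trial runs of 2.5–5 ps, targets
from 12 ps of PIMD sampling), and spectra from six NVE segments of 4 ps;
the ice spectrum uses the printed 96-molecule cell with ≥ 10 ps of NVE
sampling.  The acceptance script recomputes the ice intermolecular band
the same way.  At these sizes the statistical error of a stretch-band
maximum is a few tens of cm⁻¹ and the sup-norm agreement reachable between
trial and target RDFs is noise-limited at roughly 0.03–0.1 rather than the
0.02 attainable with full-scale (216-molecule, tens-of-ps) trajectories.

## What the generated data does and does not establish

The generators emulate the study conditions (densities, cells,
temperatures, bead counts), so passing tests demonstrate the correctness of
the machinery — exact transforms, analytic forces, canonical sampling,
fixed-point and recovery behavior of the inversion, spectral conventions —
and reproduce the headline band positions within sampling tolerances.  They
do not establish convergence of the quasi-centroid potential of mean force
itself at production quality: that requires the full-scale settings (216
molecules, P = 32/64, 30 iterations, ~50 ps trials) that the defaults
encode but the test suite deliberately scales down.  Nor does any of this
address known limitations of centroid methods themselves: overtone and
combination bands lack their quantum intensity enhancement, and the
pairwise form assumed for the intermolecular correction omits many-body
contributions that grow toward lower temperatures.
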