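"""Physical constants and unit conversions.

All internal arithmetic is carried out in Hartree atomic units: lengths in
bohr (a0), energies in hartree, masses in electron masses, and time in the
atomic time unit.  Conversions to/from femtoseconds, kelvin, kcal/mol,
angstrom and wavenumbers happen only at I/O boundaries.
"""

from __future__ import annotations

# CODATA-2018 values.
BOHR_TO_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM

HARTREE_TO_KCALMOL = 627.509474
KCALMOL_TO_HARTREE = 1.0 / HARTREE_TO_KCALMOL

# Atomic unit of time in femtoseconds.
AUT_TO_FS = 0.02418884326509
FS_TO_AUT = 1.0 / AUT_TO_FS

# Boltzmann constant, hartree per kelvin.
KB_HARTREE = 3.166811563e-6

# Atomic mass unit (dalton) in electron masses.
AMU_TO_ME = 1822.888486209

# hartree -> cm^-1 (E / (h c)).
HARTREE_TO_CM1 = 219474.6313632

# Ordinary frequency in fs^-1 -> wavenumber in cm^-1: 1/(c [cm/fs]).
INV_FS_TO_CM1 = 1.0e15 / 2.99792458e10

SPEED_OF_LIGHT_CM_S = 2.99792458e10


def beta_from_temperature(temperature_K: float) -> float:
    """Inverse temperature in 1/hartree."""
    if temperature_K <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_K}")
    return 1.0 / (KB_HARTREE * temperature_K)
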