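# q-TIP4P/f flexible four-site water model
# Habershon, Markland & Manolopoulos, J. Chem. Phys. 131, 024501 (2009),
# Table II.  Values in the units of the original parameterization; they are
# converted to atomic units on load.

# Intramolecular: quartic Morse expansion of the O-H stretch and harmonic
# H-O-H bend.
D_r_kcalmol         = 116.09     # Morse depth
a_r_inv_angstrom    = 2.287      # Morse range parameter
r_eq_angstrom       = 0.9419     # O-H equilibrium bond length
k_theta_kcalmol_rad2 = 87.85     # bend force constant
theta_eq_degree     = 107.4      # equilibrium bond angle

# Intermolecular: O-O Lennard-Jones and H/M point charges.
sigma_OO_angstrom   = 3.1589
eps_OO_kcalmol      = 0.1852
q_H_e               = 0.5564     # per hydrogen; q_M = -2 q_H
gamma_M             = 0.73612    # M-site displacement fraction

# Atomic masses.
m_O_amu             = 15.9994
m_H_amu             = 1.0078
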