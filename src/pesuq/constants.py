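"""Physical constants and element tables.

Internal units throughout the package: length in Å, energy in kcal/mol,
forces in kcal/mol/Å, time in fs, mass in amu, dipole in Debye.
"""

# Boltzmann constant, kcal/mol/K (CODATA k_B * N_A / 4184 J/kcal).
KB_KCAL_PER_MOL_K = 0.0019872041

# 1 eV = 23.0605 kcal/mol (thermochemical calorie). Used to document the
# provenance of the PhysNet-style loss weights, which were published with
# energies in eV; the energy/force weight ratio is unit invariant as long as
# energies and forces share one energy unit, so the weights carry over
# unchanged to kcal/mol internals.
EV_TO_KCAL_PER_MOL = 23.0605

# 1 amu * Å^2 / fs^2 expressed in kcal/mol:
#   1.66053906660e-27 kg * (1e-10 m)^2 / (1e-15 s)^2 * N_A / 4184
AMU_A2_FS2_TO_KCAL_PER_MOL = 2390.0573419746267

# Eigenvalues of the mass-weighted Hessian in kcal/mol/Å^2/amu -> s^-2.
KCAL_PER_MOL_A2_AMU_TO_S2 = 4.1840e26

SPEED_OF_LIGHT_CM_S = 2.99792458e10

# Standard atomic weights (amu), keyed by atomic number.
ATOMIC_MASSES = {1: 1.008, 6: 12.011, 7: 14.007, 8: 15.999}

ELEMENT_SYMBOLS = {1: "H", 6: "C", 7: "N", 8: "O"}
ATOMIC_NUMBERS = {v: k for k, v in ELEMENT_SYMBOLS.items()}

# van der Waals radii (Å) used by the bonded/non-bonded classification rule
# of the rank metric: a distance is "bonded" if it is smaller than the mean
# of the two vdW radii plus 20%.
VDW_RADII = {1: 1.10, 6: 1.70, 8: 1.52}
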