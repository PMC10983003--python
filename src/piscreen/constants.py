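"""Physical constants and unit conversions.

All internal energies are in eV and all distances in angstrom; conversions to
atomic units happen only where oscillator strengths are assembled.
"""

# e^2 / (4 pi eps0) in eV * angstrom
COULOMB_EV_ANGSTROM = 14.397

HARTREE_EV = 27.2114
BOHR_ANGSTROM = 0.529177

# Covalent radii (angstrom) for distance-based bond perception
# (Cordero et al. values for the elements parameterized here plus H).
COVALENT_RADII = {
    "H": 0.31,
    "B": 0.84,
    "C": 0.73,  # sp2
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "S": 1.05,
    "P": 1.07,
    "Cl": 1.02,
    "Br": 1.20,
}
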