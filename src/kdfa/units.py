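"""Unit conventions.

All internal quantities are atomic units (Bohr, Hartree). User-facing
boundaries (XYZ files, CLI output, free-energy tables) use Angstrom and meV.
"""

BOHR_PER_ANGSTROM = 1.8897259886
ANGSTROM_PER_BOHR = 1.0 / BOHR_PER_ANGSTROM

HARTREE_TO_MEV = 27211.386245988
MEV_TO_HARTREE = 1.0 / HARTREE_TO_MEV

#: Boltzmann constant in meV/K (CODATA 2018)
KB_MEV = 8.617333262e-2
#: Boltzmann constant in Hartree/K
KB_HARTREE = KB_MEV * MEV_TO_HARTREE
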