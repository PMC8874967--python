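"""Physical constants used throughout the package.

All energies are in kcal/mol, temperatures in kelvin, distances in
angstrom, volumes in mL/uL as labelled at call sites.  Binding constants
are dimensionless on the 1 M standard-concentration scale.
"""

#: Gas constant, kcal/(mol K).
R_KCAL: float = 1.98720425e-3

#: Coulomb prefactor e^2 N_Av / (4 pi eps_0), kcal A / mol.  Two unit
#: charges 1 A apart in vacuum interact with 332.06 kcal/mol.
COULOMB_KCAL_ANGSTROM: float = 332.06

#: Conventional standard concentration used to normalize binding
#: constants reported in 1/M, mol/L.
STANDARD_CONC_M: float = 1.0
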