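"""Physical constants and unit conversions used throughout the package.

All energies are carried internally in kcal/mol, coordinates in Angstrom,
temperatures in Kelvin.  The Hartree conversion follows the convention of
semi-empirical tight-binding codes (1 Eh = 627.5095 kcal/mol).
"""

from scipy import constants as _c

#: Hartree -> kcal/mol (xtb/CREST convention)
HARTREE_TO_KCAL = 627.5095

#: Gas constant in kcal/(mol K)
R_KCAL = 1.98720425e-3

#: 1 cm^-1 of a harmonic quantum, in kcal/mol (h c N_A)
CM1_TO_KCAL = _c.h * _c.c * 100.0 * _c.N_A / 4184.0  # ~2.85914e-3

#: Rotational constant conversion: B[MHz] = MHZ_PER_AMU_A2 / I[amu Angstrom^2]
MHZ_PER_AMU_A2 = 505379.0

#: Bohr radius in Angstrom
BOHR_TO_ANGSTROM = _c.physical_constants["Bohr radius"][0] * 1e10

#: milli-Hartree -> kcal/mol (metadynamics pushing strengths are quoted in mEh)
MILLIHARTREE_TO_KCAL = HARTREE_TO_KCAL * 1e-3

#: Default temperature (K) for all thermodynamic averaging
DEFAULT_TEMPERATURE = 298.15

#: Standard pressure (Pa) for translational thermochemistry
STANDARD_PRESSURE = 101325.0

# SI constants re-exported for the RRHO formulas
PLANCK = _c.h
BOLTZMANN = _c.k
AVOGADRO = _c.N_A
SPEED_OF_LIGHT = _c.c
AMU_KG = _c.atomic_mass


def rt(temperature: float) -> float:
    """R*T in kcal/mol."""
    return R_KCAL * temperature
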