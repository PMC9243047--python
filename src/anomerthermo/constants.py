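"""Physical constants and element tables.

All conversions in the package flow through this module. SI defining
constants (exact since the 2019 redefinition, identical in CODATA 2018):
Planck constant, speed of light, Boltzmann constant, Avogadro number.
Internal energy unit is kcal/mol; the thermochemical calorie (4.184 J)
is used throughout.
"""

from __future__ import annotations

# SI defining constants (exact)
PLANCK_J_S = 6.62607015e-34
SPEED_OF_LIGHT_M_S = 299792458.0
BOLTZMANN_J_K = 1.380649e-23
AVOGADRO = 6.02214076e23

CAL_TO_J = 4.184  # thermochemical calorie, exact
AMU_TO_KG = 1.66053906660e-27  # CODATA 2018

#: kB·N_A in kcal/(mol·K)
KB_KCAL_PER_MOL_K = BOLTZMANN_J_K * AVOGADRO / (CAL_TO_J * 1000.0)

#: conventional hartree → kcal/mol factor used for parsed electronic-structure output
HARTREE_TO_KCAL_PER_MOL = 627.5095

#: h·c in J·cm — multiply by a wavenumber in cm⁻¹ to get a photon energy
HC_J_CM = PLANCK_J_S * SPEED_OF_LIGHT_M_S * 100.0

#: 1 atm in Pa (exact)
ATM_TO_PA = 101325.0

# Covalent radii in Å (Cordero et al. consensus values) for bond perception.
COVALENT_RADII = {
    "H": 0.31,
    "B": 0.84,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "Na": 1.66,
    "Mg": 1.41,
    "Si": 1.11,
    "P": 1.07,
    "S": 1.05,
    "Cl": 1.02,
    "K": 2.03,
    "Ca": 1.76,
    "Br": 1.20,
    "I": 1.39,
    "He": 0.28,
    "Ne": 0.58,
    "Ar": 1.06,
}

# Standard atomic weights in amu (IUPAC 2021 abridged).
ATOMIC_MASSES = {
    "H": 1.008,
    "He": 4.0026,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Ne": 20.180,
    "Na": 22.990,
    "Mg": 24.305,
    "Si": 28.085,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "Ar": 39.948,
    "K": 39.098,
    "Ca": 40.078,
    "Br": 79.904,
    "I": 126.904,
}

#: tolerance factor applied to the sum of covalent radii when perceiving bonds
BOND_TOLERANCE_FACTOR = 1.15


def thermal_energy_kT(temperature_K: float) -> float:
    """kB·T·N_A in kcal/mol at the given temperature.

    At 343 K (≈70 °C, a temperature proposed for the Archean eon) this is
    0.68 kcal/mol, rounding to 0.7.
    """
    if temperature_K < 0:
        raise ValueError("temperature must be non-negative")
    return KB_KCAL_PER_MOL_K * temperature_K
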