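"""Physical constants and element tables.

Monoisotopic masses are NIST values for the most abundant isotope (Da).
Gyromagnetic ratios are CODATA-recommended, in rad s^-1 T^-1. Tabulated
locally so that everything runs without network access.
"""

from __future__ import annotations

# most-abundant-isotope masses, Da
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "B": 11.0093054,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "F": 18.99840322,
    "Na": 22.9897692809,
    "Mg": 23.9850417,
    "Si": 27.9769265325,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "K": 38.96370668,
    "Ca": 39.96259098,
    "Se": 79.9165213,
    "Br": 78.9183371,
    "I": 126.904473,
}

ELECTRON_MASS_DA = 5.48579909065e-4

# valences used by the degree-of-unsaturation (DBE) rule
DBE_MONOVALENT = {"H", "F", "Cl", "Br", "I"}
DBE_TRIVALENT = {"N", "P"}
DBE_TETRAVALENT = {"C", "Si"}
DBE_DIVALENT = {"O", "S", "Se"}

# gyromagnetic ratios, rad s^-1 T^-1
GAMMA: dict[str, float] = {
    "1H": 2.6752218744e8,
    "2H": 4.10662791e7,
    "13C": 6.728284e7,
    "15N": -2.7126e7,
    "19F": 2.518148e8,
    "31P": 1.08394e8,
}

MU0 = 1.25663706212e-6      # N A^-2
H_PLANCK = 6.62607015e-34   # J s
HC_EV_NM = 1239.841984      # eV nm, photon energy <-> wavelength

R_KCAL = 1.987204259e-3     # kcal mol^-1 K^-1

# single-bond covalent radii (Angstrom) for the distance bonding heuristic
COVALENT_RADIUS: dict[str, float] = {
    "H": 0.31,
    "B": 0.84,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "Si": 1.11,
    "P": 1.07,
    "S": 1.05,
    "Cl": 1.02,
    "Br": 1.20,
    "I": 1.39,
}
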