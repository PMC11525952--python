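"""Physical constants, atomic masses and isotope tables.

Masses are on the unified atomic mass scale (u).  Isotope abundances are
IUPAC 2021 representative values.  Energies are kcal/mol, distances Å,
frequencies cm^-1 throughout the package.
"""

from __future__ import annotations

import math

from scipy import constants as _sc

# --- fundamental -----------------------------------------------------------

PROTON_MASS_U = _sc.physical_constants["proton mass in u"][0]  # 1.00727646...
AVOGADRO = _sc.Avogadro
KCAL_PER_MOL_TO_J = _sc.calorie * 1000.0 / AVOGADRO  # J per molecule
BOLTZMANN_KCALMOL = _sc.Boltzmann * AVOGADRO / (_sc.calorie * 1000.0)  # kcal/mol/K
PLANCK = _sc.Planck
C_CM = _sc.speed_of_light * 100.0  # cm/s
AMU_KG = _sc.atomic_mass
GAS_CONSTANT_KCALMOL = BOLTZMANN_KCALMOL

# hc / k_B in cm*K — converts wavenumbers to vibrational temperatures
HC_OVER_KB_CMK = PLANCK * C_CM / _sc.Boltzmann
# h*c in kcal/mol per cm^-1 — converts wavenumbers to energies
WAVENUMBER_TO_KCALMOL = PLANCK * C_CM * AVOGADRO / (_sc.calorie * 1000.0)

# sqrt(kcal/mol/Å^2/amu) -> cm^-1 for harmonic frequencies
_lam_si = KCAL_PER_MOL_TO_J / (1e-10**2) / AMU_KG  # s^-2 per unit eigenvalue
HESSIAN_EIGVAL_TO_WAVENUMBER = math.sqrt(_lam_si) / (2.0 * math.pi * C_CM)

# --- atomic data -----------------------------------------------------------

#: most-abundant-isotope (monoisotopic) masses, u
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
    "Na": 22.98976928,
    "K": 38.9637064864,
}

#: standard atomic weights (abundance-weighted), u
AVERAGE_MASS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.973761998,
    "Na": 22.98976928,
    "K": 39.0983,
}

#: isotope tables: element -> list of (nominal mass shift, exact mass, abundance)
ISOTOPES: dict[str, list[tuple[int, float, float]]] = {
    "H": [(0, 1.0078250319, 0.999885), (1, 2.0141017780, 0.000115)],
    "C": [(0, 12.0, 0.9893), (1, 13.0033548378, 0.0107)],
    "N": [(0, 14.0030740052, 0.99636), (1, 15.0001088984, 0.00364)],
    "O": [
        (0, 15.9949146221, 0.99757),
        (1, 16.9991315, 0.00038),
        (2, 17.9991604, 0.00205),
    ],
    "S": [
        (0, 31.97207069, 0.9499),
        (1, 32.97145850, 0.0075),
        (2, 33.96786683, 0.0425),
        (4, 35.96708088, 0.0001),
    ],
}

#: masses used for mass-weighting Hessians
ATOMIC_MASS_FOR_ELEMENT = MONOISOTOPIC_MASS

STANDARD_PRESSURE_PA = 101325.0
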