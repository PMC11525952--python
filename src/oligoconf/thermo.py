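"""Rigid-rotor/harmonic-oscillator thermochemistry and free-energy crossover.

The crossover analysis captures the rigidity/entropy mechanism: a
conformer that is lower in electronic energy but uniformly stiffer loses
on entropy as temperature rises, so ΔG(T) between the two changes sign at
a crossover temperature found by bisection and verified on a 1 K grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    AMU_KG,
    AVOGADRO,
    BOLTZMANN_KCALMOL,
    HC_OVER_KB_CMK,
    PLANCK,
    STANDARD_PRESSURE_PA,
    WAVENUMBER_TO_KCALMOL,
)
from scipy import constants as _sc

__all__ = [
    "ThermoInput",
    "CrossoverResult",
    "zero_point_energy",
    "vibrational_entropy",
    "entropy",
    "free_energy",
    "crossover_temperature",
]


@dataclass
class ThermoInput:
    """Everything needed for RRHO thermochemistry of one conformer."""

    electronic_energy: float  # kcal/mol
    frequencies: np.ndarray  # cm^-1, all > 0
    total_mass: float = 0.0  # amu; 0 disables translational terms
    moments_of_inertia: np.ndarray | None = None  # amu·Å²; None disables rot.
    symmetry_number: int = 1
    quasi_harmonic_floor: float = 0.0  # raise low modes to this value (cm^-1)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if np.any(self.frequencies <= 0):
            raise ValueError("vibrational frequencies must be positive")
        if self.moments_of_inertia is not None:
            self.moments_of_inertia = np.asarray(self.moments_of_inertia, float)

    def effective_frequencies(self) -> np.ndarray:
        if self.quasi_harmonic_floor > 0:
            return np.maximum(self.frequencies, self.quasi_harmonic_floor)
        return self.frequencies


@dataclass
class CrossoverResult:
    temperature: float | None
    temperatures: np.ndarray
    delta_g: np.ndarray
    delta_e: float
    delta_zpe: float
    all_crossings: list[float] = field(default_factory=list)
    multiple: bool = False


def zero_point_energy(inp: ThermoInput) -> float:
    """ZPE = Σ ½ hc ν̃, kcal/mol."""
    return float(0.5 * WAVENUMBER_TO_KCALMOL * inp.effective_frequencies().sum())


def vibrational_entropy(inp: ThermoInput, T: float) -> float:
    """Harmonic-oscillator vibrational entropy, kcal/mol/K."""
    theta = HC_OVER_KB_CMK * inp.effective_frequencies()  # vibrational temps, K
    x = theta / T
    # guard exp overflow: high-frequency modes contribute ~0
    x = np.minimum(x, 500.0)
    s = x / np.expm1(x) - np.log1p(-np.exp(-x))
    return float(BOLTZMANN_KCALMOL * s.sum())


def _vibrational_free_energy(inp: ThermoInput, T: float) -> float:
    """ZPE + thermal vibrational free energy (kcal/mol)."""
    theta = HC_OVER_KB_CMK * inp.effective_frequencies()
    x = np.minimum(theta / T, 500.0)
    return zero_point_energy(inp) + float(
        BOLTZMANN_KCALMOL * T * np.log1p(-np.exp(-x)).sum()
    )


def _translational_free_energy(inp: ThermoInput, T: float) -> float:
    if inp.total_mass <= 0:
        return 0.0
    m = inp.total_mass * AMU_KG
    kT = _sc.Boltzmann * T
    lam = PLANCK / math.sqrt(2.0 * math.pi * m * kT)  # thermal wavelength, m
    q = kT / STANDARD_PRESSURE_PA / lam**3
    return -BOLTZMANN_KCALMOL * T * math.log(q)


def _rotational_free_energy(inp: ThermoInput, T: float) -> float:
    if inp.moments_of_inertia is None:
        return 0.0
    I_si = inp.moments_of_inertia * AMU_KG * 1e-20  # kg m^2
    kT = _sc.Boltzmann * T
    if np.count_nonzero(I_si > 1e-60) < 3:  # linear: one distinct moment
        I = float(I_si.max())
        q = 8.0 * math.pi**2 * I * kT / PLANCK**2 / inp.symmetry_number
    else:
        pref = math.sqrt(math.pi) / inp.symmetry_number
        q = pref * math.sqrt(
            np.prod(8.0 * math.pi**2 * I_si * kT / PLANCK**2)
        )
    return -BOLTZMANN_KCALMOL * T * math.log(q)


def free_energy(inp: ThermoInput, T: float) -> float:
    """G(T) = E_elec + ZPE + vibrational + rotational + translational
    free-energy contributions (kcal/mol, 1 atm standard state)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return (
        inp.electronic_energy
        + _vibrational_free_energy(inp, T)
        + _rotational_free_energy(inp, T)
        + _translational_free_energy(inp, T)
    )


def entropy(inp: ThermoInput, T: float) -> float:
    """Total entropy from -dG/dT (central difference), kcal/mol/K."""
    dT = min(0.01, T / 10.0)
    return -(free_energy(inp, T + dT) - free_energy(inp, T - dT)) / (2 * dT)


def crossover_temperature(
    a: ThermoInput,
    b: ThermoInput,
    t_range: tuple[float, float] = (10.0, 400.0),
    grid_step: float = 1.0,
    bisect_tol: float = 0.01,
) -> CrossoverResult:
    """Find where ΔG(T) = G_a(T) − G_b(T) changes sign.

    A 1 K grid scan locates sign changes; each bracket is refined by
    bisection.  With no sign change the result carries ``temperature``
    None.  Multiple crossings are all reported and flagged.
    """
    if a.total_mass and b.total_mass and not math.isclose(
        a.total_mass, b.total_mass, rel_tol=1e-9
    ):
        raise ValueError("conformers of the same complex must share total mass")
    lo, hi = t_range
    temps = np.arange(lo, hi + grid_step / 2, grid_step)
    dg = np.array([free_energy(a, t) - free_energy(b, t) for t in temps])
    crossings = []
    for i in range(len(temps) - 1):
        if dg[i] == 0.0:
            crossings.append(float(temps[i]))
        elif dg[i] * dg[i + 1] < 0:
            t_lo, t_hi = float(temps[i]), float(temps[i + 1])
            f_lo = dg[i]
            while t_hi - t_lo > bisect_tol:
                mid = 0.5 * (t_lo + t_hi)
                f_mid = free_energy(a, mid) - free_energy(b, mid)
                if f_lo * f_mid <= 0:
                    t_hi = mid
                else:
                    t_lo, f_lo = mid, f_mid
            crossings.append(0.5 * (t_lo + t_hi))
    return CrossoverResult(
        temperature=crossings[0] if crossings else None,
        temperatures=temps,
        delta_g=dg,
        delta_e=a.electronic_energy - b.electronic_energy,
        delta_zpe=zero_point_energy(a) - zero_point_energy(b),
        all_crossings=crossings,
        multiple=len(crossings) > 1,
    )
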