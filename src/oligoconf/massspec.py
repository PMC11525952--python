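"""Formula arithmetic, m/z, isotope envelopes and mixture decomposition.

Implements the mass-spectral assignment workflow for noncovalent peptide
oligomer ions: given a monomer formula, compute m/z of [n·M + z·H]^z+
species in monoisotopic or average-mass convention, build aggregated
(unit-resolution) isotope envelopes by exact convolution over the natural
isotope tables, and decompose a measured envelope into a non-negative
linear mixture of calculated component envelopes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .constants import (
    AVERAGE_MASS,
    ISOTOPES,
    MONOISOTOPIC_MASS,
    PROTON_MASS_U,
)

__all__ = [
    "IonFormula",
    "IsotopeEnvelope",
    "MixtureFit",
    "mz",
    "nominal_mz",
    "isotope_envelope",
    "align_envelope",
    "fit_mixture",
    "assign_peak",
]

#: 13C-12C mass difference; dominant isotopic spacing for CHNO formulas
C13_SPACING = ISOTOPES["C"][1][1] - ISOTOPES["C"][0][1]


@dataclass(frozen=True)
class IonFormula:
    """Element composition of an ion carrying ``charge`` added protons."""

    elements: dict[str, int] = field(default_factory=dict)
    charge: int = 1

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.elements.values()):
            raise ValueError("element counts must be non-negative")
        if self.charge < 1:
            raise ValueError("ionic charge must be >= 1")

    @classmethod
    def oligomer(cls, monomer: dict[str, int], n: int, z: int) -> "IonFormula":
        """Formula of [n·monomer + z·H]^z+ (protons tracked via ``charge``)."""
        if n < 1:
            raise ValueError("n must be >= 1")
        return cls({el: n * c for el, c in monomer.items()}, charge=z)

    def __add__(self, other: "IonFormula") -> "IonFormula":
        merged = dict(self.elements)
        for el, c in other.elements.items():
            merged[el] = merged.get(el, 0) + c
        return IonFormula(merged, charge=self.charge + other.charge - 1)


#: neutral Phe-Phe dipeptide: two Phe (C9H11NO2) condensed, one water removed
PHE2_FORMULA: dict[str, int] = {"C": 18, "H": 20, "N": 2, "O": 3}


@dataclass
class IsotopeEnvelope:
    """Normalized aggregated isotope distribution of one ion species."""

    mz: np.ndarray  # ascending, Th
    abundance: np.ndarray  # sums to 1
    label: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.mz.shape != self.abundance.shape:
            raise ValueError("m/z and abundance arrays must have equal length")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z grid must be strictly ascending")
        if np.any(self.abundance < 0):
            raise ValueError("abundances must be non-negative")
        total = float(self.abundance.sum())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"abundances must sum to 1 (got {total})")


@dataclass
class MixtureFit:
    components: list[IsotopeEnvelope]
    fractions: np.ndarray
    residual: float
    degenerate: bool = False


def _mass_table(mode: str) -> dict[str, float]:
    if mode == "monoisotopic":
        return MONOISOTOPIC_MASS
    if mode == "average":
        return AVERAGE_MASS
    raise ValueError(f"unknown mass mode {mode!r}")


def mz(formula: IonFormula, mode: str = "monoisotopic") -> float:
    """m/z in Th: (Σ atomic masses + z·m_proton) / z.

    The electron mass is neglected (charge carrier is the proton).
    """
    if not formula.elements and formula.charge == 0:
        raise ValueError("empty formula")
    table = _mass_table(mode)
    mass = 0.0
    for el, count in formula.elements.items():
        try:
            mass += table[el] * count
        except KeyError:
            raise KeyError(f"unknown element {el!r}") from None
    mass += formula.charge * PROTON_MASS_U
    return mass / formula.charge


def nominal_mz(formula: IonFormula, mode: str = "monoisotopic") -> int:
    """Nearest-integer m/z, round-half-up."""
    return int(math.floor(mz(formula, mode) + 0.5))


def _element_distribution(element: str, count: int) -> np.ndarray:
    """Aggregated abundance array (index = nominal mass shift) for n atoms."""
    try:
        table = ISOTOPES[element]
    except KeyError:
        # mono-isotopic in practice at this resolution
        return np.array([1.0])
    max_shift = max(s for s, _, _ in table)
    single = np.zeros(max_shift + 1)
    for shift, _m, ab in table:
        single[shift] = ab
    # n-fold convolution by binary exponentiation
    result = np.array([1.0])
    base = single
    n = count
    while n:
        if n & 1:
            result = np.convolve(result, base)
        n >>= 1
        if n:
            base = np.convolve(base, base)
    return result


def isotope_envelope(
    formula: IonFormula, prune: float = 1e-6, label: str = ""
) -> IsotopeEnvelope:
    """Aggregated isotope envelope at unit nominal-mass resolution.

    Exact convolution over the per-element isotope tables; isotopologue
    peaks are merged at nominal-mass spacing (1/z Th apart), pruned below
    ``prune`` relative abundance and renormalized.
    """
    if not 0.0 < prune <= 1e-3:
        raise ValueError("prune threshold must be in (0, 1e-3]")
    dist = np.array([1.0])
    for el, count in formula.elements.items():
        if count:
            dist = np.convolve(dist, _element_distribution(el, count))
    mono = mz(formula, "monoisotopic")
    z = formula.charge
    grid = mono + np.arange(dist.size) * (C13_SPACING / z)
    keep = dist >= prune * dist.max()
    # keep a contiguous leading block so the m/z grid stays regular
    last = int(np.nonzero(keep)[0].max()) + 1
    dist, grid = dist[:last], grid[:last]
    dist = dist / dist.sum()
    return IsotopeEnvelope(mz=grid, abundance=dist, label=label)


def convolve_envelopes(a: IsotopeEnvelope, b: IsotopeEnvelope) -> np.ndarray:
    """Abundance array of the combined species (associativity checks)."""
    return np.convolve(a.abundance, b.abundance)


def align_envelope(
    component: IsotopeEnvelope, grid: np.ndarray, tol: float = 0.5
) -> np.ndarray:
    """Project a component envelope onto a measured m/z grid.

    Each component peak is assigned to the nearest grid point within
    ``tol`` Th; peaks without a matching grid point are dropped.
    """
    grid = np.asarray(grid, dtype=float)
    out = np.zeros_like(grid)
    for m, a in zip(component.mz, component.abundance):
        i = int(np.argmin(np.abs(grid - m)))
        if abs(grid[i] - m) <= tol:
            out[i] += a
    return out


def fit_mixture(
    measured_mz: np.ndarray,
    measured_intensity: np.ndarray,
    components: list[IsotopeEnvelope],
    align_tol: float = 0.5,
) -> MixtureFit:
    """Non-negative least-squares decomposition of a measured envelope.

    Intensities are normalized to unit sum first, so the fit is invariant
    under rescaling of the measured trace; recovered fractions are
    renormalized to sum to 1.
    """
    if not components:
        raise ValueError("at least one component required")
    y = np.asarray(measured_intensity, dtype=float)
    if np.any(y < 0):
        raise ValueError("measured intensities must be non-negative")
    total = y.sum()
    if total <= 0:
        raise ValueError("measured envelope is empty")
    y = y / total
    grid = np.asarray(measured_mz, dtype=float)
    A = np.column_stack([align_envelope(c, grid, align_tol) for c in components])
    degenerate = False
    for i in range(A.shape[1]):
        for j in range(i + 1, A.shape[1]):
            if np.allclose(A[:, i], A[:, j], atol=1e-12):
                degenerate = True
    coef, rnorm = nnls(A, y)
    s = coef.sum()
    fractions = coef / s if s > 0 else np.full(len(components), 1.0 / len(components))
    return MixtureFit(
        components=components,
        fractions=fractions,
        residual=float(rnorm),
        degenerate=degenerate,
    )


def assign_peak(
    peak_mz: float,
    monomer: dict[str, int],
    n_range: range = range(1, 15),
    z_range: range = range(1, 4),
    mode: str = "monoisotopic",
) -> list[tuple[int, int, float]]:
    """Candidate (n, z) assignments of a peak, sorted by |Δm/z|."""
    out = []
    for n in n_range:
        for z in z_range:
            m = mz(IonFormula.oligomer(monomer, n, z), mode)
            out.append((n, z, abs(m - peak_mz)))
    out.sort(key=lambda t: (t[2], t[0], t[1]))
    return out
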