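"""Synthetic fixtures: toy landscapes, toy topologies, traces, envelopes.

Everything here is generated programmatically from a seed so the whole
pipeline is testable offline: an analytic separable double-well torsion
landscape with known minima and basins, minimal topologies exercising
the geometric predicates, synthetic IR traces built from a chosen
conformer's sticks, and isotope-envelope mixtures with known fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dedup_tfd import wrap_angles
from .ir_spectra import ExperimentalTrace, StickSpectrum, broaden
from .massspec import IonFormula, IsotopeEnvelope, isotope_envelope
from .peptide_model import Conformation, Topology

__all__ = [
    "DoubleWellLandscape",
    "hbond_toy",
    "pion_toy",
    "synthetic_trace",
    "random_decoy_sticks",
    "envelope_mixture",
]


@dataclass
class DoubleWellLandscape:
    """Separable periodic landscape with two wells per torsion.

    Per torsion (relative angle u = θ − offset, degrees):
        e(u) = a·(1 − cos u) + b·(1 − cos 2u)
    Minima at u = 0 (E=0, global) and u = 180 (E = 2a); barrier maxima at
    cos(u*) = −a/(4b).  Total energy is the sum over torsions, so the
    global minimum, all local minima, and basin boundaries are analytic.
    """

    offsets: np.ndarray
    a: float = 1.5
    b: float = 1.0

    def __post_init__(self) -> None:
        self.offsets = wrap_angles(np.asarray(self.offsets, float))
        if not -1.0 < -self.a / (4.0 * self.b) < 1.0:
            raise ValueError("a/(4b) must be < 1 for a double well")

    @property
    def n_torsions(self) -> int:
        return self.offsets.size

    def energy(self, torsions: np.ndarray) -> float:
        u = np.deg2rad(wrap_angles(np.asarray(torsions, float) - self.offsets))
        return float(
            np.sum(self.a * (1.0 - np.cos(u)) + self.b * (1.0 - np.cos(2.0 * u)))
        )

    def gradient(self, torsions: np.ndarray) -> np.ndarray:
        """dE/dθ in kcal/mol/degree."""
        u = np.deg2rad(wrap_angles(np.asarray(torsions, float) - self.offsets))
        dE_du = self.a * np.sin(u) + 2.0 * self.b * np.sin(2.0 * u)
        return dE_du * math.pi / 180.0

    @property
    def barrier_angle(self) -> float:
        """|u| of the barrier maximum separating the two wells, degrees."""
        return math.degrees(math.acos(-self.a / (4.0 * self.b)))

    def local_minima(self) -> list[np.ndarray]:
        """All local minima (every offset/offset+180 combination)."""
        out = []
        for mask in range(2**self.n_torsions):
            t = self.offsets.copy()
            for i in range(self.n_torsions):
                if mask >> i & 1:
                    t[i] += 180.0
            out.append(wrap_angles(t))
        return out

    def in_global_basin(self, torsions: np.ndarray) -> bool:
        u = np.abs(wrap_angles(np.asarray(torsions, float) - self.offsets))
        return bool(np.all(u < self.barrier_angle))

    def uniform_basin_fraction(self) -> float:
        """Probability that a uniform sample lies in the global basin."""
        return (2.0 * self.barrier_angle / 360.0) ** self.n_torsions


# ---------------------------------------------------------------------------
# toy topologies for the geometric predicates
# ---------------------------------------------------------------------------

def hbond_toy(
    da_distance: float = 2.9, dha_angle: float = 175.0
) -> Conformation:
    """N-H...O=C fixture: donor N at origin, H on the N-O axis, acceptor O
    placed at the requested distance with the requested D-H-A angle."""
    nh = 1.0
    topo = Topology(
        elements=["N", "H", "O", "C"],
        bonds=[(0, 1), (2, 3)],
        unit_of=[0, 0, 1, 1],
        residue_of=[(0, 0), (0, 0), (1, 0), (1, 0)],
        torsions=[],
        formula={"N": 1, "H": 1, "O": 1, "C": 1},
        donors=[(0, 1)],
        acceptors=[2],
        rings=[],
        charged_sites=[],
    )
    # place O so that angle(D,H,A) = dha_angle and |D-A| = da_distance
    ang = math.radians(180.0 - dha_angle)
    # H at (nh, 0, 0); solve for A position in the xy plane
    # direction from H making angle dha with H->D (=-x)
    dirv = np.array([math.cos(ang), math.sin(ang), 0.0])
    # find r along dirv with |A - D| = da_distance
    h = np.array([nh, 0.0, 0.0])
    # |h + r*dirv| = da_distance -> quadratic in r
    bq = 2.0 * float(h @ dirv)
    cq = float(h @ h) - da_distance**2
    r = (-bq + math.sqrt(bq * bq - 4 * cq)) / 2.0
    a_pos = h + r * dirv
    c_pos = a_pos + np.array([0.0, 1.23, 0.0])
    coords = np.vstack([[0.0, 0.0, 0.0], h, a_pos, c_pos])
    return Conformation(topo, coords, label="hbond_toy")


def pion_toy(
    distance: float = 4.8, same_residue: bool = False, n_rings: int = 1
) -> Conformation:
    """Charged ammonium N above one or more benzene-like rings."""
    elements: list[str] = []
    coords: list[list[float]] = []
    rings: list[list[int]] = []
    residue_of: list[tuple[int, int]] = []
    unit_of: list[int] = []
    bonds: list[tuple[int, int]] = []
    for r in range(n_rings):
        start = len(elements)
        for k in range(6):
            ang = math.pi * k / 3.0
            elements.append("C")
            coords.append([1.4 * math.cos(ang) + 20.0 * r, 1.4 * math.sin(ang), 0.0])
            residue_of.append((0, 0 if same_residue else 1 + r))
            unit_of.append(0)
            bonds.append((start + k, start + (k + 1) % 6))
        rings.append(list(range(start, start + 6)))
    n_idx = len(elements)
    elements.append("N")
    coords.append([0.0, 0.0, distance])
    residue_of.append((0, 0))
    unit_of.append(0)
    topo = Topology(
        elements=elements,
        bonds=bonds,
        unit_of=unit_of,
        residue_of=residue_of,
        torsions=[],
        formula={"C": 6 * n_rings, "N": 1},
        donors=[],
        acceptors=[],
        rings=rings,
        charged_sites=[n_idx],
    )
    return Conformation(topo, np.array(coords), label="pion_toy")


# ---------------------------------------------------------------------------
# synthetic spectra and envelopes
# ---------------------------------------------------------------------------

def synthetic_trace(
    sticks: StickSpectrum,
    fwhm: float = 8.0,
    noise: float = 0.0,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> ExperimentalTrace:
    """Experiment-like trace from a stick spectrum plus Gaussian noise."""
    trace = broaden(sticks, fwhm=fwhm, grid=grid)
    if noise > 0:
        rng = np.random.default_rng(seed)
        y = trace.intensities + rng.normal(
            0.0, noise * trace.intensities.max(), trace.intensities.size
        )
        trace = ExperimentalTrace(trace.wavenumbers, np.clip(y, 0.0, None))
    return trace


def random_decoy_sticks(
    rng: np.random.Generator,
    n_sticks: int = 12,
    lo: float = 1400.0,
    hi: float = 3650.0,
    label: str = "decoy",
) -> StickSpectrum:
    freqs = np.sort(rng.uniform(lo, hi, n_sticks))
    inten = rng.uniform(0.2, 1.0, n_sticks)
    return StickSpectrum(freqs, inten, label=label, scaled=True)


def envelope_mixture(
    fractions: tuple[float, ...] = (0.33, 0.67),
    formulas: tuple[IonFormula, ...] | None = None,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[IsotopeEnvelope]]:
    """Measured-style (m/z, intensity) arrays from a known linear mixture.

    Defaults mirror the trimer/hexamer overlap at ~938 Th:
    [3·Phe2 + H]+ and [6·Phe2 + 2H]2+.
    """
    from .massspec import PHE2_FORMULA, align_envelope

    if formulas is None:
        formulas = (
            IonFormula.oligomer(PHE2_FORMULA, 3, 1),
            IonFormula.oligomer(PHE2_FORMULA, 6, 2),
        )
    if len(fractions) != len(formulas):
        raise ValueError("one fraction per component required")
    comps = [
        isotope_envelope(f, label=f"component{i}")
        for i, f in enumerate(formulas)
    ]
    grid = np.unique(np.concatenate([c.mz for c in comps]).round(4))
    y = np.zeros_like(grid)
    for frac, comp in zip(fractions, comps):
        y += frac * align_envelope(comp, grid, tol=0.25)
    if noise > 0:
        rng = np.random.default_rng(seed)
        y = np.clip(y + rng.normal(0.0, noise * y.max(), y.size), 0.0, None)
    return grid, y, comps
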