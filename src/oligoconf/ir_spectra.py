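"""Harmonic IR stick spectra, region-wise scaling, broadening and matching.

Frequencies come from the mass-weighted Hessian; empirical region-wise
scale factors (0.955 above / 0.983 below the region boundary, matching
the 3 μm / 6 μm windows) correct the harmonic systematic error before
comparison with experimental gain or depletion traces.  Matching is
cosine similarity of baseline-subtracted, max-normalized curves; the
free-OH stretch window diagnostic discriminates charge-solvated from
salt-bridge structures.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .constants import HESSIAN_EIGVAL_TO_WAVENUMBER

__all__ = [
    "ScalingScheme",
    "StickSpectrum",
    "ExperimentalTrace",
    "harmonic_spectrum",
    "apply_scaling",
    "broaden",
    "match_score",
    "free_oh_diagnostic",
]

logger = logging.getLogger(__name__)


@dataclass
class ScalingScheme:
    """Region-wise frequency scale factors split at ``boundary`` cm^-1."""

    boundary: float = 2500.0
    high_factor: float = 0.955  # 3 μm region (X-H stretches)
    low_factor: float = 0.983  # 6 μm region (amide / fingerprint)

    def __post_init__(self) -> None:
        for f in (self.high_factor, self.low_factor):
            if not 0.8 < f < 1.05:
                raise ValueError(f"scale factor {f} outside (0.8, 1.05)")
        if not 1800.0 < self.boundary < 2800.0:
            raise ValueError("region boundary must lie in (1800, 2800) cm^-1")


@dataclass
class StickSpectrum:
    frequencies: np.ndarray  # cm^-1, ascending
    intensities: np.ndarray
    label: str = ""
    scaled: bool = False

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.frequencies.shape != self.intensities.shape:
            raise ValueError("frequency/intensity arrays must match")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class ExperimentalTrace:
    wavenumbers: np.ndarray  # ascending grid, cm^-1
    intensities: np.ndarray
    kind: str = "gain"  # or "depletion"

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.shape != self.intensities.shape:
            raise ValueError("grid/intensity arrays must match")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumber grid must be strictly ascending")
        if self.kind not in ("gain", "depletion"):
            raise ValueError(f"unknown trace kind {self.kind!r}")


def harmonic_spectrum(
    mass_weighted_hessian: np.ndarray,
    intensities: np.ndarray | None = None,
    n_rigid_modes: int = 6,
    imag_tolerance: float = 5.0,
    label: str = "",
) -> StickSpectrum:
    """Vibrational stick spectrum from a mass-weighted Hessian.

    Eigenvalues (kcal/mol/Å²/amu) convert to wavenumbers; the
    ``n_rigid_modes`` smallest-magnitude modes (translations/rotations)
    are dropped.  Any remaining mode with imaginary frequency above
    ``imag_tolerance`` cm^-1 means the geometry is not a minimum.
    """
    H = np.asarray(mass_weighted_hessian, dtype=float)
    H = 0.5 * (H + H.T)
    eigvals = np.linalg.eigvalsh(H)
    wavenumbers = np.sign(eigvals) * np.sqrt(np.abs(eigvals)) * (
        HESSIAN_EIGVAL_TO_WAVENUMBER
    )
    order = np.argsort(np.abs(wavenumbers))
    vib = wavenumbers[order[n_rigid_modes:]]
    imag = vib[vib < -imag_tolerance]
    if imag.size:
        listed = ", ".join(f"{abs(v):.1f}i" for v in sorted(imag))
        raise ValueError(f"not a minimum: imaginary frequencies {listed} cm^-1")
    vib = np.sort(vib[vib > 0])
    if intensities is None:
        inten = np.ones_like(vib)
    else:
        inten = np.asarray(intensities, dtype=float)
        if inten.size != vib.size:
            raise ValueError("intensity count does not match mode count")
    return StickSpectrum(vib, inten, label=label, scaled=False)


def apply_scaling(s: StickSpectrum, scheme: ScalingScheme | None = None) -> StickSpectrum:
    """Multiply stick frequencies by the region's empirical factor."""
    if s.scaled:
        raise ValueError("spectrum already scaled; refusing to scale twice")
    scheme = scheme or ScalingScheme()
    factors = np.where(
        s.frequencies >= scheme.boundary, scheme.high_factor, scheme.low_factor
    )
    return StickSpectrum(
        s.frequencies * factors, s.intensities.copy(), label=s.label, scaled=True
    )


def broaden(
    s: StickSpectrum,
    fwhm: float = 8.0,
    grid: np.ndarray | None = None,
) -> ExperimentalTrace:
    """Gaussian broadening; total integrated area equals stick intensity sum."""
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    if grid is None:
        lo = (s.frequencies.min() if s.frequencies.size else 1000.0) - 10 * fwhm
        hi = (s.frequencies.max() if s.frequencies.size else 1000.0) + 10 * fwhm
        grid = np.arange(lo, hi, fwhm / 8.0)
    grid = np.asarray(grid, dtype=float)
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    y = np.zeros_like(grid)
    if s.frequencies.size and (
        s.frequencies.min() < grid.min() or s.frequencies.max() > grid.max()
    ):
        logger.warning("broadening grid does not cover all sticks")
    norm = 1.0 / (sigma * math.sqrt(2.0 * math.pi))
    for f, a in zip(s.frequencies, s.intensities):
        y += a * norm * np.exp(-0.5 * ((grid - f) / sigma) ** 2)
    return ExperimentalTrace(grid, y, kind="gain")


def _as_positive(trace: ExperimentalTrace) -> np.ndarray:
    y = trace.intensities.astype(float)
    return -y if trace.kind == "depletion" else y


def match_score(curve: ExperimentalTrace, trace: ExperimentalTrace) -> float:
    """Cosine similarity in [-1, 1] of the two spectra on their common grid.

    Both inputs are baseline-subtracted (minimum removed) and
    max-normalized, so the score is invariant under positive rescaling
    and offsets of either input.  Depletion traces are sign-flipped first.
    """
    lo = max(curve.wavenumbers.min(), trace.wavenumbers.min())
    hi = min(curve.wavenumbers.max(), trace.wavenumbers.max())
    if lo >= hi:
        raise ValueError("spectra have no overlapping wavenumber range")
    grid = np.linspace(lo, hi, 2048)

    def prep(t: ExperimentalTrace) -> np.ndarray:
        y = np.interp(grid, t.wavenumbers, _as_positive(t))
        y = y - y.mean()  # baseline removal keeps negation anti-correlated
        peak = np.abs(y).max()
        return y / peak if peak > 0 else y

    a, b = prep(curve), prep(trace)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


#: free carboxyl O-H stretch window after scaling, cm^-1 (closed interval)
FREE_OH_WINDOW = (3550.0, 3600.0)


def free_oh_diagnostic(
    s: StickSpectrum, window: tuple[float, float] = FREE_OH_WINDOW
) -> bool:
    """True iff >= 1 stick lies in the free-OH stretch window (inclusive)."""
    lo, hi = window
    return bool(np.any((s.frequencies >= lo) & (s.frequencies <= hi)))
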