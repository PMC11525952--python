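"""Torsion fingerprint deviation (TFD) and uniqueness filtering.

TFD between two conformers of the same topology is the weighted mean of
per-torsion minimal periodic angular deviations, normalized by 180°, so
it lives in [0, 1].  Deduplication is a greedy pass that keeps a
conformer iff it is at least ``threshold`` away from everything kept so
far.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TorsionFingerprint", "tfd", "dedupe", "fingerprint_from_torsions"]


@dataclass
class TorsionFingerprint:
    """Ordered torsion values with weights and per-torsion symmetry periods."""

    values: np.ndarray  # degrees, wrapped to [-180, 180)
    weights: np.ndarray | None = None
    periods: np.ndarray | None = None  # 360 generic, 180 for 2-fold ends

    def __post_init__(self) -> None:
        self.values = wrap_angles(np.asarray(self.values, dtype=float))
        n = self.values.size
        if self.weights is None:
            self.weights = np.ones(n)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
        if self.periods is None:
            self.periods = np.full(n, 360.0)
        else:
            self.periods = np.asarray(self.periods, dtype=float)
        if self.weights.size != n or self.periods.size != n:
            raise ValueError("weights/periods must match torsion count")
        if np.any(self.weights < 0) or not np.any(self.weights > 0):
            raise ValueError("weights must be >= 0 with at least one > 0")


def wrap_angles(angles: np.ndarray) -> np.ndarray:
    """Wrap to [-180, 180)."""
    return (np.asarray(angles, dtype=float) + 180.0) % 360.0 - 180.0


def fingerprint_from_torsions(
    values, weights=None, periods=None
) -> TorsionFingerprint:
    return TorsionFingerprint(np.asarray(values, float), weights, periods)


def tfd(a: TorsionFingerprint, b: TorsionFingerprint) -> float:
    """Weighted normalized torsion deviation in [0, 1].

    Each per-torsion deviation is the minimal angular distance modulo the
    torsion's symmetry period, divided by 180° so a full anti alignment of
    a 360°-periodic torsion scores 1.
    """
    if a.values.size != b.values.size:
        raise ValueError(
            f"mismatched torsion counts ({a.values.size} vs {b.values.size})"
        )
    if not np.array_equal(a.periods, b.periods):
        raise ValueError("fingerprints disagree on symmetry periods")
    diff = np.abs(a.values - b.values) % a.periods
    dev = np.minimum(diff, a.periods - diff)
    w = a.weights
    return float(np.sum(w * dev / 180.0) / np.sum(w))


def dedupe(items: list, threshold: float, key=None) -> list:
    """Greedy uniqueness filter in input order.

    ``items`` are conformers or fingerprints; ``key`` maps an item to its
    TorsionFingerprint (identity by default).  An item is kept iff its TFD
    to every already-kept item is >= threshold.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    key = key or (lambda x: x)
    kept: list = []
    kept_fps: list[TorsionFingerprint] = []
    for item in items:
        fp = key(item)
        if all(tfd(fp, other) >= threshold for other in kept_fps):
            kept.append(item)
            kept_fps.append(fp)
    return kept


def auto_periods(topology) -> np.ndarray:
    """Symmetry periods per topology torsion: 180° when the torsion's far
    end is a 2-fold symmetric group (carboxylate, phenyl), else 360°."""
    periods = np.full(len(topology.torsions), 360.0)
    ring_atoms = {i for ring in topology.rings for i in ring}
    carbox_c = set()
    for a in getattr(topology, "anionic_sites", []):
        for i, j in topology.bonds:
            if a == i:
                carbox_c.add(j)
            elif a == j:
                carbox_c.add(i)
    for t_idx, (_a, b, c, _d) in enumerate(topology.torsions):
        if b in ring_atoms or c in ring_atoms or b in carbox_c or c in carbox_c:
            periods[t_idx] = 180.0
    return periods
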