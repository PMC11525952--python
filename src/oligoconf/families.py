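"""Interaction-fingerprint family clustering and candidate selection.

Conformers are grouped into families by exact equality of their
interaction pattern — the sorted sets of hydrogen-bond pairs and
proton–π contacts plus the charge location — and per family only the
minimum-energy structure within the energy cutoff (default 10 kcal/mol
relative to the pool minimum) survives into the candidate pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .peptide_model import (
    Conformation,
    GeometricCriteria,
    find_hbonds,
    find_pion_contacts,
)

__all__ = [
    "InteractionFingerprint",
    "FamilyConfig",
    "fingerprint",
    "cluster_families",
    "select_candidates",
]


@dataclass(frozen=True)
class InteractionFingerprint:
    hbonds: frozenset  # of (donor atom id, acceptor atom id)
    pion: frozenset  # of (charged site id, ring id)
    charge_location: str

    def __str__(self) -> str:
        hb = ";".join(f"{d}->{a}" for d, a in sorted(self.hbonds))
        pp = ";".join(f"{s}~{r}" for s, r in sorted(self.pion))
        return f"hb[{hb}]|pion[{pp}]|q[{self.charge_location}]"


@dataclass
class FamilyConfig:
    energy_cutoff: float = 10.0  # kcal/mol relative to the pool minimum
    per_stratum: bool = False  # reference per charge location vs global

    def __post_init__(self) -> None:
        if self.energy_cutoff <= 0:
            raise ValueError("energy cutoff must be positive")


def fingerprint(
    conf: Conformation, crit: GeometricCriteria | None = None
) -> InteractionFingerprint:
    """Interaction fingerprint of a conformation (rotation-invariant)."""
    hbonds = frozenset((d, a) for d, _h, a in find_hbonds(conf, crit))
    pion = frozenset((s, r) for s, r, _dist, _same in find_pion_contacts(conf, crit))
    topo = conf.topology
    if topo.spec is not None:
        charge = topo.spec.protonation.charge_location
    else:
        charge = ",".join(str(i) for i in topo.charged_sites) or "neutral"
    return InteractionFingerprint(hbonds, pion, charge)


def cluster_families(
    confs: list[Conformation],
    config: FamilyConfig | None = None,
    crit: GeometricCriteria | None = None,
) -> dict[InteractionFingerprint, list[Conformation]]:
    """Partition conformers into families keyed by fingerprint.

    Family members are sorted by energy (provenance string breaks ties).
    """
    for conf in confs:
        if conf.energy is None:
            raise ValueError(
                f"conformer {conf.label or conf.seed_provenance!r} has no energy"
            )
    families: dict[InteractionFingerprint, list[Conformation]] = {}
    for conf in confs:
        families.setdefault(fingerprint(conf, crit), []).append(conf)
    for members in families.values():
        members.sort(key=lambda c: (c.energy, c.seed_provenance, c.label))
    return families


def select_candidates(
    families: dict[InteractionFingerprint, list[Conformation]],
    config: FamilyConfig | None = None,
) -> list[Conformation]:
    """Per family keep the minimum iff its relative energy is within the
    cutoff; output sorted by relative energy.

    With ``per_stratum`` the reference minimum is computed separately for
    each charge location, otherwise globally over the whole pool.
    """
    config = config or FamilyConfig()
    if not families:
        return []
    minima = {fp: members[0] for fp, members in families.items() if members}
    if config.per_stratum:
        ref: dict[str, float] = {}
        for fp, conf in minima.items():
            key = fp.charge_location
            ref[key] = min(ref.get(key, np.inf), conf.energy)
        rel = {fp: c.energy - ref[fp.charge_location] for fp, c in minima.items()}
    else:
        e0 = min(c.energy for c in minima.values())
        rel = {fp: c.energy - e0 for fp, c in minima.items()}
    kept = [(rel[fp], c) for fp, c in minima.items() if rel[fp] <= config.energy_cutoff]
    kept.sort(key=lambda t: (t[0], t[1].seed_provenance, t[1].label))
    return [c for _r, c in kept]
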