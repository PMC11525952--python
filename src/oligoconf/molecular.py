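"""Bridge between torsion-space search and Cartesian molecular models."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdMolTransforms

from .energy_opt import EnergyBackend
from .peptide_model import Conformation, Topology

__all__ = ["set_torsions", "get_torsions", "TopologyEnvironment"]


def set_torsions(topology: Topology, values: np.ndarray) -> np.ndarray:
    """Cartesian coordinates with the topology's rotatable torsions set to
    ``values`` (degrees), starting from the build geometry."""
    if topology.mol is None:
        raise ValueError("topology carries no RDKit molecule")
    if len(values) != len(topology.torsions):
        raise ValueError("torsion value count mismatch")
    mol = Chem.Mol(topology.mol)
    conf = mol.GetConformer()
    for (a, b, c, d), val in zip(topology.torsions, values):
        rdMolTransforms.SetDihedralDeg(conf, a, b, c, d, float(val))
    return np.array(conf.GetPositions())


def get_torsions(topology: Topology, coords: np.ndarray) -> np.ndarray:
    """Measure the rotatable torsions (degrees) of a geometry."""
    if topology.mol is None:
        raise ValueError("topology carries no RDKit molecule")
    mol = Chem.Mol(topology.mol)
    conf = mol.GetConformer()
    for i, p in enumerate(np.asarray(coords, float)):
        conf.SetAtomPosition(i, p.tolist())
    return np.array(
        [rdMolTransforms.GetDihedralDeg(conf, *t) for t in topology.torsions]
    )


@dataclass
class TopologyEnvironment:
    """Torsion environment over a built oligomer and an energy backend.

    ``charge_labels`` may map several protonation states of the same size
    to their own (topology, backend) pair while a single policy is
    shared; the default wraps one state.
    """

    topology: Topology
    backend: EnergyBackend
    charge_labels: tuple[str, ...] = ("state0",)

    @property
    def n_torsions(self) -> int:
        return len(self.topology.torsions)

    def energy(self, torsions: np.ndarray, charge_index: int = 0) -> float:
        coords = set_torsions(self.topology, torsions)
        return float(self.backend.energy(coords))

    def is_valid(self, torsions: np.ndarray) -> bool:
        coords = set_torsions(self.topology, torsions)
        return Conformation(self.topology, coords).is_valid()

    def conformation(self, torsions: np.ndarray, label: str = "") -> Conformation:
        return Conformation(
            self.topology, set_torsions(self.topology, torsions), label=label
        )
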