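"""Oligomer topologies, protonation states and geometric predicates.

Builds noncovalent oligomers of peptide units (e.g. n copies of the
Phe-Phe dipeptide) with explicit protonation, and provides the geometric
predicates used throughout: hydrogen-bond detection, proton–π contacts
between charged ammonium groups and aromatic rings, the free-carboxyl-OH
diagnostic, and the charge–chromophore proximity filter derived from UV
band-origin shifts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

__all__ = [
    "ResidueTemplate",
    "ProtonationState",
    "OligomerSpec",
    "Topology",
    "Conformation",
    "GeometricCriteria",
    "DEFAULT_RESIDUES",
    "build_oligomer",
    "build_unit_mol",
    "initial_conformation",
    "peptide_smiles",
    "find_hbonds",
    "find_pion_contacts",
    "has_free_OH",
    "uv_constraint_filter",
]

UNIT_LABELS = ("neutral", "protonated", "zwitterion")


def _load_default_residues() -> dict[str, str]:
    import yaml

    path = Path(__file__).parent / "data" / "residues.yaml"
    return dict(yaml.safe_load(path.read_text()))


#: residue name -> side-chain SMILES fragment attached at the alpha carbon
DEFAULT_RESIDUES: dict[str, str] = _load_default_residues()


def load_residue_table(path) -> dict[str, str]:
    """User residue table (YAML mapping name -> side-chain SMILES)."""
    import yaml

    return dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class ResidueTemplate:
    """Reference chemistry/geometry of a single residue."""

    name: str
    atoms: list[tuple[str, np.ndarray]]
    bonds: list[tuple[int, int, int]]
    rotatable_torsions: list[tuple[int, int, int, int]] = field(default_factory=list)
    donor_atoms: list[int] = field(default_factory=list)
    acceptor_atoms: list[int] = field(default_factory=list)
    ring_atoms: list[list[int]] = field(default_factory=list)

    def validate(self) -> None:
        n = len(self.atoms)
        adj: dict[int, set[int]] = {i: set() for i in range(n)}
        for i, j, _order in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        seen = {0}
        stack = [0]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if len(seen) != n:
            raise ValueError(f"bond graph of {self.name} is not connected")
        for t in self.rotatable_torsions:
            for a, b in zip(t, t[1:]):
                if b not in adj[a]:
                    raise ValueError(f"torsion {t} atoms not bonded in chain")
        for ring in self.ring_atoms:
            if len(ring) < 5:
                raise ValueError("ring lists must have >= 5 atoms")


@dataclass(frozen=True)
class ProtonationState:
    """Per-unit charge assignment of an oligomer.

    ``labels[i]`` is one of ``neutral`` (pn partner), ``protonated``
    (NH3+, COOH intact, contributes +1) or ``zwitterion`` (NH3+ and COO-,
    net 0).
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        for lab in self.labels:
            if lab not in UNIT_LABELS:
                raise ValueError(f"unknown protonation label {lab!r}")

    @property
    def net_charge(self) -> int:
        return sum(1 for lab in self.labels if lab == "protonated")

    @property
    def kind(self) -> str:
        """Charge form: 'pn' (charge-solvated) or 'pz' (salt-bridge)."""
        if "zwitterion" in self.labels:
            return "pz"
        return "pn"

    @property
    def charge_location(self) -> str:
        """Hashable charge-location key used for family stratification."""
        sites = [f"{i}:{lab[0]}" for i, lab in enumerate(self.labels)
                 if lab != "neutral"]
        return ",".join(sites) or "neutral"


@dataclass(frozen=True)
class OligomerSpec:
    n_units: int
    charge: int
    protonation: ProtonationState

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be positive")
        if len(self.protonation.labels) != self.n_units:
            raise ValueError("protonation labels must cover every unit")
        if self.protonation.net_charge != self.charge:
            raise ValueError(
                f"protonation net charge {self.protonation.net_charge} "
                f"inconsistent with declared charge {self.charge}"
            )


@dataclass
class Topology:
    """Concatenated atoms/bonds of all units plus derived metadata."""

    elements: list[str]
    bonds: list[tuple[int, int]]
    unit_of: list[int]
    residue_of: list[tuple[int, int]]  # (unit, residue index within unit)
    torsions: list[tuple[int, int, int, int]]
    formula: dict[str, int]
    donors: list[tuple[int, int]]  # (heavy donor, attached H)
    acceptors: list[int]
    rings: list[list[int]]  # aromatic ring atom index lists
    charged_sites: list[int]  # formally positive atoms (ammonium N)
    anionic_sites: list[int] = field(default_factory=list)
    spec: OligomerSpec | None = None
    mol: Chem.Mol | None = None  # RDKit handle when built from chemistry

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


@dataclass
class Conformation:
    topology: Topology
    coords: np.ndarray
    energy: float | None = None
    label: str = ""
    seed_provenance: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.topology.n_atoms, 3):
            raise ValueError(
                f"coordinate shape {self.coords.shape} does not match "
                f"{self.topology.n_atoms} atoms"
            )

    def min_distance(self) -> float:
        d = self.coords[:, None, :] - self.coords[None, :, :]
        dist = np.sqrt((d**2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        return float(dist.min())

    def is_valid(self, min_dist: float = 0.7) -> bool:
        return self.topology.n_atoms < 2 or self.min_distance() > min_dist


@dataclass
class GeometricCriteria:
    """Distance/angle thresholds for the interaction predicates."""

    hbond_max_DA_distance: float = 3.5  # Å, donor–acceptor heavy atoms
    hbond_min_DHA_angle: float = 120.0  # degrees
    pion_max_centroid_distance: float = 5.0  # Å, charged N to ring centroid

    def __post_init__(self) -> None:
        if self.hbond_max_DA_distance <= 0 or self.pion_max_centroid_distance <= 0:
            raise ValueError("distance criteria must be positive")
        if not 0.0 < self.hbond_min_DHA_angle < 180.0:
            raise ValueError("angle criterion must lie in (0, 180) degrees")


# ---------------------------------------------------------------------------
# oligomer construction
# ---------------------------------------------------------------------------

def peptide_smiles(
    sequence: list[str],
    templates: dict[str, str],
    n_terminus: str = "NH2",
    c_terminus: str = "COOH",
) -> str:
    """Linear peptide SMILES from residue side-chain fragments."""
    parts = []
    for name in sequence:
        try:
            side = templates[name]
        except KeyError:
            raise KeyError(f"unknown residue name {name!r}") from None
        parts.append(f"C({side})C(=O)" if side != "[H]" else "CC(=O)")
    nterm = {"NH2": "N", "NH3+": "[NH3+]"}[n_terminus]
    cterm = {"COOH": "O", "COO-": "[O-]"}[c_terminus]
    return nterm + "N".join(parts) + cterm


def build_unit_mol(
    label: str,
    sequence: list[str] | None = None,
    templates: dict[str, str] | None = None,
    seed: int = 0,
) -> Chem.Mol:
    """Embedded 3D RDKit mol of one peptide unit in a protonation state."""
    sequence = sequence or ["Phe", "Phe"]
    templates = templates or DEFAULT_RESIDUES
    if label == "neutral":
        smi = peptide_smiles(sequence, templates, "NH2", "COOH")
    elif label == "protonated":
        smi = peptide_smiles(sequence, templates, "NH3+", "COOH")
    elif label == "zwitterion":
        smi = peptide_smiles(sequence, templates, "NH3+", "COO-")
    else:
        raise ValueError(f"unknown protonation label {label!r}")
    mol = Chem.MolFromSmiles(smi)
    if mol is None:
        raise ValueError(f"failed to parse peptide SMILES {smi!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise RuntimeError("3D embedding failed")
    return mol


def _rotatable_torsions(mol: Chem.Mol) -> list[tuple[int, int, int, int]]:
    """Four-atom tuples for every non-ring single bond between heavy atoms
    that each carry at least one other heavy/H neighbor (includes the
    C-terminal O-H torsion)."""
    torsions = []
    for bond in mol.GetBonds():
        if bond.IsInRing() or bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        b, c = bond.GetBeginAtom(), bond.GetEndAtom()
        if b.GetAtomicNum() == 1 or c.GetAtomicNum() == 1:
            continue
        if b.GetDegree() < 2 or c.GetDegree() < 2:
            continue

        def anchor(atom, other):
            nbrs = [a for a in atom.GetNeighbors() if a.GetIdx() != other.GetIdx()]
            nbrs.sort(key=lambda a: (-a.GetAtomicNum(), a.GetIdx()))
            return nbrs[0].GetIdx()

        torsions.append((anchor(b, c), b.GetIdx(), c.GetIdx(), anchor(c, b)))
    return sorted(torsions, key=lambda t: (t[1], t[2]))


def _residue_index_map(mol: Chem.Mol, sequence_len: int) -> list[int]:
    """Assign each atom to a residue by walking backbone carbonyl carbons."""
    # carbonyl carbons of the backbone in order delimit residues
    pattern = Chem.MolFromSmarts("[CX3](=O)[OX2H1,OX1-,NX3]")
    carbonyls = sorted({m[0] for m in mol.GetSubstructMatches(pattern)})
    boundaries = carbonyls[:sequence_len]
    assignment = [0] * mol.GetNumAtoms()
    # BFS from N-terminus in atom-index order approximates sequence order;
    # atoms are emitted by RDKit in SMILES order so index thresholds work
    res = 0
    for idx in range(mol.GetNumAtoms()):
        atom = mol.GetAtomWithIdx(idx)
        if atom.GetAtomicNum() == 1:
            nbr = atom.GetNeighbors()[0].GetIdx()
            assignment[idx] = assignment[nbr] if nbr < idx else res
            continue
        assignment[idx] = res
        if res < len(boundaries) and idx >= boundaries[res]:
            # move to next residue after passing this residue's carbonyl C
            if idx >= boundaries[res] + 1:
                res = min(res + 1, sequence_len - 1)
    # second pass: hydrogens follow their heavy atom
    for idx in range(mol.GetNumAtoms()):
        atom = mol.GetAtomWithIdx(idx)
        if atom.GetAtomicNum() == 1:
            assignment[idx] = assignment[atom.GetNeighbors()[0].GetIdx()]
    return assignment


def _rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def build_oligomer(
    spec: OligomerSpec,
    templates: dict[str, str] | None = None,
    sequence: list[str] | None = None,
    seed: int = 0,
    grid_spacing: float = 6.0,
) -> Topology:
    """Assemble a noncovalent oligomer topology with initial coordinates.

    Units are embedded independently and placed on a seeded grid with
    random orientations (initialization convention; the search explores
    inter-unit geometry afterwards).
    """
    sequence = sequence or ["Phe", "Phe"]
    templates = templates or DEFAULT_RESIDUES
    rng = np.random.default_rng(seed)

    elements: list[str] = []
    bonds: list[tuple[int, int]] = []
    unit_of: list[int] = []
    residue_of: list[tuple[int, int]] = []
    torsions: list[tuple[int, int, int, int]] = []
    donors: list[tuple[int, int]] = []
    acceptors: list[int] = []
    rings: list[list[int]] = []
    charged: list[int] = []
    anionic: list[int] = []
    formula: dict[str, int] = {}
    coords_blocks: list[np.ndarray] = []
    unit_mols: list[Chem.Mol] = []

    side = max(1, int(math.ceil(spec.n_units ** (1.0 / 3.0))))
    unit_xyz: list[np.ndarray] = []
    for u, label in enumerate(spec.protonation.labels):
        mol = build_unit_mol(label, sequence, templates, seed=seed + u)
        unit_mols.append(mol)
        xyz = np.array(mol.GetConformer().GetPositions())
        xyz -= xyz.mean(axis=0)
        unit_xyz.append(xyz @ _rotation_matrix(rng).T)
    # grid pitch: requested inter-unit gap plus the largest unit diameter,
    # so freshly placed units never clash
    diameter = max(
        (2.0 * float(np.linalg.norm(x, axis=1).max()) for x in unit_xyz),
        default=0.0,
    )
    pitch = grid_spacing + diameter if spec.n_units > 1 else grid_spacing
    for u, label in enumerate(spec.protonation.labels):
        mol = unit_mols[u]
        offset = len(elements)
        xyz = unit_xyz[u].copy()
        cell = np.array([u % side, (u // side) % side, u // (side * side)], float)
        xyz += cell * pitch
        coords_blocks.append(xyz)

        res_map = _residue_index_map(mol, len(sequence))
        for atom in mol.GetAtoms():
            el = atom.GetSymbol()
            elements.append(el)
            formula[el] = formula.get(el, 0) + 1
            unit_of.append(u)
            residue_of.append((u, res_map[atom.GetIdx()]))
            if atom.GetFormalCharge() > 0:
                charged.append(offset + atom.GetIdx())
            if atom.GetFormalCharge() < 0:
                anionic.append(offset + atom.GetIdx())
            if atom.GetAtomicNum() in (7, 8):
                hs = [n.GetIdx() for n in atom.GetNeighbors() if n.GetAtomicNum() == 1]
                for h in hs:
                    donors.append((offset + atom.GetIdx(), offset + h))
                if not (atom.GetAtomicNum() == 7 and atom.GetFormalCharge() > 0):
                    acceptors.append(offset + atom.GetIdx())
        for bond in mol.GetBonds():
            bonds.append(
                (offset + bond.GetBeginAtomIdx(), offset + bond.GetEndAtomIdx())
            )
        for t in _rotatable_torsions(mol):
            torsions.append(tuple(offset + i for i in t))
        for ring in mol.GetRingInfo().AtomRings():
            if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
                rings.append([offset + i for i in ring])

    combined = unit_mols[0]
    for m in unit_mols[1:]:
        combined = Chem.CombineMols(combined, m)
    combined = Chem.RWMol(combined)
    conf = Chem.Conformer(combined.GetNumAtoms())
    allxyz = np.vstack(coords_blocks)
    for i, p in enumerate(allxyz):
        conf.SetAtomPosition(i, p.tolist())
    combined.RemoveAllConformers()
    combined.AddConformer(conf)

    topo = Topology(
        elements=elements,
        bonds=bonds,
        unit_of=unit_of,
        residue_of=residue_of,
        torsions=torsions,
        formula=formula,
        donors=donors,
        acceptors=acceptors,
        rings=rings,
        charged_sites=charged,
        anionic_sites=anionic,
        spec=spec,
        mol=combined.GetMol(),
    )
    topo.initial_coords = allxyz  # type: ignore[attr-defined]
    return topo


def initial_conformation(topology: Topology, label: str = "seed") -> Conformation:
    coords = getattr(topology, "initial_coords", None)
    if coords is None:
        raise ValueError("topology carries no initial coordinates")
    return Conformation(topology, coords.copy(), label=label,
                        seed_provenance="build_oligomer")


def template_from_mol(mol: Chem.Mol, name: str) -> ResidueTemplate:
    """ResidueTemplate (with reference geometry and chemistry metadata)
    from an embedded RDKit molecule."""
    if mol.GetNumConformers() == 0:
        params = AllChem.ETKDGv3()
        params.randomSeed = 0
        mol = Chem.AddHs(mol)
        AllChem.EmbedMolecule(mol, params)
    pos = np.array(mol.GetConformer().GetPositions())
    atoms = [(a.GetSymbol(), pos[a.GetIdx()]) for a in mol.GetAtoms()]
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), int(b.GetBondTypeAsDouble()))
        for b in mol.GetBonds()
    ]
    donors, acceptors = [], []
    for a in mol.GetAtoms():
        if a.GetAtomicNum() in (7, 8):
            if any(n.GetAtomicNum() == 1 for n in a.GetNeighbors()):
                donors.append(a.GetIdx())
            if not (a.GetAtomicNum() == 7 and a.GetFormalCharge() > 0):
                acceptors.append(a.GetIdx())
    rings = [
        list(r)
        for r in mol.GetRingInfo().AtomRings()
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in r)
    ]
    tmpl = ResidueTemplate(
        name=name,
        atoms=atoms,
        bonds=bonds,
        rotatable_torsions=_rotatable_torsions(mol),
        donor_atoms=donors,
        acceptor_atoms=acceptors,
        ring_atoms=rings,
    )
    tmpl.validate()
    return tmpl


def template_from_sdf(path, name: str | None = None) -> ResidueTemplate:
    """Load a user residue/monomer template from an SDF file."""
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    mol = next((m for m in supplier if m is not None), None)
    if mol is None:
        raise ValueError(f"no readable molecule in {path}")
    return template_from_mol(mol, name or mol.GetProp("_Name") or "template")


# ---------------------------------------------------------------------------
# geometric predicates
# ---------------------------------------------------------------------------

def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def find_hbonds(
    conf: Conformation, crit: GeometricCriteria | None = None
) -> list[tuple[int, int, int]]:
    """(donor, H, acceptor) triples satisfying the distance/angle criteria.

    Criteria: donor–acceptor heavy-atom distance <= cutoff and D-H...A
    angle >= threshold.  Output sorted by (donor, H, acceptor) index.
    """
    crit = crit or GeometricCriteria()
    xyz = conf.coords
    out = []
    for d, h in conf.topology.donors:
        for a in conf.topology.acceptors:
            if a == d:
                continue
            if np.linalg.norm(xyz[d] - xyz[a]) > crit.hbond_max_DA_distance:
                continue
            if _angle_deg(xyz[d], xyz[h], xyz[a]) >= crit.hbond_min_DHA_angle:
                out.append((d, h, a))
    return sorted(out)


def find_pion_contacts(
    conf: Conformation, crit: GeometricCriteria | None = None
) -> list[tuple[int, int, float, bool]]:
    """(charged atom, ring id, centroid distance, same_residue) contacts.

    Sorted by distance, ties broken by ring id.
    """
    crit = crit or GeometricCriteria()
    topo = conf.topology
    xyz = conf.coords
    out = []
    for site in topo.charged_sites:
        for ring_id, ring in enumerate(topo.rings):
            centroid = xyz[ring].mean(axis=0)
            dist = float(np.linalg.norm(xyz[site] - centroid))
            if dist <= crit.pion_max_centroid_distance:
                same = topo.residue_of[site] == topo.residue_of[ring[0]]
                out.append((site, ring_id, dist, same))
    return sorted(out, key=lambda t: (t[2], t[1], t[0]))


def _carboxyl_oh_hydrogens(conf: Conformation) -> list[int]:
    """H atoms of hydroxyl oxygens (O donors)."""
    return [h for d, h in conf.topology.donors
            if conf.topology.elements[d] == "O"]


def has_free_OH(
    conf: Conformation, crit: GeometricCriteria | None = None
) -> bool:
    """True iff at least one carboxyl O-H donates no hydrogen bond.

    The free-OH stretch is the spectral fingerprint separating
    charge-solvated from salt-bridge structures.
    """
    oh_hs = _carboxyl_oh_hydrogens(conf)
    if not oh_hs:
        raise ValueError("topology has no carboxylic OH group")
    bonded_hs = {h for _d, h, _a in find_hbonds(conf, crit)}
    return any(h not in bonded_hs for h in oh_hs)


def uv_constraint_filter(
    confs: list[Conformation],
    mode: str,
    crit: GeometricCriteria | None = None,
) -> tuple[list[Conformation], list[Conformation]]:
    """Partition conformers by the UV-derived charge–ring proximity rule.

    monomer: the charged N-terminus must contact the C-terminal residue's
    ring of the same unit.  dimer: the charged N-terminus must contact a
    ring of a *different* residue.
    """
    if mode not in ("monomer", "dimer"):
        raise ValueError(f"unknown mode {mode!r}")
    passed, failed = [], []
    for conf in confs:
        topo = conf.topology
        contacts = find_pion_contacts(conf, crit)
        ok = False
        for site, ring_id, _dist, same in contacts:
            if mode == "monomer":
                ring_res = topo.residue_of[topo.rings[ring_id][0]]
                site_unit = topo.residue_of[site][0]
                n_res = max(r for u, r in topo.residue_of if u == site_unit)
                if ring_res == (site_unit, n_res):
                    ok = True
            else:
                if not same:
                    ok = True
        (passed if ok else failed).append(conf)
    return passed, failed
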