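"""Plain-text structure I/O: multi-frame XYZ and single-model PDB.

XYZ comments carry ``label=... energy=...`` key/value provenance so
conformer ensembles round-trip losslessly (coordinates to 1e-4 Å by
format precision choice: 6 decimals are written).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .peptide_model import Conformation, Topology

__all__ = ["write_xyz", "read_xyz", "read_xyz_raw", "write_pdb", "read_pdb"]


def _frame_comment(conf: Conformation) -> str:
    parts = []
    if conf.label:
        parts.append(f"label={conf.label}")
    if conf.energy is not None:
        parts.append(f"energy={conf.energy:.10g}")
    return " ".join(parts)


def write_xyz(path, confs, comment: str | None = None) -> None:
    """Write one or more conformations as a multi-frame XYZ file."""
    if isinstance(confs, Conformation):
        confs = [confs]
    lines = []
    for conf in confs:
        lines.append(str(conf.topology.n_atoms))
        lines.append(comment if comment is not None else _frame_comment(conf))
        for el, (x, y, z) in zip(conf.topology.elements, conf.coords):
            lines.append(f"{el:<3s} {x:16.6f} {y:16.6f} {z:16.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz_raw(path) -> list[tuple[list[str], np.ndarray, str]]:
    """All frames as (elements, coords, comment)."""
    text = Path(path).read_text().splitlines()
    frames = []
    i = 0
    while i < len(text):
        line = text[i].strip()
        if not line:
            i += 1
            continue
        n = int(line)
        comment = text[i + 1] if i + 1 < len(text) else ""
        elements, coords = [], []
        for j in range(n):
            parts = text[i + 2 + j].split()
            elements.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
        frames.append((elements, np.array(coords), comment))
        i += 2 + n
    return frames


def _parse_comment(comment: str) -> dict[str, str]:
    out = {}
    for tok in comment.split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            out[k] = v
    return out


def read_xyz(path, topology: Topology) -> list[Conformation]:
    """Read frames against a known topology (element check enforced)."""
    confs = []
    for elements, coords, comment in read_xyz_raw(path):
        if elements != topology.elements:
            raise ValueError(
                f"XYZ frame elements do not match topology in {path}"
            )
        meta = _parse_comment(comment)
        conf = Conformation(
            topology,
            coords,
            energy=float(meta["energy"]) if "energy" in meta else None,
            label=meta.get("label", ""),
        )
        confs.append(conf)
    return confs


def write_pdb(path, conf: Conformation) -> None:
    """Single-model PDB with HETATM records (noncovalent complexes)."""
    topo = conf.topology
    lines = ["MODEL     1"]
    for i, (el, (x, y, z)) in enumerate(zip(topo.elements, conf.coords), 1):
        unit = topo.unit_of[i - 1] + 1 if topo.unit_of else 1
        lines.append(
            f"HETATM{i:5d} {el:<4s}LIG {chr(64 + min(unit, 26))}{unit:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}"
        )
    lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pdb(path, topology: Topology) -> Conformation:
    elements, coords = [], []
    for line in Path(path).read_text().splitlines():
        if line.startswith(("ATOM", "HETATM")):
            elements.append(line[76:78].strip() or line[12:16].strip()[:1])
            coords.append(
                [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            )
    if elements != topology.elements:
        raise ValueError(f"PDB atoms do not match topology in {path}")
    return Conformation(topology, np.array(coords))
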