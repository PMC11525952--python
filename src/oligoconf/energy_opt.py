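"""Energy backends, local geometry optimization and numerical Hessians.

The internal production backend is MMFF94 via RDKit (force-field level by
design; DFT-quality energetics are delegated to the external-optimizer
adapter).  Toy backends (harmonic wells, periodic torsion landscapes) back
the test oracles.  The optimizer is BFGS with backtracking line search so
the energy trace is monotone by construction.
"""

from __future__ import annotations

import re
import shlex
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol

import numpy as np

from .constants import ATOMIC_MASS_FOR_ELEMENT
from .peptide_model import Conformation

__all__ = [
    "EnergyBackend",
    "FunctionBackend",
    "HarmonicBackend",
    "MMFFBackend",
    "OptimizationResult",
    "minimize",
    "minimize_conformation",
    "numerical_hessian",
    "mass_weight_hessian",
    "ExternalAdapterConfig",
    "external_optimize",
]


class EnergyBackend(Protocol):
    """Contract: energies in kcal/mol, gradients in kcal/mol/Å."""

    name: str
    supports_gradient: bool

    def energy(self, x: np.ndarray) -> float: ...

    def gradient(self, x: np.ndarray) -> np.ndarray: ...


@dataclass
class FunctionBackend:
    """Backend from plain callables; gradient falls back to central
    differences when not supplied."""

    name: str
    energy_fn: Callable[[np.ndarray], float]
    gradient_fn: Callable[[np.ndarray], np.ndarray] | None = None
    fd_step: float = 1e-6
    supports_gradient: bool = True

    def energy(self, x: np.ndarray) -> float:
        return float(self.energy_fn(np.asarray(x, float)))

    def gradient(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.gradient_fn is not None:
            return np.asarray(self.gradient_fn(x), dtype=float)
        g = np.zeros_like(x.ravel())
        flat = x.ravel().copy()
        for i in range(flat.size):
            flat[i] += self.fd_step
            ep = self.energy_fn(flat.reshape(x.shape))
            flat[i] -= 2 * self.fd_step
            em = self.energy_fn(flat.reshape(x.shape))
            flat[i] += self.fd_step
            g[i] = (ep - em) / (2 * self.fd_step)
        return g.reshape(x.shape)


@dataclass
class HarmonicBackend:
    """E = sum_i k_i |x_i - x0_i|^2 — closed-form test backend."""

    x0: np.ndarray
    k: float | np.ndarray = 1.0
    name: str = "harmonic"
    supports_gradient: bool = True

    def energy(self, x: np.ndarray) -> float:
        d = np.asarray(x, float) - self.x0
        return float(np.sum(self.k * d * d))

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return 2.0 * self.k * (np.asarray(x, float) - self.x0)


class MMFFBackend:
    """MMFF94 energies/gradients of an RDKit molecule, kcal/mol units."""

    name = "mmff94"
    supports_gradient = True

    def __init__(self, mol):
        from rdkit.Chem import AllChem

        self._mol = mol
        props = AllChem.MMFFGetMoleculeProperties(mol)
        if props is None:
            raise ValueError("MMFF parameters unavailable for molecule")
        self._props = props
        self._AllChem = AllChem

    def _field(self, x: np.ndarray):
        conf = self._mol.GetConformer()
        for i, p in enumerate(np.asarray(x, float).reshape(-1, 3)):
            conf.SetAtomPosition(i, p.tolist())
        return self._AllChem.MMFFGetMoleculeForceField(self._mol, self._props)

    def energy(self, x: np.ndarray) -> float:
        return float(self._field(x).CalcEnergy())

    def gradient(self, x: np.ndarray) -> np.ndarray:
        ff = self._field(x)
        g = np.array(ff.CalcGrad(), dtype=float)
        return g.reshape(np.asarray(x).shape)


@dataclass
class OptimizationResult:
    x: np.ndarray
    energy: float
    energy_trace: list[float]
    converged: bool
    gradient_norm: float
    n_steps: int
    provenance: str = ""
    conformation: Conformation | None = None


def minimize(
    x0: np.ndarray,
    backend: EnergyBackend,
    gtol: float = 1e-4,
    max_steps: int = 2000,
    max_step: float | None = None,
) -> OptimizationResult:
    """BFGS with backtracking line search; the recorded energy trace is
    non-increasing because only descent steps are accepted.

    ``max_step`` caps the displacement norm per step (useful to keep the
    search basin-preserving on rugged landscapes)."""
    if not getattr(backend, "supports_gradient", True):
        raise ValueError(f"backend {backend.name} does not supply gradients")
    shape = np.asarray(x0, float).shape
    x = np.asarray(x0, float).ravel().copy()
    n = x.size
    H = np.eye(n)  # inverse-Hessian approximation
    e = backend.energy(x.reshape(shape))
    g = backend.gradient(x.reshape(shape)).ravel()
    trace = [e]
    steps = 0
    alpha0 = 1.0  # adaptive trial step: grows through flat regions
    scaled = False
    n_stalled = 0
    converged = float(np.max(np.abs(g))) <= gtol
    while not converged and steps < max_steps:
        p = -H @ g
        if p @ g > 0:  # not a descent direction; reset curvature
            H = np.eye(n)
            p = -g
        alpha = alpha0
        if max_step is not None:
            pnorm = float(np.linalg.norm(p))
            if pnorm > 0:
                alpha = min(alpha, max_step / pnorm)
        ls_ok = False
        for k in range(60):
            x_new = x + alpha * p
            e_new = backend.energy(x_new.reshape(shape))
            if np.isfinite(e_new) and e_new <= e + 1e-4 * alpha * (g @ p):
                ls_ok = True
                break
            alpha *= 0.5
        if not ls_ok:
            break
        alpha0 = min(alpha * 2.0, 1e8) if k == 0 else max(alpha, 1.0)
        g_new = backend.gradient(x_new.reshape(shape)).ravel()
        s, ydiff = x_new - x, g_new - g
        sy = s @ ydiff
        if sy > 1e-12:
            if not scaled:  # standard initial inverse-Hessian scaling
                H = np.eye(n) * (sy / (ydiff @ ydiff))
                scaled = True
            rho = 1.0 / sy
            V = np.eye(n) - rho * np.outer(s, ydiff)
            H = V @ H @ V.T + rho * np.outer(s, s)
        stalled = (e - e_new) <= 1e-14 * max(1.0, abs(e))
        x, e, g = x_new, e_new, g_new
        trace.append(e)
        steps += 1
        converged = float(np.max(np.abs(g))) <= gtol
        n_stalled = n_stalled + 1 if stalled else 0
        if n_stalled >= 5:  # energy at float-precision floor
            break
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("optimization produced non-finite coordinates")
    return OptimizationResult(
        x=x.reshape(shape),
        energy=e,
        energy_trace=trace,
        converged=converged,
        gradient_norm=float(np.max(np.abs(g))),
        n_steps=steps,
        provenance=f"minimize[{backend.name}]",
    )


def minimize_conformation(
    conf: Conformation,
    backend: EnergyBackend,
    gtol: float = 1e-4,
    max_steps: int = 2000,
) -> OptimizationResult:
    res = minimize(conf.coords, backend, gtol=gtol, max_steps=max_steps)
    out = Conformation(
        conf.topology,
        res.x,
        energy=res.energy,
        label=conf.label,
        seed_provenance=f"{conf.seed_provenance};{res.provenance}",
    )
    res.conformation = out
    return res


def numerical_hessian(
    coords: np.ndarray,
    backend: EnergyBackend,
    step: float = 0.005,
) -> np.ndarray:
    """Symmetrized central-difference Hessian, kcal/mol/Å² (not mass
    weighted)."""
    x = np.asarray(coords, float).ravel().copy()
    n = x.size
    H = np.zeros((n, n))
    shape = np.asarray(coords).shape
    for i in range(n):
        x[i] += step
        gp = backend.gradient(x.reshape(shape)).ravel()
        x[i] -= 2 * step
        gm = backend.gradient(x.reshape(shape)).ravel()
        x[i] += step
        if not (np.all(np.isfinite(gp)) and np.all(np.isfinite(gm))):
            raise FloatingPointError(
                f"gradient failure at displacement of coordinate {i}"
            )
        H[i] = (gp - gm) / (2 * step)
    return 0.5 * (H + H.T)


def mass_weight_hessian(H: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """H_ij / sqrt(m_i m_j) with per-atom masses repeated over x,y,z."""
    m = np.repeat(np.asarray(masses, float), 3)
    if m.size != H.shape[0]:
        raise ValueError("mass vector does not match Hessian dimension")
    inv = 1.0 / np.sqrt(m)
    return H * np.outer(inv, inv)


def conformation_hessian(
    conf: Conformation, backend: EnergyBackend, step: float = 0.005
) -> np.ndarray:
    """Mass-weighted Hessian of a conformation (kcal/mol/Å²/amu)."""
    H = numerical_hessian(conf.coords, backend, step)
    masses = np.array(
        [ATOMIC_MASS_FOR_ELEMENT[el] for el in conf.topology.elements]
    )
    return mass_weight_hessian(H, masses)


# ---------------------------------------------------------------------------
# external optimizer adapter
# ---------------------------------------------------------------------------

@dataclass
class ExternalAdapterConfig:
    """Adapter contract for an external quantum-chemistry optimizer.

    ``command`` is a shell template with ``{input}``/``{output}``
    placeholders.  The adapter writes an XYZ input, runs the command, and
    parses the final energy (kcal/mol, ``energy_pattern`` group 1) and
    geometry (XYZ block) from the output file.
    """

    command: str
    name: str = "external"
    energy_pattern: str = r"ENERGY\s*=\s*(-?\d+\.?\d*)"
    workdir: str | None = None


def external_optimize(
    conf: Conformation, adapter: ExternalAdapterConfig
) -> OptimizationResult:
    from .xyzio import read_xyz, write_xyz

    workdir = Path(adapter.workdir or tempfile.mkdtemp(prefix="oligoconf_ext_"))
    workdir.mkdir(parents=True, exist_ok=True)
    inp = workdir / "input.xyz"
    out = workdir / "output.xyz"
    write_xyz(inp, [conf], comment="oligoconf external adapter input")
    cmd = adapter.command.format(input=str(inp), output=str(out))
    try:
        proc = subprocess.run(
            shlex.split(cmd), capture_output=True, text=True, timeout=600
        )
    except FileNotFoundError as exc:
        raise RuntimeError(
            f"external backend unavailable: {exc.filename or cmd!r} not found"
        ) from exc
    if proc.returncode != 0:
        raise RuntimeError(
            f"external backend {adapter.name} failed (exit {proc.returncode}): "
            f"{proc.stderr.strip()[:500]}"
        )
    if not out.exists():
        raise RuntimeError(f"external backend produced no output file {out}")
    try:
        frames = read_xyz(out, conf.topology)
    except Exception as exc:
        raise ValueError(f"malformed adapter output in {out}: {exc}") from exc
    if not frames:
        raise ValueError(f"malformed adapter output in {out}: no frames")
    final = frames[-1]
    text = out.read_text()
    m = re.search(adapter.energy_pattern, text)
    energy = float(m.group(1)) if m else float("nan")
    final.energy = energy
    final.label = conf.label
    final.seed_provenance = f"{conf.seed_provenance};external[{adapter.name}]"
    return OptimizationResult(
        x=final.coords,
        energy=energy,
        energy_trace=[energy],
        converged=True,
        gradient_norm=float("nan"),
        n_steps=1,
        provenance=f"external[{adapter.name}]",
        conformation=final,
    )
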