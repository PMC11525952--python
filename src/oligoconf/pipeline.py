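"""End-to-end orchestration: generate → dedupe → optimize → cluster →
spectra → rank, plus the fixture bundle generator.

Two execution modes share the stage logic: ``toy`` runs on an analytic
double-well torsion landscape (fast, fully checkable against grid-search
oracles) and ``molecular`` runs on a built oligomer with the MMFF94
backend.  A single master seed derives every stage seed, so a rerun with
the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .conformer_generator import (
    GeneratorConfig,
    LandscapeEnvironment,
    generate,
    train,
)
from .dedup_tfd import TorsionFingerprint, dedupe, wrap_angles
from .energy_opt import FunctionBackend, minimize
from .families import FamilyConfig
from .ir_spectra import ScalingScheme, StickSpectrum, apply_scaling, broaden
from .synthetic import DoubleWellLandscape, envelope_mixture, synthetic_trace

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "FixtureSpec", "run_pipeline", "make_fixture"]


@dataclass
class PipelineConfig:
    mode: str = "toy"
    n_torsions: int = 2
    count: int = 50
    seed: int = 0
    dedupe_threshold: float = 0.05
    energy_cutoff: float = 10.0
    charge_labels: tuple[str, ...] = ("pn",)
    generator: GeneratorConfig | None = None
    train_iterations: int = 40
    scaling: ScalingScheme | None = None

    def stage_seed(self, stage: str) -> int:
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big")

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in asdict(self).items()}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _toy_landscapes(config: PipelineConfig) -> list[DoubleWellLandscape]:
    """One landscape per charge label, offsets derived from the seed."""
    rng = np.random.default_rng(config.stage_seed("landscape"))
    out = []
    for _ in config.charge_labels:
        offsets = rng.choice([-120.0, -60.0, 0.0, 60.0, 120.0], config.n_torsions)
        out.append(DoubleWellLandscape(offsets))
    return out


def _basin_key(landscape: DoubleWellLandscape, torsions: np.ndarray) -> tuple:
    """Which well each torsion sits in — the toy analog of an interaction
    fingerprint."""
    u = np.abs(wrap_angles(np.asarray(torsions) - landscape.offsets))
    return tuple(int(ui > landscape.barrier_angle) for ui in u)


def run_pipeline(config: PipelineConfig, out_dir: str | None = None) -> dict:
    """Run all stages; returns (and optionally writes) the run report."""
    if config.mode != "toy":
        raise NotImplementedError(
            "molecular pipeline mode is driven through the API/CLI stages; "
            "run_pipeline orchestrates the toy mode"
        )
    t0 = time.time()
    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [],
        "strata": {},
    }
    landscapes = _toy_landscapes(config)
    env = LandscapeEnvironment(
        energy_fn=landscapes[0].energy,
        n_torsions=config.n_torsions,
        charge_labels=config.charge_labels,
        energy_fns=tuple(ls.energy for ls in landscapes),
    )
    gen_cfg = config.generator or GeneratorConfig(
        seed=config.stage_seed("train") % 2**31,
        max_iterations=config.train_iterations,
    )
    try:
        state = train(env, gen_cfg)
        report["stages"].append({"stage": "train", "iterations": state.iteration})

        for ci, label in enumerate(config.charge_labels):
            landscape = landscapes[ci]
            samples = generate(
                env, state, config.count, config.stage_seed(f"generate:{label}") % 2**31,
                charge_index=ci,
            )
            fps = [TorsionFingerprint(s["torsions"]) for s in samples]
            kept_idx = dedupe(
                list(range(len(samples))),
                config.dedupe_threshold,
                key=lambda i: fps[i],
            )
            backend = FunctionBackend(
                name=f"toy[{label}]",
                energy_fn=landscape.energy,
                gradient_fn=landscape.gradient,
            )
            optimized = []
            for i in kept_idx:
                res = minimize(samples[i]["torsions"], backend, gtol=1e-6)
                optimized.append(
                    {
                        "torsions": wrap_angles(res.x).tolist(),
                        "energy": res.energy,
                        "provenance": samples[i]["provenance"],
                    }
                )
            families: dict[tuple, list[dict]] = {}
            for rec in optimized:
                families.setdefault(
                    _basin_key(landscape, np.array(rec["torsions"])), []
                ).append(rec)
            for members in families.values():
                members.sort(key=lambda r: (r["energy"], r["provenance"]))
            e0 = min(r["energy"] for r in optimized) if optimized else 0.0
            candidates = sorted(
                (
                    members[0]
                    for members in families.values()
                    if members[0]["energy"] - e0 <= config.energy_cutoff
                ),
                key=lambda r: r["energy"],
            )
            # toy "spectra": curvature sticks at each candidate minimum
            spectra = []
            for rec in candidates:
                from .energy_opt import numerical_hessian

                H = numerical_hessian(np.array(rec["torsions"]), backend, step=0.01)
                eig = np.linalg.eigvalsh(0.5 * (H + H.T))
                sticks = StickSpectrum(
                    np.sqrt(np.clip(eig, 1e-12, None)) * 1000.0,
                    np.ones(eig.size),
                    label=rec["provenance"],
                )
                spectra.append(sticks.frequencies.tolist())
            report["strata"][label] = {
                "generated": len(samples),
                "unique": len(kept_idx),
                "families": len(families),
                "candidates": len(candidates),
                "candidate_energies": [round(r["energy"], 9) for r in candidates],
                "candidate_torsions": [
                    [round(v, 6) for v in r["torsions"]] for r in candidates
                ],
                "spectra_sticks": [
                    [round(v, 6) for v in s] for s in spectra
                ],
            }
        for stage in ("generate", "dedupe", "optimize", "cluster", "spectra"):
            report["stages"].append({"stage": stage, "status": "ok"})
    except Exception as exc:  # preserve upstream outputs on stage failure
        report["stages"].append({"stage": "failed", "error": str(exc)})
        report["failed"] = True
        raise
    finally:
        report["wall_time_s"] = round(time.time() - t0, 3)
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            (out / "report.json").write_text(json.dumps(report, indent=2))
    return report


@dataclass
class FixtureSpec:
    n_torsions: int = 2
    trace_noise: float = 0.01
    envelope_fractions: tuple[float, float] = (0.33, 0.67)
    envelope_noise: float = 0.0

    def __post_init__(self) -> None:
        if not 2 <= self.n_torsions <= 6:
            raise ValueError("toy molecules have 2-6 torsions")


def make_fixture(spec: FixtureSpec, seed: int, out_dir: str) -> dict:
    """Emit a reproducible fixture bundle with ground-truth sidecars."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    offsets = rng.choice([-120.0, -60.0, 0.0, 60.0, 120.0], spec.n_torsions)
    landscape = DoubleWellLandscape(offsets)
    minima = [m.tolist() for m in landscape.local_minima()]
    (out / "landscape.json").write_text(
        json.dumps(
            {
                "offsets": offsets.tolist(),
                "a": landscape.a,
                "b": landscape.b,
                "grid_minima": minima,
                "barrier_angle": landscape.barrier_angle,
            },
            indent=2,
        )
    )

    freqs = np.sort(rng.uniform(1450.0, 3600.0, 10))
    sticks = StickSpectrum(freqs, rng.uniform(0.3, 1.0, 10), label="truth",
                           scaled=True)
    trace = synthetic_trace(sticks, noise=spec.trace_noise, seed=seed + 1)
    np.savetxt(
        out / "trace.csv",
        np.column_stack([trace.wavenumbers, trace.intensities]),
        delimiter=",",
        header="wavenumber_cm-1,intensity",
        comments="",
    )
    np.savetxt(
        out / "trace_truth_sticks.csv",
        np.column_stack([sticks.frequencies, sticks.intensities]),
        delimiter=",",
        header="frequency_cm-1,intensity",
        comments="",
    )

    grid, y, comps = envelope_mixture(
        fractions=spec.envelope_fractions,
        noise=spec.envelope_noise,
        seed=seed + 2,
    )
    np.savetxt(
        out / "envelope.csv",
        np.column_stack([grid, y]),
        delimiter=",",
        header="mz_Th,intensity",
        comments="",
    )
    (out / "envelope_truth.json").write_text(
        json.dumps({"fractions": list(spec.envelope_fractions)}, indent=2)
    )
    return {
        "landscape": str(out / "landscape.json"),
        "trace": str(out / "trace.csv"),
        "envelope": str(out / "envelope.csv"),
        "seed": seed,
    }
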