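import sys
from pathlib import Path

import numpy as np
import pytest

from oligoconf.constants import HESSIAN_EIGVAL_TO_WAVENUMBER
from oligoconf.dedup_tfd import wrap_angles
from oligoconf.energy_opt import (
    ExternalAdapterConfig,
    FunctionBackend,
    HarmonicBackend,
    MMFFBackend,
    external_optimize,
    mass_weight_hessian,
    minimize,
    minimize_conformation,
    numerical_hessian,
)

from conftest import random_rigid_motion


def diatomic_backend(k=700.0, r0=1.0):
    def energy(x):
        x = x.reshape(2, 3)
        r = np.linalg.norm(x[1] - x[0])
        return 0.5 * k * (r - r0) ** 2

    return FunctionBackend("diatomic", energy, fd_step=1e-5)


class TestMinimize:
    def test_start_at_minimum(self):
        be = HarmonicBackend(x0=np.array([1.0, 2.0, 3.0]), k=2.0)
        res = minimize(be.x0.copy(), be)
        assert res.n_steps == 0
        assert res.converged

    def test_harmonic_converges_anywhere(self):
        rng = np.random.default_rng(3)
        x0 = np.array([0.5, -1.5, 2.0, 4.0])
        be = HarmonicBackend(x0=x0, k=3.0)
        for _ in range(10):
            res = minimize(rng.uniform(-10, 10, 4), be, gtol=1e-8)
            assert res.converged
            assert res.x == pytest.approx(x0, abs=1e-6)

    def test_monotone_trace(self, landscape):
        be = FunctionBackend("toy", landscape.energy, landscape.gradient)
        res = minimize(np.array([100.0, -30.0]), be, gtol=1e-8)
        trace = res.energy_trace
        assert all(a >= b - 1e-12 for a, b in zip(trace, trace[1:]))

    def test_multistart_recovers_grid_minima(self, landscape):
        """Distinct minima from 100 seeded starts equal the exhaustive
        10-degree grid-search minima (independent oracle)."""
        # oracle: periodic local minima on the 10° grid
        grid = np.arange(-180.0, 180.0, 10.0)
        E = {
            (a, b): landscape.energy(np.array([a, b]))
            for a in grid
            for b in grid
        }

        def is_local_min(a, b):
            e0 = E[(a, b)]
            for da in (-10.0, 0.0, 10.0):
                for db in (-10.0, 0.0, 10.0):
                    if da == db == 0.0:
                        continue
                    na = wrap_angles(np.array([a + da]))[0]
                    nb = wrap_angles(np.array([b + db]))[0]
                    if E[(na, nb)] < e0:
                        return False
            return True

        oracle = {
            (a, b) for a in grid for b in grid if is_local_min(a, b)
        }

        be = FunctionBackend("toy", landscape.energy, landscape.gradient)
        rng = np.random.default_rng(11)
        found = set()
        for _ in range(100):
            res = minimize(rng.uniform(-180, 180, 2), be, gtol=1e-5, max_step=15.0)
            t = wrap_angles(res.x)
            found.add((round(t[0] / 10.0) * 10.0, round(t[1] / 10.0) * 10.0))
        found = {(wrap_angles(np.array([a]))[0], wrap_angles(np.array([b]))[0])
                 for a, b in found}
        assert found == oracle

    def test_backend_without_gradient_rejected(self):
        be = FunctionBackend("e-only", lambda x: 0.0)
        be.supports_gradient = False
        with pytest.raises(ValueError):
            minimize(np.zeros(2), be)

    def test_minimize_conformation_updates_provenance(self, dimer_pn_conf):
        be = MMFFBackend(dimer_pn_conf.topology.mol)
        res = minimize_conformation(dimer_pn_conf, be, gtol=5.0, max_steps=50)
        assert res.conformation is not None
        assert "minimize[mmff94]" in res.conformation.seed_provenance
        trace = res.energy_trace
        assert all(a >= b - 1e-9 for a, b in zip(trace, trace[1:]))


class TestHessian:
    def test_diatomic_closed_form(self):
        k, mu = 700.0, 1.008 / 2.0
        be = diatomic_backend(k=k)
        coords = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        H = numerical_hessian(coords, be)
        Hmw = mass_weight_hessian(H, np.array([1.008, 1.008]))
        eig = np.linalg.eigvalsh(Hmw)
        omega = np.sqrt(eig.max()) * HESSIAN_EIGVAL_TO_WAVENUMBER
        assert omega == pytest.approx(
            np.sqrt(k / mu) * HESSIAN_EIGVAL_TO_WAVENUMBER, rel=1e-3
        )

    def test_translation_modes_near_zero(self):
        be = diatomic_backend()
        coords = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        Hmw = mass_weight_hessian(
            numerical_hessian(coords, be), np.array([1.008, 1.008])
        )
        w = np.sqrt(np.abs(np.linalg.eigvalsh(Hmw))) * HESSIAN_EIGVAL_TO_WAVENUMBER
        assert np.sum(np.sort(w)[:3] < 5.0) == 3  # rigid translations

    def test_step_halving_converged(self):
        be = diatomic_backend()
        coords = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        masses = np.array([1.008, 1.008])
        freqs = []
        for step in (0.005, 0.0025):
            Hmw = mass_weight_hessian(
                numerical_hessian(coords, be, step=step), masses
            )
            freqs.append(
                np.sqrt(np.linalg.eigvalsh(Hmw).max())
                * HESSIAN_EIGVAL_TO_WAVENUMBER
            )
        assert abs(freqs[1] - freqs[0]) / freqs[0] < 1e-3

    def test_symmetric(self):
        be = diatomic_backend()
        H = numerical_hessian(np.array([[0.0, 0, 0], [1.1, 0, 0]]), be)
        assert np.allclose(H, H.T)

    def test_mass_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mass_weight_hessian(np.eye(6), np.array([1.0]))


class TestMMFFInvariance:
    def test_energy_rigid_motion_invariant(self, dimer_pn_conf):
        be = MMFFBackend(dimer_pn_conf.topology.mol)
        e0 = be.energy(dimer_pn_conf.coords)
        rng = np.random.default_rng(9)
        for _ in range(3):
            moved = random_rigid_motion(dimer_pn_conf.coords, rng)
            assert be.energy(moved) == pytest.approx(e0, abs=1e-6)


MOCK_ADAPTER = '''
import sys
inp, out = sys.argv[1], sys.argv[2]
text = open(inp).read().splitlines()
n = int(text[0])
lines = [str(n), "ENERGY = {energy}"]
lines += text[2:2+n]
open(out, "w").write("\\n".join(lines) + "\\n")
'''


class TestExternalAdapter:
    def _write_mock(self, tmp_path, energy="0.0"):
        script = tmp_path / "mock.py"
        script.write_text(MOCK_ADAPTER.replace("{energy}", energy))
        return script

    def test_roundtrip_identity(self, tmp_path, dimer_pn_conf):
        script = self._write_mock(tmp_path)
        cfg = ExternalAdapterConfig(
            command=f"{sys.executable} {script} {{input}} {{output}}",
            name="mock",
            workdir=str(tmp_path / "wd"),
        )
        res = external_optimize(dimer_pn_conf, cfg)
        assert res.energy == pytest.approx(0.0)
        assert np.allclose(res.x, dimer_pn_conf.coords, atol=1e-4)
        assert "external[mock]" in res.conformation.seed_provenance

    def test_missing_executable(self, tmp_path, dimer_pn_conf):
        cfg = ExternalAdapterConfig(
            command="/nonexistent/dft_prog {input} {output}",
            workdir=str(tmp_path),
        )
        with pytest.raises(RuntimeError, match="external backend unavailable"):
            external_optimize(dimer_pn_conf, cfg)

    def test_malformed_output(self, tmp_path, dimer_pn_conf):
        script = tmp_path / "bad.py"
        script.write_text(
            "import sys; open(sys.argv[2],'w').write('garbage\\nnot xyz\\n')"
        )
        cfg = ExternalAdapterConfig(
            command=f"{sys.executable} {script} {{input}} {{output}}",
            workdir=str(tmp_path / "wd"),
        )
        with pytest.raises(ValueError, match="malformed adapter output"):
            external_optimize(dimer_pn_conf, cfg)
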