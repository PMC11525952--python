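import numpy as np
import pytest

from oligoconf.conformer_generator import (
    GeneratorConfig,
    LandscapeEnvironment,
    new_training_state,
    train,
)
from oligoconf.peptide_model import (
    OligomerSpec,
    ProtonationState,
    build_oligomer,
    initial_conformation,
)
from oligoconf.synthetic import DoubleWellLandscape


@pytest.fixture(scope="session")
def landscape():
    """2-torsion double well with offsets on the 10° grid."""
    return DoubleWellLandscape([60.0, -120.0])


@pytest.fixture(scope="session")
def toy_env(landscape):
    return LandscapeEnvironment(landscape.energy, landscape.n_torsions)


@pytest.fixture(scope="session")
def trained_state(toy_env):
    """One PPO training run shared across the suite (deterministic)."""
    cfg = GeneratorConfig(seed=1, max_iterations=120, batch_size=32)
    return train(toy_env, cfg)


@pytest.fixture(scope="session")
def untrained_state(toy_env):
    cfg = GeneratorConfig(seed=1, max_iterations=120, batch_size=32)
    return new_training_state(toy_env, cfg)


@pytest.fixture(scope="session")
def dimer_pn_topology():
    spec = OligomerSpec(2, 1, ProtonationState(("protonated", "neutral")))
    return build_oligomer(spec, seed=3)


@pytest.fixture(scope="session")
def dimer_pn_conf(dimer_pn_topology):
    return initial_conformation(dimer_pn_topology)


def random_rigid_motion(coords: np.ndarray, rng: np.random.Generator):
    """Random rotation + translation for invariance tests."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.uniform(-20, 20, 3)
    return coords @ R.T + t
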