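import copy

import numpy as np
import pytest

from oligoconf.conformer_generator import (
    Episode,
    GeneratorConfig,
    LandscapeEnvironment,
    clipped_objective,
    generate,
    load_checkpoint,
    new_training_state,
    plateau_reached,
    ppo_update,
    reward,
    save_checkpoint,
    train,
)
from oligoconf.dedup_tfd import TorsionFingerprint


class TestReward:
    def test_empty_archive_novelty_one(self, toy_env):
        # at a landscape minimum E=0, so r = w_N * 1.0
        r = reward(
            np.array([60.0, -120.0]), toy_env, [], w_energy=1.0, w_novelty=0.7
        )
        assert r == pytest.approx(0.7)

    def test_archived_identical_zero_novelty(self, toy_env):
        t = np.array([60.0, -120.0])
        archive = [TorsionFingerprint(t)]
        r = reward(t, toy_env, archive, w_energy=0.0, w_novelty=1.0)
        assert r == pytest.approx(0.0)

    def test_ranking_matches_grid_oracle(self, landscape, toy_env):
        # with w_N=0 the reward ranking equals the brute-force energy
        # ranking over the exhaustive 36x36 grid
        grid = np.arange(-180.0, 180.0, 10.0)
        points = [np.array([a, b]) for a in grid for b in grid]
        rewards = [reward(p, toy_env, [], 1.0, 0.0) for p in points]
        energies = [landscape.energy(p) for p in points]
        assert np.argsort(rewards).tolist() == np.argsort(
            [-e for e in energies]
        ).tolist()


class TestClippedObjective:
    def test_clip_arithmetic(self):
        # r=2, A=1, eps=0.2 -> min(2*1, 1.2*1) = 1.2
        assert clipped_objective(2.0, 1.0, 0.2) == pytest.approx(1.2)

    def test_unclipped_region(self):
        assert clipped_objective(1.1, 2.0, 0.2) == pytest.approx(2.2)

    def test_negative_advantage_clip(self):
        assert clipped_objective(0.5, -1.0, 0.2) == pytest.approx(-0.8)


def _manual_batch(state, toy_env, rng, n_episodes=4, horizon=6):
    """Episodes whose returns exactly match the value baseline, so every
    advantage is zero."""
    episodes = []
    n_actions = state.policy.b[-1].size
    for _ in range(n_episodes):
        states = rng.normal(size=(horizon, state.policy.W[0].shape[0]))
        v, _ = state.value.forward(states)
        v = v[:, 0]
        rewards = np.empty(horizon)
        rewards[:-1] = v[:-1] - v[1:]
        rewards[-1] = v[-1]
        actions = rng.integers(n_actions, size=horizon)
        logits, _ = state.policy.forward(states)
        probs = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs /= probs.sum(axis=1, keepdims=True)
        logps = np.log(probs[np.arange(horizon), actions] + 1e-12)
        episodes.append(
            Episode(states, actions, rewards, logps, np.zeros(2))
        )
    return episodes


class TestPpoUpdate:
    def test_zero_advantage_leaves_parameters_unchanged(self, toy_env):
        cfg = GeneratorConfig(seed=5)
        state = new_training_state(toy_env, cfg)
        rng = np.random.default_rng(0)
        batch = _manual_batch(state, toy_env, rng)
        before = [w.copy() for w in state.policy.W + state.policy.b]
        before_v = [w.copy() for w in state.value.W + state.value.b]
        ppo_update(batch, state, cfg)
        after = state.policy.W + state.policy.b
        after_v = state.value.W + state.value.b
        for b, a in zip(before, after):
            assert np.allclose(b, a, atol=1e-12)
        for b, a in zip(before_v, after_v):
            assert np.allclose(b, a, atol=1e-9)

    def test_advantage_trace_appended(self, toy_env):
        cfg = GeneratorConfig(seed=5)
        state = new_training_state(toy_env, cfg)
        batch = _manual_batch(state, toy_env, np.random.default_rng(0))
        ppo_update(batch, state, cfg)
        assert state.iteration == 1
        assert len(state.advantage_trace) == 1

    def test_empty_batch_rejected(self, toy_env):
        state = new_training_state(toy_env, GeneratorConfig())
        with pytest.raises(ValueError):
            ppo_update([], state)

    def test_deterministic_repeat(self, toy_env):
        cfg = GeneratorConfig(seed=5)
        results = []
        for _ in range(2):
            state = new_training_state(toy_env, cfg)
            rng = np.random.default_rng(3)
            batch = _manual_batch(state, toy_env, rng)
            # perturb rewards so advantages are nonzero
            for ep in batch:
                ep.rewards = ep.rewards + np.linspace(-1, 1, ep.rewards.size)
            ppo_update(batch, state, cfg)
            results.append([w.copy() for w in state.policy.W])
        for a, b in zip(results[0], results[1]):
            assert np.array_equal(a, b)


class TestPlateau:
    def _state_with_trace(self, toy_env, trace):
        cfg = GeneratorConfig(seed=0)
        state = new_training_state(toy_env, cfg)
        state.advantage_trace = list(trace)
        state.iteration = len(trace)
        return state

    def test_constant_trace(self, toy_env):
        state = self._state_with_trace(toy_env, [2.0] * 12)
        assert plateau_reached(state, window=10, tolerance=0.01)

    def test_increasing_trace(self, toy_env):
        state = self._state_with_trace(toy_env, list(range(1, 13)))
        assert not plateau_reached(state, window=10, tolerance=0.01)

    def test_flattening_trace_example(self, toy_env):
        state = self._state_with_trace(toy_env, [1, 2, 3, 3.0001, 3.0002])
        assert plateau_reached(state, window=3, tolerance=1e-3)

    def test_short_trace(self, toy_env):
        state = self._state_with_trace(toy_env, [1.0])
        assert not plateau_reached(state, window=10, tolerance=0.01)


class TestGenerate:
    def test_count_zero(self, toy_env, trained_state):
        assert generate(toy_env, trained_state, 0, seed=1) == []

    def test_exact_count(self, toy_env, trained_state):
        out = generate(toy_env, trained_state, 17, seed=2)
        assert len(out) == 17

    def test_determinism(self, toy_env, trained_state):
        a = generate(toy_env, trained_state, 10, seed=42)
        b = generate(toy_env, trained_state, 10, seed=42)
        for x, y in zip(a, b):
            assert np.array_equal(x["torsions"], y["torsions"])

    def test_provenance(self, toy_env, trained_state):
        out = generate(toy_env, trained_state, 1, seed=9)
        assert "seed=9" in out[0]["provenance"]
        assert f"iter={trained_state.iteration}" in out[0]["provenance"]

    def test_basin_enrichment_over_uniform(self, landscape, toy_env, trained_state):
        samples = generate(toy_env, trained_state, 500, seed=7)
        trained_frac = np.mean(
            [landscape.in_global_basin(s["torsions"]) for s in samples]
        )
        rng = np.random.default_rng(7)
        uniform = rng.uniform(-180, 180, (500, 2))
        uniform_frac = np.mean([landscape.in_global_basin(u) for u in uniform])
        assert trained_frac > uniform_frac

    def test_trained_beats_untrained_mean_energy(
        self, toy_env, trained_state, untrained_state
    ):
        trained = generate(toy_env, trained_state, 500, seed=3)
        untrained = generate(toy_env, untrained_state, 500, seed=3)
        assert np.mean([s["energy"] for s in trained]) <= np.mean(
            [s["energy"] for s in untrained]
        )

    def test_invalid_terminal_states_resampled(self, landscape):
        env = LandscapeEnvironment(
            landscape.energy,
            landscape.n_torsions,
            validity_fn=lambda t: abs(t[0]) < 150.0,
        )
        cfg = GeneratorConfig(seed=0, max_iterations=1, batch_size=4)
        state = train(env, cfg)
        out = generate(env, state, 25, seed=5)
        assert len(out) == 25
        assert all(abs(s["torsions"][0]) < 150.0 for s in out)

    def test_charge_agnostic_api(self, landscape):
        # one trained policy serves every protonation state of the size
        env = LandscapeEnvironment(
            landscape.energy,
            landscape.n_torsions,
            charge_labels=("pn", "pz"),
            energy_fns=(landscape.energy, lambda t: landscape.energy(t) + 1.0),
        )
        cfg = GeneratorConfig(seed=2, max_iterations=10, batch_size=8)
        state = train(env, cfg)
        for ci in (0, 1):
            out = generate(env, state, 5, seed=1, charge_index=ci)
            assert len(out) == 5


class TestTraining:
    def test_trace_length_matches_iterations(self, trained_state):
        assert len(trained_state.advantage_trace) == trained_state.iteration

    def test_trained_flag(self, trained_state):
        assert trained_state.trained

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GeneratorConfig(clip_eps=1.5)
        with pytest.raises(ValueError):
            GeneratorConfig(plateau_window=1)


class TestCheckpoint:
    def test_roundtrip(self, toy_env, trained_state, tmp_path):
        path = tmp_path / "ckpt.json"
        save_checkpoint(path, trained_state)
        loaded = load_checkpoint(path)
        a = generate(toy_env, trained_state, 5, seed=11)
        b = generate(toy_env, loaded, 5, seed=11)
        for x, y in zip(a, b):
            assert np.array_equal(x["torsions"], y["torsions"])

    def test_version_check(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"version": 99}')
        with pytest.raises(ValueError, match="version"):
            load_checkpoint(path)
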