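"""PPO-trained torsion-space conformer generator.

A small feed-forward policy proposes torsion rotations (pick a torsion,
rotate by one of a discrete angle set); training with proximal policy
optimization rewards low energy plus novelty (minimum torsion-fingerprint
deviation to an archive of already-seen conformers) and stops when the
batch-mean advantage plateaus.  One policy is trained per oligomer size
regardless of charge location: the charge assignment enters the state
encoding as a one-hot, so every protonation state shares the network.

Implemented in pure numpy (manual backprop through two-layer tanh MLPs)
to stay dependency-light and bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol, Sequence

import numpy as np

from .dedup_tfd import TorsionFingerprint, tfd, wrap_angles

__all__ = [
    "GeneratorConfig",
    "TorsionEnvironment",
    "LandscapeEnvironment",
    "Episode",
    "TrainingState",
    "reward",
    "clipped_objective",
    "ppo_update",
    "plateau_reached",
    "train",
    "generate",
    "save_checkpoint",
    "load_checkpoint",
]

logger = logging.getLogger(__name__)

DEFAULT_ANGLE_SET = (-120.0, -60.0, -30.0, 30.0, 60.0, 120.0, 180.0)


@dataclass
class GeneratorConfig:
    angle_set: tuple[float, ...] = DEFAULT_ANGLE_SET
    horizon: int | None = None  # default 3 × torsion count
    w_energy: float = 1.0
    w_novelty: float = 0.0
    clip_eps: float = 0.2
    learning_rate: float = 3e-3
    batch_size: int = 32
    ppo_epochs: int = 4
    plateau_window: int = 10
    plateau_tolerance: float = 0.01
    max_iterations: int = 200
    hidden: tuple[int, int] = (64, 64)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.clip_eps < 1.0:
            raise ValueError("clip ratio must be in (0, 1)")
        if self.plateau_window < 2:
            raise ValueError("plateau window must be >= 2")


class TorsionEnvironment(Protocol):
    """Minimal contract the generator needs from a molecular system."""

    n_torsions: int
    charge_labels: Sequence[str]

    def energy(self, torsions: np.ndarray, charge_index: int = 0) -> float: ...


@dataclass
class LandscapeEnvironment:
    """Environment over an analytic torsion-space energy function.

    ``energy_fns`` (one callable per charge label) makes the landscape
    charge-dependent while the policy stays shared across labels.
    """

    energy_fn: Callable[[np.ndarray], float]
    n_torsions: int
    charge_labels: tuple[str, ...] = ("pn",)
    validity_fn: Callable[[np.ndarray], bool] | None = None
    energy_fns: tuple[Callable[[np.ndarray], float], ...] | None = None

    def energy(self, torsions: np.ndarray, charge_index: int = 0) -> float:
        fn = self.energy_fns[charge_index] if self.energy_fns else self.energy_fn
        return float(fn(np.asarray(torsions, float)))

    def is_valid(self, torsions: np.ndarray) -> bool:
        return self.validity_fn(torsions) if self.validity_fn else True


@dataclass
class Episode:
    states: np.ndarray  # (T, state_dim)
    actions: np.ndarray  # (T,) int
    rewards: np.ndarray  # (T,)
    log_probs: np.ndarray  # (T,) under behavior policy
    terminal_torsions: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.rewards)):
            raise ValueError("episode rewards must be finite")

    @property
    def return_value(self) -> float:
        return float(self.rewards.sum())


# ---------------------------------------------------------------------------
# tiny MLP with manual backprop
# ---------------------------------------------------------------------------

class _MLP:
    """Two-hidden-layer tanh network with Adam; forward caches activations."""

    def __init__(self, sizes: Sequence[int], rng: np.random.Generator):
        self.W = [
            rng.normal(0, math.sqrt(2.0 / sizes[i]), (sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self._adam_m = [np.zeros_like(w) for w in self.W + self.b]
        self._adam_v = [np.zeros_like(w) for w in self.W + self.b]
        self._adam_t = 0

    def forward(self, X: np.ndarray):
        acts = [X]
        h = X
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            h = h @ W + b
            if i < len(self.W) - 1:
                h = np.tanh(h)
            acts.append(h)
        return h, acts

    def backward(self, acts: list[np.ndarray], d_out: np.ndarray):
        gW = [np.zeros_like(w) for w in self.W]
        gb = [np.zeros_like(b) for b in self.b]
        delta = d_out
        for i in reversed(range(len(self.W))):
            gW[i] = acts[i].T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.W[i].T) * (1.0 - acts[i] ** 2)
        return gW, gb

    def adam_step(self, gW, gb, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        grads = gW + gb
        params = self.W + self.b
        total = sum(float(np.sum(g * g)) for g in grads)
        if total < 1e-24:  # zero gradient: no step (avoids Adam blow-up)
            return
        self._adam_t += 1
        t = self._adam_t
        for p, g, m, v in zip(params, grads, self._adam_m, self._adam_v):
            if not np.all(np.isfinite(g)):
                raise FloatingPointError("non-finite gradient")
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    def to_lists(self):
        return {
            "W": [w.tolist() for w in self.W],
            "b": [b.tolist() for b in self.b],
        }

    @classmethod
    def from_lists(cls, data) -> "_MLP":
        obj = cls.__new__(cls)
        obj.W = [np.array(w, float) for w in data["W"]]
        obj.b = [np.array(b, float) for b in data["b"]]
        obj._adam_m = [np.zeros_like(w) for w in obj.W + obj.b]
        obj._adam_v = [np.zeros_like(w) for w in obj.W + obj.b]
        obj._adam_t = 0
        return obj


@dataclass
class TrainingState:
    policy: _MLP
    value: _MLP
    advantage_trace: list[float]
    iteration: int
    seed: int
    config: GeneratorConfig
    trained: bool = False

    def __post_init__(self) -> None:
        if len(self.advantage_trace) != self.iteration:
            raise ValueError("advantage trace must match iteration counter")


def _state_vector(
    torsions: np.ndarray, charge_index: int, n_labels: int
) -> np.ndarray:
    rad = np.deg2rad(torsions)
    onehot = np.zeros(n_labels)
    onehot[charge_index] = 1.0
    return np.concatenate([np.sin(rad), np.cos(rad), onehot])


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def new_training_state(env: TorsionEnvironment, config: GeneratorConfig) -> TrainingState:
    rng = np.random.default_rng(config.seed)
    n_labels = len(env.charge_labels)
    state_dim = 2 * env.n_torsions + n_labels
    n_actions = env.n_torsions * len(config.angle_set)
    h1, h2 = config.hidden
    policy = _MLP([state_dim, h1, h2, n_actions], rng)
    value = _MLP([state_dim, h1, h2, 1], rng)
    return TrainingState(policy, value, [], 0, config.seed, config)


# ---------------------------------------------------------------------------
# reward
# ---------------------------------------------------------------------------

def reward(
    torsions: np.ndarray,
    env: TorsionEnvironment,
    archive: Sequence[TorsionFingerprint],
    w_energy: float = 1.0,
    w_novelty: float = 0.0,
    charge_index: int = 0,
) -> float:
    """r = -w_E · E + w_N · novelty; novelty is the minimum TFD to the
    archive (1.0 when the archive is empty)."""
    e = env.energy(torsions, charge_index)
    if not np.isfinite(e):
        raise FloatingPointError("energy evaluation failed")
    novelty = 1.0
    if archive:
        fp = TorsionFingerprint(np.asarray(torsions, float))
        novelty = min(tfd(fp, other) for other in archive)
    return -w_energy * e + w_novelty * novelty


# ---------------------------------------------------------------------------
# rollouts
# ---------------------------------------------------------------------------

def _rollout(
    env,
    state: TrainingState,
    rng: np.random.Generator,
    archive: Sequence[TorsionFingerprint],
    charge_index: int = 0,
) -> Episode:
    cfg = state.config
    horizon = cfg.horizon or 3 * env.n_torsions
    n_labels = len(env.charge_labels)
    torsions = wrap_angles(rng.uniform(-180.0, 180.0, env.n_torsions))
    r_prev = reward(torsions, env, archive, cfg.w_energy, cfg.w_novelty, charge_index)
    states, actions, rewards, logps = [], [], [], []
    for _ in range(horizon):
        s = _state_vector(torsions, charge_index, n_labels)
        logits, _ = state.policy.forward(s[None, :])
        probs = _softmax(logits[0])
        a = int(rng.choice(probs.size, p=probs))
        t_idx, ang_idx = divmod(a, len(cfg.angle_set))
        torsions = torsions.copy()
        torsions[t_idx] = wrap_angles(
            np.array([torsions[t_idx] + cfg.angle_set[ang_idx]])
        )[0]
        r_new = reward(torsions, env, archive, cfg.w_energy, cfg.w_novelty, charge_index)
        states.append(s)
        actions.append(a)
        rewards.append(r_new - r_prev)  # potential-based shaping
        logps.append(math.log(probs[a] + 1e-12))
        r_prev = r_new
    return Episode(
        states=np.array(states),
        actions=np.array(actions, dtype=int),
        rewards=np.array(rewards),
        log_probs=np.array(logps),
        terminal_torsions=torsions,
    )


# ---------------------------------------------------------------------------
# PPO update
# ---------------------------------------------------------------------------

def clipped_objective(ratio, advantage, clip_eps: float = 0.2):
    """Per-sample clipped surrogate: min(r·A, clip(r, 1-ε, 1+ε)·A)."""
    ratio = np.asarray(ratio, float)
    advantage = np.asarray(advantage, float)
    clipped = np.clip(ratio, 1.0 - clip_eps, 1.0 + clip_eps)
    return np.minimum(ratio * advantage, clipped * advantage)


def ppo_update(
    batch: list[Episode], state: TrainingState, config: GeneratorConfig | None = None
) -> TrainingState:
    """One clipped-surrogate PPO update over a batch of episodes.

    Objective per sample: min(r·A, clip(r, 1-ε, 1+ε)·A) with r the
    new/old probability ratio and A the normalized advantage
    (return-to-go minus value baseline).  The value net is regressed on
    returns-to-go.  Appends the batch-mean (unnormalized) advantage to
    the trace.
    """
    if not batch:
        raise ValueError("PPO batch must be non-empty")
    cfg = config or state.config
    S = np.vstack([ep.states for ep in batch])
    A_idx = np.concatenate([ep.actions for ep in batch])
    logp_old = np.concatenate([ep.log_probs for ep in batch])
    returns = np.concatenate(
        [np.cumsum(ep.rewards[::-1])[::-1] for ep in batch]
    )
    values, _ = state.value.forward(S)
    adv_raw = returns - values[:, 0]
    mean_adv = float(adv_raw.mean())
    std = adv_raw.std()
    if std > 1e-9 and np.abs(adv_raw).max() > 1e-9:
        adv = (adv_raw - mean_adv) / (std + 1e-8)
    else:
        adv = np.zeros_like(adv_raw)

    n = S.shape[0]
    try:
        for _ in range(cfg.ppo_epochs):
            logits, acts = state.policy.forward(S)
            probs = _softmax(logits)
            logp = np.log(probs[np.arange(n), A_idx] + 1e-12)
            ratio = np.exp(logp - logp_old)
            clipped_hi = (adv > 0) & (ratio > 1.0 + cfg.clip_eps)
            clipped_lo = (adv < 0) & (ratio < 1.0 - cfg.clip_eps)
            active = ~(clipped_hi | clipped_lo)
            # d(-objective)/d(logits): -A·r·(onehot - softmax) on active rows
            coef = np.where(active, adv * ratio, 0.0) / n
            d_logits = probs * coef[:, None]
            d_logits[np.arange(n), A_idx] -= coef
            gW, gb = state.policy.backward(acts, d_logits)
            state.policy.adam_step(gW, gb, cfg.learning_rate)

            v, vacts = state.value.forward(S)
            d_v = 2.0 * (v - returns[:, None]) / n
            gWv, gbv = state.value.backward(vacts, d_v)
            state.value.adam_step(gWv, gbv, cfg.learning_rate)
    except FloatingPointError:
        logger.warning("non-finite gradient; PPO update skipped")

    state.advantage_trace.append(mean_adv)
    state.iteration += 1
    return state


def plateau_reached(
    state: TrainingState, window: int | None = None, tolerance: float | None = None
) -> bool:
    """True iff the advantage trace has flattened: the spread of the last
    ``window`` values, relative to the overall trace scale, is below
    ``tolerance``."""
    cfg = state.config
    window = window or cfg.plateau_window
    tolerance = tolerance if tolerance is not None else cfg.plateau_tolerance
    trace = state.advantage_trace
    if len(trace) < window:
        return False
    recent = np.asarray(trace[-window:])
    spread = float(recent.max() - recent.min())
    scale = max(float(np.max(np.abs(trace))), 1e-8)
    return spread / scale < tolerance


def train(
    env,
    config: GeneratorConfig,
    state: TrainingState | None = None,
    archive: list[TorsionFingerprint] | None = None,
) -> TrainingState:
    """Train the policy until the advantage trace plateaus (or the
    iteration cap is hit)."""
    state = state or new_training_state(env, config)
    rng = np.random.default_rng(config.seed + 1)
    archive = archive if archive is not None else []
    n_labels = len(env.charge_labels)
    while state.iteration < config.max_iterations:
        batch = []
        for k in range(config.batch_size):
            ci = int(rng.integers(n_labels)) if n_labels > 1 else 0
            try:
                batch.append(_rollout(env, state, rng, archive, ci))
            except FloatingPointError:
                logger.warning("episode aborted: energy evaluation failure")
        if not batch:
            continue
        state = ppo_update(batch, state, config)
        if config.w_novelty > 0:
            for ep in batch:
                archive.append(TorsionFingerprint(ep.terminal_torsions))
        if plateau_reached(state):
            logger.info("advantage plateau at iteration %d", state.iteration)
            break
    state.trained = True
    return state


def generate(
    env,
    state: TrainingState,
    count: int,
    seed: int,
    charge_index: int = 0,
    max_resamples: int = 50,
) -> list[dict]:
    """Generate ``count`` conformer torsion vectors by policy rollouts.

    Invalid terminal states (per the environment's validity check) are
    rejected and resampled so the accepted count always equals the
    request.  Each record carries provenance (seed, policy iteration).
    """
    if not state.trained:
        logger.warning("policy flagged untrained; rollouts use current weights")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(count):
        for _attempt in range(max_resamples):
            ep = _rollout(env, state, rng, [], charge_index)
            t = ep.terminal_torsions
            if not hasattr(env, "is_valid") or env.is_valid(t):
                out.append(
                    {
                        "torsions": t,
                        "energy": env.energy(t, charge_index),
                        "provenance": f"ppo:seed={seed}:iter={state.iteration}:sample={i}",
                    }
                )
                break
        else:
            raise RuntimeError("could not generate a valid conformation")
    return out


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(path, state: TrainingState) -> None:
    data = {
        "version": CHECKPOINT_VERSION,
        "policy": state.policy.to_lists(),
        "value": state.value.to_lists(),
        "advantage_trace": state.advantage_trace,
        "iteration": state.iteration,
        "seed": state.seed,
        "trained": state.trained,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(state.config).items()
        },
    }
    Path(path).write_text(json.dumps(data))


def load_checkpoint(path) -> TrainingState:
    data = json.loads(Path(path).read_text())
    if data.get("version") != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {data.get('version')}")
    cfg_raw = data["config"]
    cfg = GeneratorConfig(
        **{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in cfg_raw.items()
        }
    )
    return TrainingState(
        policy=_MLP.from_lists(data["policy"]),
        value=_MLP.from_lists(data["value"]),
        advantage_trace=list(data["advantage_trace"]),
        iteration=data["iteration"],
        seed=data["seed"],
        config=cfg,
        trained=data["trained"],
    )
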