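"""Double-DQN training and the coarse-to-fine inference policy.

Training follows the classic recipe: epsilon-greedy rollouts fill a FIFO
experience-replay buffer of (s, a, r, s') tuples; every optimiser step
draws a uniform batch and minimises the Double-DQN objective

    L(theta) = E[(R + gamma * Q(s', argmax_a Q(s', a; theta); theta^-)
                  - Q(s, a; theta))^2]

where the online network selects the bootstrap action and the frozen
target network theta^- evaluates it; theta^- is refreshed from theta every
C optimiser steps.  Gradients are clipped element-wise to [-1, 1] and
applied with Adadelta.  Terminal transitions drop the bootstrap term.

Inference is greedy (epsilon = 0), starting at the image centre on the
coarsest scale; when the agent revisits a position often enough
(oscillation) it descends one scale, and at the finest scale it returns
the most frequently visited position.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import asdict, dataclass, field

import numpy as np

from .mdp_env import ACTION_DELTAS, EnvConfig, LandmarkEnv, Transition, extract_patch
from .networks import Adadelta, QNetwork, QNetworkSpec

__all__ = [
    "QNetworkSpec",
    "QNetwork",
    "ReplayBuffer",
    "TrainConfig",
    "double_dqn_loss",
    "train",
    "infer_landmark",
    "DQNPolicy",
    "OraclePolicy",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1


class ReplayBuffer:
    """FIFO transition store with uniform batch sampling (no replacement)."""

    def __init__(self, capacity: int = 10**6):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self._store: deque[Transition] = deque(maxlen=capacity)

    def __len__(self) -> int:
        return len(self._store)

    def append(self, t: Transition) -> None:
        self._store.append(t)

    def sample(self, rng: np.random.Generator, batch_size: int) -> list[Transition]:
        if batch_size > len(self._store):
            raise ValueError("batch larger than buffer")
        idx = rng.choice(len(self._store), size=batch_size, replace=False)
        return [self._store[int(i)] for i in idx]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters.

    Published values: batch 96, discount 0.9, replay capacity 1e6, Adadelta,
    element-wise gradient clipping to [-1, 1].  The target-sync period C and
    the exploration schedule (epsilon linear 1.0 -> 0.1 over the first half
    of training, then constant) are standard-DQN choices.
    """

    total_steps: int = 20_000
    batch_size: int = 96
    gamma: float = 0.9
    buffer_capacity: int = 10**6
    target_sync: int = 500
    train_every: int = 1
    eps_start: float = 1.0
    eps_end: float = 0.1
    eps_fraction: float = 0.5
    grad_clip: float = 1.0
    adadelta_rho: float = 0.95
    adadelta_eps: float = 1e-6
    log_every: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.gamma < 1:
            raise ValueError("discount factor must be in (0, 1)")
        if self.target_sync < 1:
            raise ValueError("target sync period C must be >= 1")

    def epsilon(self, step: int) -> float:
        horizon = max(1, int(self.eps_fraction * self.total_steps))
        frac = min(1.0, step / horizon)
        return self.eps_start + frac * (self.eps_end - self.eps_start)


def _batch_arrays(batch: list[Transition]):
    s = np.stack([t.state for t in batch])
    a = np.array([t.action for t in batch], dtype=int)
    r = np.array([t.reward for t in batch], dtype=np.float32)
    s2 = np.stack([t.next_state for t in batch])
    done = np.array([t.done for t in batch], dtype=bool)
    return s, a, r, s2, done


def _targets(online: QNetwork, target: QNetwork, s2, r, done, gamma: float) -> np.ndarray:
    q2_online = online.forward(s2)
    best = np.argmax(q2_online, axis=1)
    q2_target = target.forward(s2)
    bootstrap = q2_target[np.arange(len(best)), best]
    return r + gamma * bootstrap * (~done)


def double_dqn_loss(
    batch: list[Transition], online: QNetwork, target: QNetwork, gamma: float = 0.9
) -> float:
    """Mean squared Double-DQN temporal-difference error over a batch."""
    if not batch:
        raise ValueError("empty batch")
    s, a, r, s2, done = _batch_arrays(batch)
    y = _targets(online, target, s2, r, done, gamma)
    q = online.forward(s)
    q_sa = q[np.arange(len(a)), a]
    return float(np.mean((y - q_sa) ** 2))


def _train_step(
    batch: list[Transition],
    online: QNetwork,
    target: QNetwork,
    opt: Adadelta,
    cfg: TrainConfig,
) -> float:
    s, a, r, s2, done = _batch_arrays(batch)
    y = _targets(online, target, s2, r, done, cfg.gamma)
    q = online.forward(s)  # forward on s last so caches refer to s
    q_sa = q[np.arange(len(a)), a]
    err = q_sa - y
    loss = float(np.mean(err**2))
    dq = np.zeros_like(q)
    dq[np.arange(len(a)), a] = 2.0 * err / len(a)
    grads = online.backward(dq)
    grads = [np.clip(g, -cfg.grad_clip, cfg.grad_clip) for g in grads]
    params = [p for layer in online.layers for p in layer.params]
    opt.step(params, grads)
    return loss


@dataclass
class TrainLog:
    """Loss / exploration / episode-distance traces recorded during training."""

    rows: list[dict] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows)

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _as_envs(envs, env_cfg: EnvConfig) -> list[LandmarkEnv]:
    out = []
    for e in envs:
        if isinstance(e, LandmarkEnv):
            out.append(e)
        else:
            image, target_px = e
            out.append(LandmarkEnv(image, target_px, env_cfg))
    return out


def train(
    envs,
    netspec: QNetworkSpec | None = None,
    cfg: TrainConfig | None = None,
    env_cfg: EnvConfig | None = None,
    seed: int = 0,
) -> tuple[QNetwork, TrainLog]:
    """Train one Double-DQN agent on a set of (image, target) environments.

    Fully deterministic for a given seed.  Each episode picks an
    environment and a zoom scale uniformly at random and starts the agent
    at a random position away from the border.
    """
    env_cfg = env_cfg or EnvConfig()
    envs = _as_envs(envs, env_cfg)
    if not envs:
        raise ValueError("at least one training environment is required")
    netspec = netspec or QNetworkSpec()
    cfg = cfg or TrainConfig()
    rng = np.random.default_rng(seed)
    online = QNetwork(netspec, rng)
    target = QNetwork(netspec, rng)
    target.set_params(online.get_params())
    opt = Adadelta(
        [p for layer in online.layers for p in layer.params],
        rho=cfg.adadelta_rho,
        eps=cfg.adadelta_eps,
    )
    buffer = ReplayBuffer(cfg.buffer_capacity)
    log = TrainLog()

    def new_episode():
        env = envs[int(rng.integers(len(envs)))]
        state = env.reset(rng=rng, scale_index=0)
        return env, state

    env, state = new_episode()
    finest = len(env_cfg.scales) - 1
    opt_steps = 0
    loss = float("nan")
    recent_final = deque(maxlen=20)
    for step in range(cfg.total_steps):
        eps = cfg.epsilon(step)
        if rng.random() < eps:
            action = int(rng.integers(4))
        else:
            action = int(np.argmax(online.q_values(state)))
        next_state, r, done, info = env.step(action)
        buffer.append(Transition(state, action, r, next_state, done))
        state = next_state
        if done:
            # episodes run coarse-to-fine, mirroring inference: reaching
            # the per-scale radius descends one scale and continues; the
            # stored transition stays terminal for that scale's Q
            if info["reached"] and env.scale_index < finest:
                state = env.set_scale(env.scale_index + 1)
            else:
                recent_final.append(env.distance_to_target())
                env, state = new_episode()
        if len(buffer) >= cfg.batch_size and step % cfg.train_every == 0:
            batch = buffer.sample(rng, cfg.batch_size)
            loss = _train_step(batch, online, target, opt, cfg)
            opt_steps += 1
            if opt_steps % cfg.target_sync == 0:
                target.set_params(online.get_params())
        if step % cfg.log_every == 0 or step == cfg.total_steps - 1:
            log.rows.append(
                {
                    "step": step,
                    "loss": loss,
                    "epsilon": eps,
                    "mean_episode_distance": float(np.mean(recent_final))
                    if recent_final
                    else float("nan"),
                }
            )
    return online, log


# ---------------------------------------------------------------------------
# inference


class DQNPolicy:
    """Greedy policy backed by a trained Q-network."""

    def __init__(self, network: QNetwork):
        self.network = network

    def q_values(self, state: np.ndarray, pos: np.ndarray, step_px: int) -> np.ndarray:
        return self.network.q_values(state)


class OraclePolicy:
    """Q replaced by the negative true pixel distance after each action.

    Greedy descent on the true distance field is optimal, so this policy
    isolates the geometric plumbing from learning quality in tests.
    """

    def __init__(self, target_px):
        self.target = np.asarray(target_px, dtype=float).reshape(2)

    def q_values(self, state: np.ndarray, pos: np.ndarray, step_px: int) -> np.ndarray:
        pos = np.asarray(pos, dtype=float)
        nxt = pos[None, :] + ACTION_DELTAS * step_px
        return -np.linalg.norm(nxt - self.target[None, :], axis=1)


def infer_landmark(
    image,
    policy,
    env_cfg: EnvConfig | None = None,
    max_steps_per_scale: int = 100,
    revisit_threshold: int = 4,
) -> tuple[np.ndarray, dict]:
    """Multi-scale greedy navigation on a projected image.

    Starts at the image centre on the coarsest scale; descends one scale
    whenever a position has been revisited ``revisit_threshold`` times
    (oscillation); at the finest scale terminates on oscillation or after
    ``max_steps_per_scale`` steps and returns the most frequently visited
    position (ties broken by earliest visit).
    """
    env_cfg = env_cfg or EnvConfig()
    img = np.asarray(getattr(image, "pixels", image), dtype=np.float32)
    if isinstance(policy, QNetwork):
        policy = DQNPolicy(policy)
    h, w = img.shape
    pos = np.array([w // 2, h // 2], dtype=int)
    trace: dict = {"scales": []}
    for si, zoom in enumerate(env_cfg.scales):
        finest = si == len(env_cfg.scales) - 1
        step_px = env_cfg.step_size(si)
        visits: dict[tuple[int, int], int] = {}
        first_seen: dict[tuple[int, int], int] = {}
        history: deque[np.ndarray] = deque(maxlen=env_cfg.history)
        path = []
        for t in range(max_steps_per_scale):
            key = (int(pos[0]), int(pos[1]))
            visits[key] = visits.get(key, 0) + 1
            first_seen.setdefault(key, t)
            path.append(key)
            if visits[key] >= revisit_threshold:
                break  # oscillation detected at this scale
            patch = extract_patch(img, pos, zoom, env_cfg.patch_size)
            history.append(patch)
            while len(history) < env_cfg.history:
                history.appendleft(patch.copy())
            state = np.stack(history)
            q = policy.q_values(state, pos, step_px)
            action = int(np.argmax(q))
            pos = pos + ACTION_DELTAS[action] * step_px
            pos[0] = np.clip(pos[0], 0, w - 1)
            pos[1] = np.clip(pos[1], 0, h - 1)
        trace["scales"].append({"zoom": zoom, "visits": visits, "path": path})
        if finest:
            best = max(visits.items(), key=lambda kv: (kv[1], -first_seen[kv[0]]))
            return np.array(best[0], dtype=int), trace
        # descend one scale, keeping the current position
    raise RuntimeError("unreachable: scales always end at the finest level")


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(
    path,
    network: QNetwork,
    cfg: TrainConfig | None = None,
    env_cfg: EnvConfig | None = None,
    seed: int | None = None,
) -> None:
    """Persist parameters + architecture + configs as a versioned .npz."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "netspec": asdict(network.spec),
        "train_config": asdict(cfg) if cfg else None,
        "env_config": asdict(env_cfg) if env_cfg else None,
        "seed": seed,
    }
    params = network.get_params()
    np.savez(
        path,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **{f"param_{i}": p for i, p in enumerate(params)},
    )


def load_checkpoint(path) -> tuple[QNetwork, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')!r}")
        ns = meta["netspec"]
        ns["conv"] = tuple(tuple(c) for c in ns["conv"])
        ns["fc"] = tuple(ns["fc"])
        net = QNetwork(QNetworkSpec(**ns), rng=0)
        params = [data[f"param_{i}"] for i in range(len(net.get_params()))]
        net.set_params(params)
    return net, meta
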