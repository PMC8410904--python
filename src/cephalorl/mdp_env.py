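"""The landmark-seeking Markov decision process on a projected image.

The environment is a 2D grayscale view; the agent occupies an integer pixel
position and moves right/left/up/down.  The state is a stack of the k most
recent square patches centred on the agent, each cropped at the current
zoom (patch_size * zoom window, area-averaged down to patch_size) so that
coarse scales see global context and the fine scale sees native resolution.
The reward is the decrease in Euclidean pixel distance to the target:

    R_t = Dist(AP_{t-1}, TP) - Dist(AP_t, TP)

which telescopes over an episode to start-minus-end distance.  Transitions
are deterministic: moves translate the agent by the scale's step size,
clamped at the image border.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

ACTIONS = ("right", "left", "up", "down")
#: pixel displacement per unit step, as (du, dv); image v grows downward
ACTION_DELTAS = np.array([[1, 0], [-1, 0], [0, -1], [0, 1]], dtype=int)


@dataclass(frozen=True)
class EnvConfig:
    """Environment parameters.

    ``scales`` are the coarse-to-fine zoom factors (window = patch_size *
    zoom, agent step = zoom pixels); they must be strictly decreasing and
    end at 1.  ``success_radius`` terminates a training episode when the
    agent is within ``success_radius * zoom`` pixels of the target, i.e.
    1 px at the finest scale by default.
    """

    patch_size: int = 128
    history: int = 4
    scales: tuple[int, ...] = (4, 2, 1)
    max_steps: int = 100
    success_radius: float = 1.0
    start_margin: float = 0.1  # training starts avoid this border fraction

    def __post_init__(self) -> None:
        if self.history < 1:
            raise ValueError("frame history k must be >= 1")
        if list(self.scales) != sorted(self.scales, reverse=True) or self.scales[-1] != 1:
            raise ValueError("scales must be strictly decreasing and end at 1")
        if len(set(self.scales)) != len(self.scales):
            raise ValueError("scales must be strictly decreasing")

    def step_size(self, scale_index: int) -> int:
        return int(self.scales[scale_index])


@dataclass
class AgentPosition:
    u: int
    v: int
    scale_index: int = 0

    def as_array(self) -> np.ndarray:
        return np.array([self.u, self.v], dtype=float)


@dataclass
class Transition:
    """One (s, a, r, s', done) tuple for the replay buffer."""

    state: np.ndarray  # (k, patch, patch)
    action: int
    reward: float
    next_state: np.ndarray
    done: bool

    def __post_init__(self) -> None:
        if not np.isfinite(self.reward):
            raise ValueError("reward must be finite")


def reward(prev, curr, target) -> float:
    """Decrease in Euclidean distance to the target pixel (Eq.-style
    start-minus-end form; positive iff the agent moved closer)."""
    prev = np.asarray(prev, dtype=float)
    curr = np.asarray(curr, dtype=float)
    target = np.asarray(target, dtype=float)
    return float(np.linalg.norm(prev - target) - np.linalg.norm(curr - target))


def extract_patch(image: np.ndarray, pos, zoom: int, patch_size: int) -> np.ndarray:
    """Crop a (patch_size * zoom)^2 window centred at ``pos`` and area-average
    it down to patch_size^2; out-of-image area is zero-padded."""
    u, v = int(pos[0]), int(pos[1])
    w = patch_size * zoom
    half = w // 2
    h_img, w_img = image.shape
    out = np.zeros((w, w), dtype=np.float32)
    r0, r1 = v - half, v - half + w
    c0, c1 = u - half, u - half + w
    rr0, rr1 = max(r0, 0), min(r1, h_img)
    cc0, cc1 = max(c0, 0), min(c1, w_img)
    if rr1 > rr0 and cc1 > cc0:
        out[rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0] = image[rr0:rr1, cc0:cc1]
    if zoom == 1:
        return out
    return out.reshape(patch_size, zoom, patch_size, zoom).mean(axis=(1, 3))


class LandmarkEnv:
    """Gym-style deterministic environment for one (image, target) pair."""

    def __init__(self, image, target_px, cfg: EnvConfig | None = None):
        self.image = np.asarray(getattr(image, "pixels", image), dtype=np.float32)
        if self.image.ndim != 2:
            raise ValueError("environment image must be 2D grayscale")
        self.target = np.asarray(target_px, dtype=float).reshape(2)
        self.cfg = cfg or EnvConfig()
        self.pos: np.ndarray | None = None
        self.scale_index = 0
        self.steps = 0
        self._history: deque[np.ndarray] = deque(maxlen=self.cfg.history)

    # -- helpers ---------------------------------------------------------
    @property
    def size(self) -> tuple[int, int]:
        return self.image.shape[1], self.image.shape[0]  # (width, height)

    def distance_to_target(self, pos=None) -> float:
        p = self.pos if pos is None else np.asarray(pos, dtype=float)
        return float(np.linalg.norm(p - self.target))

    def _observe(self) -> np.ndarray:
        zoom = self.cfg.scales[self.scale_index]
        patch = extract_patch(self.image, self.pos, zoom, self.cfg.patch_size)
        self._history.append(patch)
        while len(self._history) < self.cfg.history:
            self._history.appendleft(patch.copy())
        return np.stack(self._history)

    def state(self) -> np.ndarray:
        """Current k-frame patch stack without advancing the history."""
        return np.stack(self._history)

    # -- gym-style API ---------------------------------------------------
    def reset(
        self,
        rng: np.random.Generator | None = None,
        start=None,
        scale_index: int = 0,
    ) -> np.ndarray:
        w, h = self.size
        if start is None:
            if rng is None:
                start = (w // 2, h // 2)
            else:
                m = self.cfg.start_margin
                start = (
                    int(rng.integers(int(m * w), w - int(m * w))),
                    int(rng.integers(int(m * h), h - int(m * h))),
                )
        self.pos = np.array([int(start[0]), int(start[1])], dtype=int)
        self.scale_index = int(scale_index)
        self.steps = 0
        self._history.clear()
        return self._observe()

    def set_scale(self, scale_index: int) -> np.ndarray:
        """Switch resolution (coarse-to-fine descent); resets the per-scale
        step budget and the frame history."""
        self.scale_index = int(scale_index)
        self.steps = 0
        self._history.clear()
        return self._observe()

    def step(self, action: int) -> tuple[np.ndarray, float, bool, dict]:
        if self.pos is None:
            raise RuntimeError("call reset() before step()")
        if not 0 <= int(action) < len(ACTIONS):
            raise ValueError(f"action must be in 0..3, got {action}")
        step_px = self.cfg.step_size(self.scale_index)
        prev = self.pos.copy()
        w, h = self.size
        new = prev + ACTION_DELTAS[int(action)] * step_px
        new[0] = np.clip(new[0], 0, w - 1)
        new[1] = np.clip(new[1], 0, h - 1)
        self.pos = new
        self.steps += 1
        r = reward(prev, new, self.target)
        zoom = self.cfg.scales[self.scale_index]
        reached = self.distance_to_target() <= self.cfg.success_radius * zoom
        done = reached or self.steps >= self.cfg.max_steps
        return (
            self._observe(),
            r,
            bool(done),
            {"position": self.pos.copy(), "reached": bool(reached)},
        )
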