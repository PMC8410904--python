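"""A small CPU convolutional Q-network with hand-written backprop.

The architecture follows the agent network used for landmark detection:
stacked (conv -> leaky ReLU -> 2x2 max-pool) blocks followed by
fully-connected rectifier layers and a linear 4-output head, one Q-value
per planar action.  Parameters are initialised from the Glorot uniform
distribution and trained with Adadelta.  Everything is float32 numpy; the
convolutions are im2col + GEMM, which is plenty fast at the patch sizes
the agents use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_F32 = np.float32


@dataclass(frozen=True)
class QNetworkSpec:
    """Architecture description; immutable once built.

    Defaults are the full-size agent network: 128x128xk input (k = 4 frame
    history), conv layers of 32/32/64/64 filters (5x5, 5x5, 3x3, 3x3, all
    stride 1), each followed by leaky ReLU and 2x2 max-pool stride 2, then
    fully-connected 512/256/128 rectifier layers and a linear layer with
    exactly 4 outputs.
    """

    input_size: int = 128
    in_channels: int = 4
    conv: tuple[tuple[int, int], ...] = ((32, 5), (32, 5), (64, 3), (64, 3))
    fc: tuple[int, ...] = (512, 256, 128)
    n_actions: int = 4
    leak: float = 0.01

    def __post_init__(self) -> None:
        if self.n_actions != 4:
            raise ValueError("the agent has exactly 4 planar actions")


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(_F32)


class _Conv:
    def __init__(self, rng, in_ch, out_ch, k, leak):
        self.k = k
        self.leak = leak
        fan_in = in_ch * k * k
        fan_out = out_ch * k * k
        self.W = _glorot(rng, (fan_in, out_ch), fan_in, fan_out)
        self.b = np.zeros(out_ch, dtype=_F32)
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        k = self.k
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        # (B, C, H', W', k, k) -> (B, H'*W', C*k*k)
        Hp, Wp = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, Hp * Wp, C * k * k)
        z = cols @ self.W + self.b
        out = np.where(z > 0, z, self.leak * z)
        self._cache = (x.shape, cols, z, Hp, Wp)
        return out.transpose(0, 2, 1).reshape(B, -1, Hp, Wp)

    def backward(self, dout: np.ndarray):
        x_shape, cols, z, Hp, Wp = self._cache
        B, C, H, W = x_shape
        k = self.k
        d = dout.reshape(B, -1, Hp * Wp).transpose(0, 2, 1)
        d = d * np.where(z > 0, _F32(1.0), _F32(self.leak))
        dW = np.einsum("bif,bio->fo", cols, d, optimize=True)
        db = d.sum(axis=(0, 1))
        dcols = d @ self.W.T  # (B, Hp*Wp, C*k*k)
        dcols = dcols.reshape(B, Hp, Wp, C, k, k).transpose(0, 3, 1, 2, 4, 5)
        dx = np.zeros(x_shape, dtype=_F32)
        for i in range(k):
            for j in range(k):
                dx[:, :, i : i + Hp, j : j + Wp] += dcols[:, :, :, :, i, j]
        return dx, [dW.astype(_F32), db.astype(_F32)]


class _MaxPool2:
    def __init__(self):
        self._cache = None

    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        H2, W2 = H // 2, W // 2
        xc = x[:, :, : 2 * H2, : 2 * W2]
        r = xc.reshape(B, C, H2, 2, W2, 2)
        out = r.max(axis=(3, 5))
        mask = r == out[:, :, :, None, :, None]
        self._cache = (x.shape, mask)
        return out

    def backward(self, dout: np.ndarray):
        x_shape, mask = self._cache
        B, C, H, W = x_shape
        H2, W2 = mask.shape[2], mask.shape[4]
        dr = mask * dout[:, :, :, None, :, None]
        dx = np.zeros(x_shape, dtype=_F32)
        dx[:, :, : 2 * H2, : 2 * W2] = dr.reshape(B, C, 2 * H2, 2 * W2)
        return dx, []


class _Dense:
    def __init__(self, rng, n_in, n_out, leak, linear=False):
        self.W = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out, dtype=_F32)
        self.leak = leak
        self.linear = linear
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x2 = x.reshape(x.shape[0], -1)
        z = x2 @ self.W + self.b
        out = z if self.linear else np.where(z > 0, z, self.leak * z)
        self._cache = (x.shape, x2, z)
        return out

    def backward(self, dout: np.ndarray):
        x_shape, x2, z = self._cache
        if not self.linear:
            dout = dout * np.where(z > 0, _F32(1.0), _F32(self.leak))
        dW = x2.T @ dout
        db = dout.sum(axis=0)
        dx = (dout @ self.W.T).reshape(x_shape)
        return dx, [dW.astype(_F32), db.astype(_F32)]


class QNetwork:
    """Q(s, a; theta): maps a (k, p, p) patch stack to 4 action values."""

    def __init__(self, spec: QNetworkSpec | None = None, rng=None):
        self.spec = spec or QNetworkSpec()
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        s = self.spec
        self.layers: list = []
        ch, hw = s.in_channels, s.input_size
        for out_ch, k in s.conv:
            self.layers.append(_Conv(rng, ch, out_ch, k, s.leak))
            hw = hw - k + 1
            self.layers.append(_MaxPool2())
            hw = hw // 2
            ch = out_ch
            if hw < 1:
                raise ValueError("input too small for the conv stack")
        n_in = ch * hw * hw
        for n_out in s.fc:
            self.layers.append(_Dense(rng, n_in, n_out, s.leak))
            n_in = n_out
        self.layers.append(_Dense(rng, n_in, s.n_actions, s.leak, linear=True))

    # -- parameter plumbing ---------------------------------------------
    def get_params(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params]

    def set_params(self, params: list[np.ndarray]) -> None:
        flat = [p for layer in self.layers for p in layer.params]
        if len(flat) != len(params):
            raise ValueError("parameter list does not match architecture")
        for dst, src in zip(flat, params):
            if dst.shape != src.shape:
                raise ValueError("parameter shapes do not match architecture")
            dst[...] = src

    def checksum(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for layer in self.layers:
            for p in layer.params:
                h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()

    # -- forward / backward ---------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        out = np.asarray(x, dtype=_F32)
        if out.ndim == 3:
            out = out[None]
        for layer in self.layers:
            out = layer.forward(out)
        return out

    def q_values(self, state: np.ndarray) -> np.ndarray:
        """Q-values for one state; shape (4,)."""
        return self.forward(state)[0]

    def backward(self, dout: np.ndarray) -> list[np.ndarray]:
        """Gradients of all parameters given dL/d(output); call after
        forward() on the same batch."""
        grads: list[np.ndarray] = []
        d = dout.astype(_F32)
        for layer in reversed(self.layers):
            d, g = layer.backward(d)
            grads = g + grads
        return grads


class Adadelta:
    """Classic Adadelta (per-parameter running RMS of gradients and updates)."""

    def __init__(self, params: list[np.ndarray], rho: float = 0.95, eps: float = 1e-6):
        self.rho = rho
        self.eps = eps
        self.Eg2 = [np.zeros_like(p) for p in params]
        self.Edx2 = [np.zeros_like(p) for p in params]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        for p, g, eg, ed in zip(params, grads, self.Eg2, self.Edx2):
            eg *= self.rho
            eg += (1 - self.rho) * g * g
            dx = -np.sqrt((ed + self.eps) / (eg + self.eps)) * g
            ed *= self.rho
            ed += (1 - self.rho) * dx * dx
            p += dx
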