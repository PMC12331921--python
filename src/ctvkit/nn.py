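"""A small NumPy 3D convolutional network engine with analytic backprop.

No autodiff framework is assumed: convolutions are im2col matrix products
and every layer implements an explicit backward pass.  This is sized for
desk-scale volumes (≈32–64³ voxels, single sample per step), which is all
the segmentation trainer needs; it is not a general-purpose deep-learning
library.

Layers: 3×3×3 "same" convolution, 1×1×1 projection, ReLU, 2× average
pooling, 2× nearest-neighbour upsampling, channel concatenation.  The U-Net
assembles them into a symmetric encoder/decoder with skip connections and a
single-channel logit output.  Optimization is Adam.
"""

from __future__ import annotations

import dataclasses

import numpy as np

DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


class Conv3d:
    """k×k×k convolution, stride 1, zero same-padding, He initialization.

    Implemented as k³ shifted GEMMs rather than an im2col patch matrix:
    for each kernel offset the (c_out × c_in) slice multiplies the shifted
    input, which keeps memory flat and runs close to BLAS speed on the
    small channel counts used here.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k**3))
        self.w = Param(rng.standard_normal((c_out, c_in, k, k, k)) * scale)
        self.b = Param(np.zeros(c_out))
        self.k = k
        self._xp = None  # cached padded input for the backward pass

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = x.astype(DTYPE, copy=False)
        c_out = self.w.value.shape[0]
        d, h, w = x.shape[1:]
        n = d * h * w
        if self.k == 1:
            self._xp = x
            y = self.w.value.reshape(c_out, -1) @ x.reshape(x.shape[0], n)
        else:
            p = self.k // 2
            xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
            self._xp = xp
            y = np.zeros((c_out, n), dtype=DTYPE)
            for di in range(self.k):
                for dj in range(self.k):
                    for dk in range(self.k):
                        xs = np.ascontiguousarray(
                            xp[:, di:di + d, dj:dj + h, dk:dk + w]
                        ).reshape(-1, n)
                        y += self.w.value[:, :, di, dj, dk] @ xs
        return (y + self.b.value[:, None]).reshape(c_out, d, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c_out, c_in = self.w.value.shape[:2]
        d, h, w = dy.shape[1:]
        n = d * h * w
        dym = np.ascontiguousarray(dy, dtype=DTYPE).reshape(c_out, n)
        self.b.grad += dym.sum(axis=1)
        if self.k == 1:
            x2d = self._xp.reshape(c_in, n)
            self.w.grad += (dym @ x2d.T).reshape(self.w.value.shape)
            dx = (self.w.value.reshape(c_out, c_in).T @ dym).reshape(c_in, d, h, w)
        else:
            p = self.k // 2
            xp = self._xp
            dxp = np.zeros_like(xp)
            for di in range(self.k):
                for dj in range(self.k):
                    for dk in range(self.k):
                        xs = np.ascontiguousarray(
                            xp[:, di:di + d, dj:dj + h, dk:dk + w]
                        ).reshape(-1, n)
                        self.w.grad[:, :, di, dj, dk] += dym @ xs.T
                        dxp[:, di:di + d, dj:dj + h, dk:dk + w] += (
                            self.w.value[:, :, di, dj, dk].T @ dym
                        ).reshape(c_in, d, h, w)
            dx = dxp[:, p:p + d, p:p + h, p:p + w]
        self._xp = None
        return np.ascontiguousarray(dx)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class AvgPool2:
    """2× average pooling per axis (requires even extents)."""

    def params(self):
        return []

    def forward(self, x):
        c, d, h, w = x.shape
        return x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(2, 4, 6))

    def backward(self, dy):
        return np.repeat(np.repeat(np.repeat(dy, 2, 1), 2, 2), 2, 3) / 8.0


class Upsample2:
    """2× nearest-neighbour upsampling per axis."""

    def params(self):
        return []

    def forward(self, x):
        return np.repeat(np.repeat(np.repeat(x, 2, 1), 2, 2), 2, 3)

    def backward(self, dy):
        c, d, h, w = dy.shape
        return dy.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(2, 4, 6))


class ConvBlock:
    """Two (conv 3×3×3 → ReLU) units, the per-stage block of the U-Net."""

    def __init__(self, c_in, c_out, rng):
        self.layers = [Conv3d(c_in, c_out, 3, rng), ReLU(),
                       Conv3d(c_out, c_out, 3, rng), ReLU()]

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class UNet3D:
    """Symmetric encoder/decoder with concatenation skips and logit output.

    ``stages`` encoder levels with feature width doubling from
    ``base_features``; average-pool downsampling, nearest-neighbour
    upsampling, and a final 1×1×1 projection to one channel.  Input extents
    must be divisible by 2**(stages-1) (the trainer pads).
    """

    def __init__(self, in_channels: int, base_features: int = 8,
                 stages: int = 4, seed: int = 0):
        if stages < 2 or base_features < 4:
            raise ValueError("need stages >= 2 and base_features >= 4")
        rng = np.random.default_rng(seed)
        self.stages = stages
        feats = [base_features * 2**i for i in range(stages)]
        self.enc = []
        c = in_channels
        for f in feats:
            self.enc.append(ConvBlock(c, f, rng))
            c = f
        self.pools = [AvgPool2() for _ in range(stages - 1)]
        self.ups = [Upsample2() for _ in range(stages - 1)]
        self.dec = []
        for i in range(stages - 2, -1, -1):
            self.dec.append(ConvBlock(feats[i + 1] + feats[i], feats[i], rng))
        self.head = Conv3d(feats[0], 1, 1, rng)
        self._skip_channels = feats

    def params(self):
        ps = []
        for b in self.enc + self.dec:
            ps.extend(b.params())
        ps.extend(self.head.params())
        return ps

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(C, D, H, W) float input -> (D, H, W) logits."""
        x = x.astype(DTYPE)
        for ax, n in enumerate(x.shape[1:]):
            if n % 2 ** (self.stages - 1):
                raise ValueError(
                    f"axis {ax} extent {n} not divisible by "
                    f"{2 ** (self.stages - 1)}; pad the input")
        skips = []
        for i, block in enumerate(self.enc):
            x = block.forward(x)
            if i < self.stages - 1:
                skips.append(x)
                x = self.pools[i].forward(x)
        for j, block in enumerate(self.dec):
            x = self.ups[j].forward(x)
            x = np.concatenate([x, skips[-(j + 1)]], axis=0)
            x = block.forward(x)
        return self.head.forward(x)[0]

    def backward(self, dlogits: np.ndarray) -> None:
        pending = {}  # encoder level -> gradient arriving via the skip
        dy = self.head.backward(dlogits[None].astype(DTYPE))
        for j in range(len(self.dec) - 1, -1, -1):
            level = self.stages - 2 - j  # encoder level dec[j] concatenates
            dy = self.dec[j].backward(dy)
            n_up = dy.shape[0] - self._skip_channels[level]
            dy, dskip = dy[:n_up], dy[n_up:]
            dy = self.ups[j].backward(dy)
            pending[level] = dskip
        for i in range(self.stages - 1, -1, -1):
            if i < self.stages - 1:
                dy = self.pools[i].backward(dy)
                dy = dy + pending.pop(i)
            dy = self.enc[i].backward(dy)

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0

    def state(self):
        return [p.value.copy() for p in self.params()]

    def load_state(self, state):
        for p, v in zip(self.params(), state):
            p.value[...] = v


@dataclasses.dataclass
class Adam:
    """Adaptive-moment optimizer (the package's adaptive first-order default)."""

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0

    def step(self, params) -> None:
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for p in params:
            p.m = self.beta1 * p.m + (1 - self.beta1) * p.grad
            p.v = self.beta2 * p.v + (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (p.m / b1c) / (np.sqrt(p.v / b2c) + self.eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
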