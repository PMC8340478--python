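"""Minimal numpy convolutional network with dense (concatenative) skip wiring.

A small, CPU-trainable stand-in for a full densely connected classification
network, keeping the property that defines the family: inside a dense block
every layer receives the concatenation of the block input and all previous
layer outputs, so a block of L layers carries L(L+1)/2 concatenation edges.
Forward and backward passes are hand-written on numpy arrays (no deep
learning framework is required); the optimiser is SGD with Nesterov momentum
and decoupled L2 weight decay.

Tensors are NCHW float64.  He-normal initialisation throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2d",
    "Linear",
    "DenseBlock",
    "DenseNetMini",
    "SGDNesterov",
]


class Conv2d:
    """2-D convolution (cross-correlation) with 'same' or valid padding."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = (k // 2) if pad is None else pad
        self.k = k
        fan_in = in_ch * k * k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, k, k))
        self.b = np.zeros(out_ch)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        s, p, k = self.stride, self.pad, self.k
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (N, C, Ho, Wo, k, k)
        out = np.einsum("ncijuv,fcuv->nfij", win, self.w, optimize=True)
        out += self.b[None, :, None, None]
        self._cache = (win, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        win, x_shape = self._cache
        s, p, k = self.stride, self.pad, self.k
        n, c, h, w = x_shape
        ho, wo = dout.shape[2], dout.shape[3]
        self.dw += np.einsum("ncijuv,nfij->fcuv", win, dout, optimize=True)
        self.db += dout.sum(axis=(0, 2, 3))
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for u in range(k):
            for v in range(k):
                dxp[:, :, u : u + s * ho : s, v : v + s * wo : s] += np.einsum(
                    "nfij,fc->ncij", dout, self.w[:, :, u, v], optimize=True
                )
        return dxp[:, :, p : p + h, p : p + w]

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class Linear:
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.w = rng.normal(0.0, np.sqrt(2.0 / in_f), size=(in_f, out_f))
        self.b = np.zeros(out_f)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw += self._x.T @ dout
        self.db += dout.sum(axis=0)
        return dout @ self.w.T

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


def _relu_f(x):
    return np.maximum(x, 0.0)


def _avgpool2(x):
    n, c, h, w = x.shape
    return x[:, :, : h // 2 * 2, : w // 2 * 2].reshape(
        n, c, h // 2, 2, w // 2, 2
    ).mean(axis=(3, 5))


def _avgpool2_back(dout, in_shape):
    n, c, h, w = in_shape
    dx = np.zeros(in_shape)
    up = np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) / 4.0
    dx[:, :, : h // 2 * 2, : w // 2 * 2] = up
    return dx


class DenseBlock:
    """L conv+ReLU layers; layer l consumes the concatenation of the block
    input and the outputs of layers 1..l-1 and appends ``growth`` channels."""

    def __init__(self, in_ch: int, n_layers: int, growth: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_ch = in_ch
        self.growth = growth
        self.convs = [
            Conv2d(in_ch + l * growth, growth, k=3, rng=rng)
            for l in range(n_layers)
        ]
        self._cache = None

    @property
    def out_ch(self) -> int:
        return self.in_ch + len(self.convs) * self.growth

    def concatenation_edges(self) -> list[tuple[int, int]]:
        """Edges (source feature, consuming layer) of the dense wiring.

        Source 0 is the block input; source i >= 1 is layer i's output.
        Layer l consumes sources 0..l-1, giving L(L+1)/2 edges for L layers.
        """
        edges = []
        for l in range(1, len(self.convs) + 1):
            for src in range(l):
                edges.append((src, l))
        return edges

    def forward(self, x: np.ndarray) -> np.ndarray:
        feats = [x]
        masks = []
        for conv in self.convs:
            inp = np.concatenate(feats, axis=1)
            pre = conv.forward(inp)
            masks.append(pre > 0)
            feats.append(_relu_f(pre))
        self._cache = masks
        return np.concatenate(feats, axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        masks = self._cache
        chs = [self.in_ch] + [self.growth] * len(self.convs)
        bounds = np.cumsum([0] + chs)
        gfeats = [
            dout[:, bounds[i] : bounds[i + 1]].copy() for i in range(len(chs))
        ]
        for l in range(len(self.convs), 0, -1):
            g = gfeats[l] * masks[l - 1]
            dinp = self.convs[l - 1].backward(g)
            ib = np.cumsum([0] + chs[:l])
            for i in range(l):
                gfeats[i] += dinp[:, ib[i] : ib[i + 1]]
        return gfeats[0]

    def params(self):
        return [p for conv in self.convs for p in conv.params()]


class DenseNetMini:
    """Stem conv -> two dense blocks with a 1x1 transition -> GAP -> linear.

    Input: N x 3 x 64 x 64 floats in [0, 1].  Output: N x n_classes logits.
    """

    def __init__(self, n_classes: int = 2, block_layers: int = 3, growth: int = 4,
                 stem_ch: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.stem = Conv2d(3, stem_ch, k=3, stride=2, rng=rng)  # 64 -> 32
        self.block1 = DenseBlock(stem_ch, block_layers, growth, rng=rng)
        t_in = self.block1.out_ch
        self.transition = Conv2d(t_in, t_in // 2, k=1, pad=0, rng=rng)
        self.block2 = DenseBlock(t_in // 2, block_layers, growth, rng=rng)
        self.head = Linear(self.block2.out_ch, n_classes, rng=rng)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        h0 = self.stem.forward(x)
        m0 = h0 > 0
        h0 = _relu_f(h0)
        s_pool_in = h0.shape
        h1 = _avgpool2(h0)  # 32 -> 16
        h2 = self.block1.forward(h1)
        h3 = self.transition.forward(h2)
        m3 = h3 > 0
        h3 = _relu_f(h3)
        t_pool_in = h3.shape
        h4 = _avgpool2(h3)  # 16 -> 8
        h5 = self.block2.forward(h4)
        gap_in = h5.shape
        h6 = h5.mean(axis=(2, 3))
        logits = self.head.forward(h6)
        self._cache = (m0, s_pool_in, m3, t_pool_in, gap_in)
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        m0, s_pool_in, m3, t_pool_in, gap_in = self._cache
        g = self.head.backward(dlogits)
        n, c, h, w = gap_in
        g = np.broadcast_to(g[:, :, None, None], gap_in) / (h * w)
        g = self.block2.backward(np.ascontiguousarray(g))
        g = _avgpool2_back(g, t_pool_in)
        g = self.transition.backward(g * m3)
        g = self.block1.backward(g)
        g = _avgpool2_back(g, s_pool_in)
        self.stem.backward(g * m0)

    def zero_grad(self) -> None:
        for p, g in self.params():
            g[...] = 0.0

    def params(self):
        return (
            self.stem.params()
            + self.block1.params()
            + self.transition.params()
            + self.block2.params()
            + self.head.params()
        )

    # -- checkpointing ----------------------------------------------------

    def state_arrays(self) -> list[np.ndarray]:
        return [p for p, _ in self.params()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ValueError("checkpoint does not match the model architecture")
        for dst, src in zip(own, arrays):
            if dst.shape != src.shape:
                raise ValueError("checkpoint shape mismatch")
            dst[...] = src


class SGDNesterov:
    """SGD with Nesterov momentum (no dampening) and L2 weight decay."""

    def __init__(self, params, lr: float, momentum: float = 0.9,
                 weight_decay: float = 1e-4):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p) for p, _ in params]

    def step(self) -> None:
        mu = self.momentum
        for (p, g), v in zip(self.params, self.velocity):
            d = g + self.weight_decay * p
            v *= mu
            v += d
            p -= self.lr * (d + mu * v)
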