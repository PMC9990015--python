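"""A compact numpy convolutional network for six-class patch classification.

The reference classifier mirrors, at desk scale, the dual-branch topology the
framework is built around: a residual-style branch and a dense-connectivity
branch over the input patch, channel concatenation, a convolution +
average-pool head (tagged ``"post_concat"`` — the layer Grad-CAM taps), and a
three-level perceptron with two Monte-Carlo dropout layers feeding a six-way
softmax.  Forward and backward passes are written directly in numpy, which
keeps the activation/gradient plumbing needed for Grad-CAM, guided
backpropagation and Monte-Carlo dropout fully inspectable.

Array layout is ``(batch, height, width, channels)``; a depth-3 patch maps
its three slices to the three input channels.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# layers


class Conv2D:
    """3x3-style convolution, 'same'-flavoured padding, optional stride."""

    def __init__(self, c_in: int, c_out: int, ksize: int = 3, stride: int = 1,
                 pad: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * ksize * ksize
        limit = np.sqrt(6.0 / fan_in)  # He-uniform
        self.W = rng.uniform(-limit, limit, size=(c_in, ksize, ksize, c_out))
        self.b = np.zeros(c_out)
        self.ksize, self.stride, self.pad = ksize, stride, pad
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def out_hw(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.ksize, self.stride, self.pad
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        B, H, W_, C = x.shape
        k, s, p = self.ksize, self.stride, self.pad
        Ho, Wo = self.out_hw(H, W_)
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        out = np.broadcast_to(self.b, (B, Ho, Wo, self.b.size)).copy()
        for di in range(k):
            for dj in range(k):
                patch = xp[:, di:di + s * Ho:s, dj:dj + s * Wo:s, :]
                out += (patch.reshape(-1, C) @ self.W[:, di, dj, :]).reshape(
                    B, Ho, Wo, -1
                )
        return out, {"xp": xp, "in_shape": x.shape}

    def backward(self, dout: np.ndarray, cache: dict) -> np.ndarray:
        xp = cache["xp"]
        B, H, W_, C = cache["in_shape"]
        k, s, p = self.ksize, self.stride, self.pad
        Ho, Wo = dout.shape[1], dout.shape[2]
        dxp = np.zeros_like(xp)
        dW = np.zeros_like(self.W)
        dflat = dout.reshape(-1, dout.shape[-1])
        for di in range(k):
            for dj in range(k):
                patch = xp[:, di:di + s * Ho:s, dj:dj + s * Wo:s, :]
                dW[:, di, dj, :] = patch.reshape(-1, C).T @ dflat
                dxp[:, di:di + s * Ho:s, dj:dj + s * Wo:s, :] += (
                    dflat @ self.W[:, di, dj, :].T
                ).reshape(B, Ho, Wo, C)
        self.dW = dW
        self.db = dout.sum(axis=(0, 1, 2))
        if p:
            return dxp[:, p:-p, p:-p, :]
        return dxp

    def param_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        limit = np.sqrt(6.0 / n_in)
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        return x @ self.W + self.b, {"x": x}

    def backward(self, dout: np.ndarray, cache: dict) -> np.ndarray:
        self.dW = cache["x"].T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def param_grads(self):
        return [(self.W, self.dW), (self.b, self.db)]


def relu_forward(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mask = x > 0
    return x * mask, mask


def relu_backward(dout: np.ndarray, mask: np.ndarray, guided: bool) -> np.ndarray:
    dx = dout * mask
    if guided:
        # guided backpropagation additionally zeroes negative gradients
        dx = dx * (dout > 0)
    return dx


def avgpool_forward(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    B, H, W_, C = x.shape
    return x.reshape(B, H // kh, kh, W_ // kw, kw, C).mean(axis=(2, 4))


def avgpool_backward(dout: np.ndarray, kh: int, kw: int) -> np.ndarray:
    d = dout / (kh * kw)
    return np.repeat(np.repeat(d, kh, axis=1), kw, axis=2)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# the network


class DenResMini:
    """Width-reduced dual-branch patch classifier (see module docstring).

    Parameters
    ----------
    input_size
        Patch extent ``(h, w, d)``; ``h == w`` in {8, 16, 32, 64}, ``d == 3``.
    width_factor
        Scales the convolutional channel counts (base 8/8/16).
    dropout_p
        Probability for both Monte-Carlo dropout layers (active during
        training and whenever a stochastic forward pass is requested).
    """

    SUPPORTED = (8, 16, 32, 64)
    N_OUT = 6
    POOL_TARGET = 8
    # fixed affine input normalization: intensities in [0, 1] are mapped to
    # [-3, 3] so gradient magnitudes suit the fixed 1e-4 learning rate
    INPUT_OFFSET = 0.5
    INPUT_GAIN = 6.0

    def __init__(self, input_size: tuple[int, int, int], width_factor: float = 1.0,
                 dropout_p: float = 0.3, seed: int = 0):
        h, w, d = input_size
        if h != w or h not in self.SUPPORTED or d != 3:
            raise ValueError(
                f"unsupported input size {input_size}; expected (s, s, 3) with "
                f"s in {self.SUPPORTED}"
            )
        if not 0.0 <= dropout_p < 1.0:
            raise ValueError(f"dropout_p must be in [0, 1), got {dropout_p}")
        self.input_size = tuple(input_size)
        self.dropout_p = float(dropout_p)
        self.width_factor = float(width_factor)
        self.seed = int(seed)
        wf = lambda n: max(1, int(round(n * width_factor)))
        rng = np.random.default_rng(seed)
        cb, cp = wf(8), wf(16)
        self.widths = (cb, cp)
        # residual-style branch (stride-2 stem, then a residual conv)
        self.convR1 = Conv2D(3, cb, stride=2, rng=rng)
        self.convR2 = Conv2D(cb, cb, rng=rng)
        # dense-connectivity branch (features concatenated layer over layer)
        self.convD1 = Conv2D(3, cb, stride=2, rng=rng)
        self.convD2 = Conv2D(cb, cb, rng=rng)
        # post-concatenation conv + average-pool head (Grad-CAM tap)
        self.convP = Conv2D(3 * cb, cp, rng=rng)
        half = h // 2
        self.pool_k = max(1, half // self.POOL_TARGET)
        pooled = half // self.pool_k
        flat = cp * pooled * pooled
        # three-level perceptron with two Monte-Carlo dropout layers
        self.fc1 = Dense(flat, 256, rng=rng)
        self.fc2 = Dense(256, 64, rng=rng)
        self.fc3 = Dense(64, self.N_OUT, rng=rng)

    # -- plumbing ----------------------------------------------------------

    def layers(self):
        return [self.convR1, self.convR2, self.convD1, self.convD2,
                self.convP, self.fc1, self.fc2, self.fc3]

    def param_grads(self):
        for layer in self.layers():
            yield from layer.param_grads()

    def n_parameters(self) -> int:
        return sum(p.size for layer in self.layers() for p, _ in layer.param_grads())

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers()):
            out[f"l{i}_W"] = layer.W
            out[f"l{i}_b"] = layer.b
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers()):
            layer.W = np.asarray(state[f"l{i}_W"])
            layer.b = np.asarray(state[f"l{i}_b"])

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, stochastic: bool = False,
                rng: np.random.Generator | None = None) -> tuple[np.ndarray, dict]:
        """Full forward pass; returns softmax probabilities and caches."""
        if stochastic and rng is None:
            raise ValueError("stochastic forward pass requires an rng")
        x = (x - self.INPUT_OFFSET) * self.INPUT_GAIN
        c: dict = {}
        r1p, c["convR1"] = self.convR1.forward(x)
        r1, c["mR1"] = relu_forward(r1p)
        r2p, c["convR2"] = self.convR2.forward(r1)
        r, c["mR"] = relu_forward(r2p + r1)          # residual skip
        d1p, c["convD1"] = self.convD1.forward(x)
        d1, c["mD1"] = relu_forward(d1p)
        d2p, c["convD2"] = self.convD2.forward(d1)
        d2, c["mD2"] = relu_forward(d2p)
        cat = np.concatenate([r, d1, d2], axis=-1)   # dense branch keeps d1
        pp, c["convP"] = self.convP.forward(cat)
        A, c["mP"] = relu_forward(pp)
        c["post_concat"] = A
        g = avgpool_forward(A, self.pool_k, self.pool_k)
        flat = g.reshape(g.shape[0], -1)
        c["flat_shape"] = g.shape
        h1p, c["fc1"] = self.fc1.forward(flat)
        h1, c["m1"] = relu_forward(h1p)
        h1, c["drop1"] = self._dropout(h1, stochastic, rng)
        h2p, c["fc2"] = self.fc2.forward(h1)
        h2, c["m2"] = relu_forward(h2p)
        h2, c["drop2"] = self._dropout(h2, stochastic, rng)
        logits, c["fc3"] = self.fc3.forward(h2)
        c["logits"] = logits
        return softmax(logits), c

    def _dropout(self, x, stochastic, rng):
        if not stochastic or self.dropout_p == 0.0:
            return x, None
        keep = rng.random(x.shape) >= self.dropout_p
        scale = keep / (1.0 - self.dropout_p)
        return x * scale, scale

    def backward(self, dlogits: np.ndarray, c: dict, guided: bool = False,
                 capture: str | None = None) -> tuple[np.ndarray, np.ndarray | None]:
        """Backpropagate ``dlogits``; returns (dx, gradient at captured tag)."""
        dh2 = self.fc3.backward(dlogits, c["fc3"])
        if c["drop2"] is not None:
            dh2 = dh2 * c["drop2"]
        dh2 = relu_backward(dh2, c["m2"], guided)
        dh1 = self.fc2.backward(dh2, c["fc2"])
        if c["drop1"] is not None:
            dh1 = dh1 * c["drop1"]
        dh1 = relu_backward(dh1, c["m1"], guided)
        dflat = self.fc1.backward(dh1, c["fc1"])
        dg = dflat.reshape(c["flat_shape"])
        dA = avgpool_backward(dg, self.pool_k, self.pool_k)
        dA = relu_backward(dA, c["mP"], guided)
        captured = dA.copy() if capture == "post_concat" else None
        dcat = self.convP.backward(dA, c["convP"])
        cb = self.widths[0]
        dr, dd1_cat, dd2 = (
            dcat[..., :cb], dcat[..., cb:2 * cb], dcat[..., 2 * cb:]
        )
        dd2 = relu_backward(dd2, c["mD2"], guided)
        dd1 = self.convD2.backward(dd2, c["convD2"]) + dd1_cat
        dd1 = relu_backward(dd1, c["mD1"], guided)
        dxD = self.convD1.backward(dd1, c["convD1"])
        dsum = relu_backward(dr, c["mR"], guided)
        dr1 = self.convR2.backward(dsum, c["convR2"]) + dsum  # skip path
        dr1 = relu_backward(dr1, c["mR1"], guided)
        dxR = self.convR1.backward(dr1, c["convR1"])
        # chain through the fixed input normalization
        return (dxR + dxD) * self.INPUT_GAIN, captured
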