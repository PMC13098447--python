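"""Minimal NumPy convolutional-network engine for the collagen U-Nets.

Implements exactly the primitives the segmentation architecture needs —
3x3/1x1 same-padding convolutions, ReLU, 2x2 max pooling, fixed bilinear
2x upsampling, additive attention gates, a sigmoid/binary-cross-entropy
head and the Adam optimizer — each with an analytically derived backward
pass (verified against numerical gradients in the test suite).

Tensors are channels-last ``(N, H, W, C)`` float32; convolutions are
evaluated as nine shifted BLAS matmuls (shift-and-accumulate), which on a
single CPU core is considerably faster than an im2col lowering for 3x3
kernels at these channel widths.
"""

from __future__ import annotations

import numpy as np

__all__ = ["UNet", "Adam", "bce_with_logits", "sigmoid"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy of logits ``z`` against targets ``y``; returns (loss, dz)."""
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    dz = (sigmoid(z) - y) / z.size
    return loss, dz.astype(z.dtype)


class _Conv:
    """Same-padding stride-1 convolution with bias; odd kernel size.

    Weights are stored as ``(k, k, cin, cout)``; init is the standard
    uniform fan-in scheme ``U(-1/sqrt(fan_in), 1/sqrt(fan_in))``.
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(cin * k * k)
        self.W = rng.uniform(-bound, bound, size=(k, k, cin, cout)).astype(np.float32)
        self.b = rng.uniform(-bound, bound, size=cout).astype(np.float32)
        self.k = k
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None
        self._xp: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, pad = self.k, self.k // 2
        n, h, w, _ = x.shape
        if k == 1:
            self._x = x
            out = np.tensordot(x, self.W[0, 0], axes=([3], [0]))
        else:
            xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
            self._xp = xp
            out = np.tensordot(xp[:, 0:h, 0:w], self.W[0, 0], axes=([3], [0]))
            for di in range(k):
                for dj in range(k):
                    if di == 0 and dj == 0:
                        continue
                    out += np.tensordot(xp[:, di : di + h, dj : dj + w], self.W[di, dj], axes=([3], [0]))
        return out + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        k, pad = self.k, self.k // 2
        n, h, w, _ = g.shape
        self.gb[:] = g.sum(axis=(0, 1, 2))
        if k == 1:
            self.gW[0, 0] = np.tensordot(self._x, g, axes=([0, 1, 2], [0, 1, 2]))
            self._x = None
            return np.tensordot(g, self.W[0, 0].T, axes=([3], [0]))
        xp = self._xp
        for di in range(k):
            for dj in range(k):
                self.gW[di, dj] = np.tensordot(
                    xp[:, di : di + h, dj : dj + w], g, axes=([0, 1, 2], [0, 1, 2])
                )
        self._xp = None
        # input gradient = full correlation with the 180-rotated, transposed kernel
        gp = np.pad(g, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        gx = np.tensordot(gp[:, 0:h, 0:w], self.W[k - 1, k - 1].T, axes=([3], [0]))
        for di in range(k):
            for dj in range(k):
                if di == 0 and dj == 0:
                    continue
                gx += np.tensordot(
                    gp[:, di : di + h, dj : dj + w],
                    self.W[k - 1 - di, k - 1 - dj].T,
                    axes=([3], [0]),
                )
        return gx

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def n_params(self) -> int:
        return self.W.size + self.b.size


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class _MaxPool2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        v = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        v = np.ascontiguousarray(v).reshape(n, h // 2, w // 2, 4, c)
        self._idx = v.argmax(axis=3)
        self._xshape = x.shape
        return np.take_along_axis(v, self._idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, h, w, c = self._xshape
        gv = np.zeros((n, h // 2, w // 2, 4, c), dtype=g.dtype)
        np.put_along_axis(gv, self._idx[:, :, :, None, :], g[:, :, :, None, :], axis=3)
        gx = gv.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        return np.ascontiguousarray(gx).reshape(n, h, w, c)


_UP_CACHE: dict[int, np.ndarray] = {}


def _up_matrix(n: int) -> np.ndarray:
    """(2n x n) bilinear interpolation matrix, half-pixel-centered (align_corners=False)."""
    if n not in _UP_CACHE:
        src = np.clip((np.arange(2 * n) + 0.5) / 2.0 - 0.5, 0.0, n - 1.0)
        i0 = np.floor(src).astype(int)
        i1 = np.minimum(i0 + 1, n - 1)
        w1 = (src - i0).astype(np.float32)
        A = np.zeros((2 * n, n), dtype=np.float32)
        A[np.arange(2 * n), i0] += 1.0 - w1
        A[np.arange(2 * n), i1] += w1
        _UP_CACHE[n] = A
    return _UP_CACHE[n]


class _BilinearUp2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        self._hw = (h, w)
        Ah, Aw = _up_matrix(h), _up_matrix(w)
        y = np.einsum("ph,nhwc->npwc", Ah, x, optimize=True)
        return np.einsum("qw,npwc->npqc", Aw, y, optimize=True)

    def backward(self, g: np.ndarray) -> np.ndarray:
        h, w = self._hw
        Ah, Aw = _up_matrix(h), _up_matrix(w)
        y = np.einsum("qw,npqc->npwc", Aw, g, optimize=True)
        return np.einsum("ph,npwc->nhwc", Ah, y, optimize=True)


class _AttentionGate:
    """Additive attention: skip is rescaled by sigmoid(psi(relu(theta(skip) + phi(gate))))."""

    def __init__(self, channels: int, rng: np.random.Generator):
        inter = max(channels // 2, 1)
        self.theta = _Conv(channels, inter, 1, rng)
        self.phi = _Conv(channels, inter, 1, rng)
        self.psi = _Conv(inter, 1, 1, rng)

    def forward(self, skip: np.ndarray, gate: np.ndarray) -> np.ndarray:
        self._skip = skip
        f = self.theta.forward(skip) + self.phi.forward(gate)
        self._mask = f > 0
        self._alpha = sigmoid(self.psi.forward(f * self._mask))
        return skip * self._alpha

    def backward(self, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        galpha = (g * self._skip).sum(axis=3, keepdims=True)
        gz = galpha * self._alpha * (1.0 - self._alpha)
        gf = self.psi.backward(gz.astype(g.dtype)) * self._mask
        gskip = self.theta.backward(gf) + g * self._alpha
        ggate = self.phi.backward(gf)
        self._skip = None
        return gskip, ggate

    def convs(self):
        return [self.theta, self.phi, self.psi]


class UNet:
    """Downsized U-Net: ``stacked_down`` 3x3 conv+ReLU blocks per encoder level
    with 2x2 max pooling, bilinear 2x upsampling followed by a channel-halving
    3x3 conv, skip concatenation, ``stacked_up`` conv+ReLU blocks per decoder
    level, and a 1x1 sigmoid head.  No normalization layers; biases everywhere.
    """

    def __init__(
        self,
        depth: int = 3,
        filters: tuple[int, ...] = (8, 16, 32),
        stacked_down: int = 2,
        stacked_up: int = 2,
        in_channels: int = 3,
        attention: bool = False,
        seed: int = 0,
    ):
        if len(filters) != depth:
            raise ValueError("len(filters) must equal depth")
        if depth < 1 or any(f < 1 for f in filters) or stacked_down < 1 or stacked_up < 1:
            raise ValueError("invalid architecture configuration")
        self.depth = depth
        self.filters = tuple(int(f) for f in filters)
        self.stacked_down = stacked_down
        self.stacked_up = stacked_up
        self.in_channels = in_channels
        self.attention = attention
        self.seed = seed
        rng = np.random.default_rng(seed)

        self.enc: list[list] = []
        cin = in_channels
        for i in range(depth):
            level = []
            for s in range(stacked_down):
                level.append(_Conv(cin if s == 0 else self.filters[i], self.filters[i], 3, rng))
                level.append(_ReLU())
            self.enc.append(level)
            cin = self.filters[i]
        self.pools = [_MaxPool2() for _ in range(depth - 1)]

        self.ups: list[_BilinearUp2] = []
        self.upconvs: list[_Conv] = []
        self.uprelus: list[_ReLU] = []
        self.gates: list[_AttentionGate | None] = []
        self.dec: list[list] = []
        for i in range(depth - 2, -1, -1):
            self.ups.append(_BilinearUp2())
            self.upconvs.append(_Conv(self.filters[i + 1], self.filters[i], 3, rng))
            self.uprelus.append(_ReLU())
            self.gates.append(_AttentionGate(self.filters[i], rng) if attention else None)
            level = []
            for s in range(stacked_up):
                cin_s = 2 * self.filters[i] if s == 0 else self.filters[i]
                level.append(_Conv(cin_s, self.filters[i], 3, rng))
                level.append(_ReLU())
            self.dec.append(level)
        self.head = _Conv(self.filters[0], 1, 1, rng)

    # -- graph traversal -------------------------------------------------

    def _all_convs(self) -> list[_Conv]:
        convs: list[_Conv] = []
        for level in self.enc:
            convs.extend(l for l in level if isinstance(l, _Conv))
        for i, upconv in enumerate(self.upconvs):
            convs.append(upconv)
            if self.gates[i] is not None:
                convs.extend(self.gates[i].convs())
            convs.extend(l for l in self.dec[i] if isinstance(l, _Conv))
        convs.append(self.head)
        return convs

    def count_parameters(self) -> int:
        return sum(c.n_params() for c in self._all_convs())

    def parameters(self):
        out = []
        for c in self._all_convs():
            out.extend(c.params())
        return out

    # -- forward / backward ----------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, H, W, C) float32 in [0, 1]; returns logits (N, H, W, 1)."""
        h, w = x.shape[1], x.shape[2]
        div = 2 ** (self.depth - 1)
        if h % div or w % div:
            raise ValueError(f"input size {h}x{w} not divisible by {div}; pad the tile first")
        skips = []
        for i, level in enumerate(self.enc):
            for layer in level:
                x = layer.forward(x)
            if i < self.depth - 1:
                skips.append(x)
                x = self.pools[i].forward(x)
        self._concat_channels = []
        for j in range(self.depth - 1):
            x = self.ups[j].forward(x)
            x = self.uprelus[j].forward(self.upconvs[j].forward(x))
            skip = skips[-(j + 1)]
            if self.gates[j] is not None:
                skip = self.gates[j].forward(skip, x)
            self._concat_channels.append(skip.shape[3])
            x = np.concatenate([skip, x], axis=3)
            for layer in self.dec[j]:
                x = layer.forward(x)
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.head.backward(dlogits)
        gskips = []
        for j in range(self.depth - 2, -1, -1):
            for layer in reversed(self.dec[j]):
                g = layer.backward(g)
            cs = self._concat_channels[j]
            gskip, g = g[:, :, :, :cs], g[:, :, :, cs:]
            if self.gates[j] is not None:
                gskip, ggate = self.gates[j].backward(gskip)
                g = g + ggate
            gskips.append(gskip)
            g = self.upconvs[j].backward(self.uprelus[j].backward(g))
            g = self.ups[j].backward(g)
        for i in range(self.depth - 1, -1, -1):
            if i < self.depth - 1:
                g = self.pools[i].backward(g)
                g = g + gskips[i]  # gskips[i] holds the skip gradient of level i
            for layer in reversed(self.enc[i]):
                g = layer.backward(g)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Sigmoid probabilities for a batch; forward pass only."""
        return sigmoid(self.forward(x))

    def astype(self, dtype) -> "UNet":
        """Cast all weights in place (float64 is used for gradient verification)."""
        for c in self._all_convs():
            c.W = c.W.astype(dtype)
            c.b = c.b.astype(dtype)
            c.gW = np.zeros_like(c.W)
            c.gb = np.zeros_like(c.b)
        return self

    # -- serialization ---------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {
            f"conv{i}.{nm}": getattr(c, nm)
            for i, c in enumerate(self._all_convs())
            for nm in ("W", "b")
        }

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, c in enumerate(self._all_convs()):
            c.W = np.asarray(state[f"conv{i}.W"], dtype=np.float32)
            c.b = np.asarray(state[f"conv{i}.b"], dtype=np.float32)
            c.gW = np.zeros_like(c.W)
            c.gb = np.zeros_like(c.b)


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params  # list of (value, grad) array pairs, updated in place
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
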