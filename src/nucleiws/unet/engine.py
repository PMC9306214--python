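"""A compact CPU conv-net engine (float32, BLAS-backed) with manual backprop.

Only what the U-Nets here need: same-padded N-D convolutions implemented as
one GEMM per kernel offset (no im2col blow-up), 2x2(x1) max pooling over the
in-plane axes, zero-stuffing transposed convolutions, skip concatenation,
ReLU, a fused sigmoid + binary-cross-entropy head, and Adam.

Array layout is channels-last: ``(B, Y, X, C)`` in 2D and ``(B, Z, Y, X, C)``
in 3D; pooling and upsampling always act on the two axes preceding C (the
in-plane axes), which realises the 2x2 (2D) and 2x2x1 (3D) factors.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

F32 = np.float32


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> List[Tuple[np.ndarray, np.ndarray]]:
        """(value, gradient) pairs."""
        return []


def _kernel_offsets(ndim: int, k: int = 3):
    ranges = [range(k)] * ndim
    out = []
    def rec(prefix, rest):
        if not rest:
            out.append(tuple(prefix))
            return
        for v in rest[0]:
            rec(prefix + [v], rest[1:])
    rec([], ranges)
    return out


class Conv(Layer):
    """Same-padded convolution, kernel 3 (or 1) per spatial axis, + bias."""

    def __init__(self, cin: int, cout: int, ndim: int, kernel: int = 3,
                 rng: Optional[np.random.Generator] = None):
        self.cin, self.cout, self.ndim, self.kernel = cin, cout, ndim, kernel
        rng = rng or np.random.default_rng(0)
        fan_in = cin * kernel ** ndim
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU stacks
        shape = (kernel,) * ndim + (cin, cout)
        self.W = (rng.standard_normal(shape) * scale).astype(F32)
        self.b = np.zeros(cout, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._offsets = _kernel_offsets(ndim, kernel)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def _pad(self, x):
        if self.kernel == 1:
            return x
        p = self.kernel // 2
        pad = [(0, 0)] + [(p, p)] * self.ndim + [(0, 0)]
        return np.pad(x, pad)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        spatial = x.shape[1:-1]
        xp = self._pad(x)
        out = np.empty(x.shape[:-1] + (self.cout,), dtype=F32)
        out[:] = self.b
        flat_out = out.reshape(-1, self.cout)
        for off in self._offsets:
            sl = (slice(None),) + tuple(slice(o, o + s) for o, s in zip(off, spatial))
            xs = xp[sl].reshape(-1, self.cin)
            flat_out += xs @ self.W[off]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        spatial = x.shape[1:-1]
        xp = self._pad(x)
        gxp = np.zeros_like(xp)
        gflat = grad.reshape(-1, self.cout)
        self.db[:] = gflat.sum(axis=0)
        for off in self._offsets:
            sl = (slice(None),) + tuple(slice(o, o + s) for o, s in zip(off, spatial))
            xs = xp[sl].reshape(-1, self.cin)
            self.dW[off] = xs.T @ gflat
            gxp[sl] += (gflat @ self.W[off].T).reshape(xp[sl].shape)
        if self.kernel == 1:
            return gxp
        p = self.kernel // 2
        core = (slice(None),) + tuple(slice(p, p + s) for s in spatial) + (slice(None),)
        return gxp[core]


class ReLU(Layer):
    def forward(self, x):
        self._m = x > 0
        return np.where(self._m, x, F32(0))

    def backward(self, grad):
        return np.where(self._m, grad, F32(0))


class MaxPool2(Layer):
    """2x2 max pooling over the two axes preceding the channel axis."""

    def forward(self, x):
        *lead, Y, X, C = x.shape
        self._shape = x.shape
        v = x.reshape(*lead, Y // 2, 2, X // 2, 2, C)
        cand = np.stack([v[..., 0, :, 0, :], v[..., 0, :, 1, :],
                         v[..., 1, :, 0, :], v[..., 1, :, 1, :]], axis=-1)
        self._arg = cand.argmax(axis=-1)
        return cand.max(axis=-1)

    def backward(self, grad):
        *lead, Y, X, C = self._shape
        g = np.zeros(self._shape, dtype=F32).reshape(*lead, Y // 2, 2, X // 2, 2, C)
        a = self._arg
        for q in range(4):
            sel = a == q
            g[..., q // 2, :, q % 2, :][sel] = grad[sel]
        return g.reshape(self._shape)


class ZeroStuffUp2(Layer):
    """x2 zero-stuffing upsample on the two axes preceding C (transposed-conv
    front half; a trailing Conv supplies the learnable kernel)."""

    def forward(self, x):
        *lead, Y, X, C = x.shape
        out = np.zeros((*lead, 2 * Y, 2 * X, C), dtype=F32)
        out[..., ::2, ::2, :] = x
        return out

    def backward(self, grad):
        return np.ascontiguousarray(grad[..., ::2, ::2, :])


class SigmoidBCE:
    """Fused sigmoid + (optionally voxel-weighted) binary cross-entropy."""

    EPS = 1e-7

    def forward(self, logits: np.ndarray, target: np.ndarray,
                weights: Optional[np.ndarray] = None) -> float:
        p = 1.0 / (1.0 + np.exp(-logits.astype(np.float64)))
        self._p, self._t = p, target
        self._w = weights
        pc = np.clip(p, self.EPS, 1 - self.EPS)
        ll = -(target * np.log(pc) + (1 - target) * np.log(1 - pc))
        if weights is not None:
            self._norm = float(weights.sum())
            return float((ll * weights).sum() / self._norm)
        self._norm = float(ll.size)
        return float(ll.mean())

    def backward(self) -> np.ndarray:
        g = (self._p - self._t)
        if self._w is not None:
            g = g * self._w
        return (g / self._norm).astype(F32)

    @staticmethod
    def probabilities(logits: np.ndarray) -> np.ndarray:
        return (1.0 / (1.0 + np.exp(-logits.astype(np.float64)))).astype(F32)


class Adam:
    def __init__(self, params: List[Tuple[np.ndarray, np.ndarray]],
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


# ---------------------------------------------------------------------------
# Graph pieces: sequential trunk with explicit skip bookkeeping
# ---------------------------------------------------------------------------

class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad

    def params(self):
        out = []
        for l in self.layers:
            out.extend(l.params())
        return out


class UNetGraph:
    """Encoder/decoder with skip concatenation; variant-agnostic.

    ``encoders`` are per-level Sequentials applied before pooling; the last
    entry is the bottleneck (no pool).  Each decoder level holds an
    up-block (zero-stuff + conv) and a post-concat Sequential.
    """

    def __init__(self, encoders: List[Sequential], decoders: List[Tuple[Sequential, Sequential]],
                 final: Conv):
        self.encoders = encoders
        self.decoders = decoders
        self.final = final

    def forward(self, x: np.ndarray) -> np.ndarray:
        skips = []
        self._pools = []
        for enc in self.encoders[:-1]:
            x = enc.forward(x)
            skips.append(x)
            pool = MaxPool2()
            x = pool.forward(x)
            self._pools.append(pool)
        x = self.encoders[-1].forward(x)
        self._skips = skips
        self._splits = []
        for (up, post), skip in zip(self.decoders, reversed(skips)):
            x = up.forward(x)
            self._splits.append(x.shape[-1])
            x = np.concatenate([x, skip], axis=-1)
            x = post.forward(x)
        return self.final.forward(x)

    def backward(self, grad: np.ndarray) -> None:
        grad = self.final.backward(grad)
        skip_grads = [None] * len(self._skips)
        n = len(self.decoders)
        for i in range(n - 1, -1, -1):
            up, post = self.decoders[i]
            grad = post.backward(grad)
            c = self._splits[i]
            gskip = grad[..., c:]
            skip_grads[n - 1 - i] = gskip
            grad = up.backward(np.ascontiguousarray(grad[..., :c]))
        grad = self.encoders[-1].backward(grad)
        for i in range(len(self.encoders) - 2, -1, -1):
            grad = self._pools[i].backward(grad)
            grad = grad + skip_grads[i]   # skip_grads is indexed by skip level
            grad = self.encoders[i].backward(grad)

    def params(self):
        out = []
        for enc in self.encoders:
            out.extend(enc.params())
        for up, post in self.decoders:
            out.extend(up.params())
            out.extend(post.params())
        out.extend(self.final.params())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.params()))

    def get_weights(self) -> List[np.ndarray]:
        return [p.copy() for p, _ in self.params()]

    def set_weights(self, weights: List[np.ndarray]) -> None:
        for (p, _), w in zip(self.params(), weights):
            p[...] = w
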