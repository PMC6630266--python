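"""Minimal dense/convolutional network engine in numpy.

The classifier operates on tiny inputs (8 x 8 x 4 reduced-spectrogram
tiles), so a straightforward numpy implementation with explicit backprop is
fast, dependency-free and fully deterministic under a seed. Layers follow
the NHWC convention (batch, rows, cols, channels). Convolutions use "same"
zero padding (TensorFlow convention for even kernels: less padding before,
more after), max pooling is 2 x 2 with stride 2 (a dimension of size 1 is
left untouched), and dropout is the inverted variant, active only during
training.

Everything is float64: gradient checks against central differences are part
of the test contract.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "MaxPool2D",
    "ReLU",
    "Dropout",
    "Flatten",
    "Dense",
    "Concat",
    "Sequential",
    "ParallelBranches",
    "Adam",
    "softmax",
    "cross_entropy",
    "Network",
]


def softmax(scores: np.ndarray) -> np.ndarray:
    """Row-wise softmax with overflow-safe shifting.

    Accepts a single score vector or a (batch, classes) matrix; the output
    rows are non-negative and sum to one.
    """
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("softmax of an empty score vector")
    squeeze = s.ndim == 1
    s = np.atleast_2d(s)
    if not np.all(np.isfinite(s)):
        raise ValueError("softmax requires finite scores")
    z = s - s.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    return p[0] if squeeze else p


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-likelihood of integer labels under row probabilities."""
    p = probs[np.arange(len(labels)), labels]
    return float(-np.mean(np.log(np.clip(p, 1e-12, None))))


class Layer:
    """Forward/backward building block; parameters exposed for the optimiser."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


def _same_pad(k: int) -> tuple[int, int]:
    before = (k - 1) // 2
    return before, k - 1 - before


class Conv2D(Layer):
    """2-D convolution (cross-correlation), "same" padding, stride 1, He init."""

    def __init__(self, kh: int, kw: int, cin: int, cout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (kh * kw * cin))
        self.W = rng.normal(0.0, scale, size=(kh, kw, cin, cout))
        self.b = np.zeros(cout)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x_pad: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        kh, kw, cin, cout = self.W.shape
        if x.shape[3] != cin:
            raise ValueError(f"expected {cin} input channels, got {x.shape[3]}")
        pt, pb = _same_pad(kh)
        pl, pr = _same_pad(kw)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        B, H, W_, _ = x.shape
        out = np.broadcast_to(self.b, (B, H, W_, cout)).copy()
        for di in range(kh):
            for dj in range(kw):
                patch = xp[:, di : di + H, dj : dj + W_, :]
                out += np.tensordot(patch, self.W[di, dj], axes=([3], [0]))
        self._x_pad = xp
        self._in_shape = x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        kh, kw, cin, cout = self.W.shape
        xp = self._x_pad
        B, H, W_, _ = self._in_shape
        pt, _ = _same_pad(kh)
        pl, _ = _same_pad(kw)
        self.dW[...] = 0.0
        dxp = np.zeros_like(xp)
        for di in range(kh):
            for dj in range(kw):
                patch = xp[:, di : di + H, dj : dj + W_, :]
                # dW[di,dj,c,f] = sum_{b,i,j} x_pad[b,i+di,j+dj,c] * grad[b,i,j,f]
                self.dW[di, dj] = np.tensordot(patch, grad, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, di : di + H, dj : dj + W_, :] += np.tensordot(grad, self.W[di, dj], axes=([3], [1]))
        self.db[...] = grad.sum(axis=(0, 1, 2))
        return dxp[:, pt : pt + H, pl : pl + W_, :]

    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.db]


class MaxPool2D(Layer):
    """Max pooling, nominal 2 x 2 / stride 2; a size-1 axis is not pooled.

    Trailing rows/cols that do not fill a window are dropped (floor mode).
    """

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, H, W_, C = x.shape
        sh = self.size if H >= self.size else 1
        sw = self.size if W_ >= self.size else 1
        Ho, Wo = H // sh, W_ // sw
        xc = x[:, : Ho * sh, : Wo * sw, :]
        xr = xc.reshape(B, Ho, sh, Wo, sw, C)
        out = xr.max(axis=(2, 4))
        # ties share the gradient equally (see backward); with continuous
        # activations exact ties are vanishingly rare
        self._mask = xr == out[:, :, None, :, None, :]
        self._x_shape = x.shape
        self._pool = (sh, sw, Ho, Wo)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, H, W_, C = self._x_shape
        sh, sw, Ho, Wo = self._pool
        counts = self._mask.sum(axis=(2, 4), keepdims=True)
        g = (self._mask / counts) * grad[:, :, None, :, None, :]
        dx = np.zeros(self._x_shape)
        dx[:, : Ho * sh, : Wo * sw, :] = g.reshape(B, Ho * sh, Wo * sw, C)
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not (0 <= p < 1):
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1 - self.p)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.db]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self) -> list[np.ndarray]:
        return [p for l in self.layers for p in l.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for l in self.layers for g in l.grads()]


class ParallelBranches(Layer):
    """Feed the same input through each branch, concatenate flat outputs."""

    def __init__(self, branches: list[Sequential]):
        self.branches = branches

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        outs = [b.forward(x, train) for b in self.branches]
        self._widths = [o.shape[1] for o in outs]
        return np.concatenate(outs, axis=1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        dx = None
        offset = 0
        for b, w in zip(self.branches, self._widths):
            g = b.backward(grad[:, offset : offset + w])
            dx = g if dx is None else dx + g
            offset += w
        return dx

    def params(self) -> list[np.ndarray]:
        return [p for b in self.branches for p in b.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for b in self.branches for g in b.grads()]


class Adam:
    """Adaptive-moment-estimation optimiser with bias correction."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g**2
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class Network:
    """A layer graph with a softmax/cross-entropy head and minibatch training."""

    def __init__(self, body: Layer, n_params_note: str = ""):
        self.body = body
        self.note = n_params_note

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.body.forward(x, train)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.logits(x, train=False))

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.body.params()))

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray, train: bool = True) -> float:
        """Forward + backward pass; leaves gradients in the layers."""
        logits = self.body.forward(x, train)
        probs = softmax(logits)
        loss = cross_entropy(probs, y)
        grad = probs.copy()
        grad[np.arange(len(y)), y] -= 1.0
        grad /= len(y)
        self.body.backward(grad)
        return loss

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        *,
        epochs: int = 50,
        batch_size: int = 32,
        lr: float = 1e-3,
        seed: int = 0,
        patience: int | None = None,
        val_fraction: float = 0.0,
    ) -> list[float]:
        """Minibatch Adam training; returns the per-epoch mean loss history.

        A batch of training examples is drawn (by shuffling) each epoch;
        optional early stopping watches held-out loss with the given
        patience. Fully deterministic under ``seed``.
        """
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain at least two classes")
        rng = np.random.default_rng(seed)
        n = len(x)
        n_val = int(round(val_fraction * n)) if patience else 0
        if n_val:
            perm = rng.permutation(n)
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            xv, yv = x[val_idx], y[val_idx]
            x, y = x[tr_idx], y[tr_idx]
            n = len(x)
        opt = Adam(self.body.params(), lr=lr)
        history: list[float] = []
        best_val, since_best = np.inf, 0
        for _epoch in range(epochs):
            order = rng.permutation(n)
            losses = []
            for i in range(0, n, batch_size):
                idx = order[i : i + batch_size]
                loss = self.loss_and_grad(x[idx], y[idx], train=True)
                opt.step(self.body.grads())
                losses.append(loss)
            history.append(float(np.mean(losses)))
            if n_val:
                val_loss = cross_entropy(self.predict_proba(xv), yv)
                if val_loss < best_val - 1e-6:
                    best_val, since_best = val_loss, 0
                else:
                    since_best += 1
                    if patience is not None and since_best >= patience:
                        break
        return history
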