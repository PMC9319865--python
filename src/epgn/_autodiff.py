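"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the operations the unrolled reconstruction network needs:
3x3 / 1x1 bias-free convolutions, ReLU, channel-wise soft shrinkage,
momentum interpolation, learnable data-fidelity gradient steps, embedded
attention (pairwise logits, row softmax, weighted aggregation), channel
concatenation, and a mean squared-error loss.  Every op records its parents
and a closure that accumulates gradients; `backward` runs a topological
sweep from the loss.

Gradients of every op are validated against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "add",
    "lincomb",
    "conv2d",
    "conv1x1",
    "relu",
    "soft_shrink_op",
    "fidelity_step",
    "pairwise_logits",
    "softmax_last",
    "attend",
    "concat_channels",
    "flatten_hw",
    "unflatten_hw",
    "mse_loss",
    "Adam",
]


class Tensor:
    """A numpy array plus gradient bookkeeping.

    ``requires_grad`` marks learnable leaves; interior nodes receive
    gradients whenever any ancestor requires them.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Reverse sweep seeding d(self)/d(self) = 1 (self must be scalar)."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep for many phases
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
        out.requires_grad = False
    return out


# ---------------------------------------------------------------------------
# elementwise / linear ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def backward(g):
        a._accum(g)
        b._accum(g)

    return _node(data, (a, b), backward)


def lincomb(x: Tensor, x_prev: Tensor, gamma: Tensor) -> Tensor:
    """Momentum interpolation ``x + gamma * (x - x_prev)`` with learnable gamma."""
    x, x_prev, gamma = _as_tensor(x), _as_tensor(x_prev), _as_tensor(gamma)
    diff = x.data - x_prev.data
    data = x.data + gamma.data * diff

    def backward(g):
        x._accum(g * (1.0 + gamma.data))
        x_prev._accum(-gamma.data * g)
        gamma._accum(np.sum(g * diff).reshape(gamma.data.shape))

    return _node(data, (x, x_prev, gamma), backward)


def relu(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0
    data = np.where(mask, x.data, 0.0)

    def backward(g):
        x._accum(g * mask)

    return _node(data, (x,), backward)


def soft_shrink_op(z: Tensor, theta: Tensor) -> Tensor:
    """Channel-wise soft shrinkage ``sign(z) * max(|z| - theta_c, 0)``.

    ``z`` is (N, C, H, W); ``theta`` is length-C, broadcast per channel.
    Negative thresholds are permitted (the formula stays well defined).
    """
    z, theta = _as_tensor(z), _as_tensor(theta)
    th = theta.data.reshape(1, -1, 1, 1)
    mag = np.abs(z.data) - th
    active = mag > 0
    sgn = np.sign(z.data)
    data = np.where(active, sgn * mag, 0.0)

    def backward(g):
        z._accum(g * active)
        theta._accum(-np.sum(g * sgn * active, axis=(0, 2, 3)))

    return _node(data, (z, theta), backward)


def conv2d(x: Tensor, kernel: Tensor) -> Tensor:
    """Bias-free 3x3 (or any odd-size) correlation, stride 1, zero same-padding.

    ``x``: (N, Cin, H, W); ``kernel``: (Cout, Cin, kh, kw).
    """
    x, kernel = _as_tensor(x), _as_tensor(kernel)
    kh, kw = kernel.data.shape[2:]
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (N,Cin,H,W,kh,kw)
    data = np.einsum("nchwij,ocij->nohw", win, kernel.data, optimize=True)

    def backward(g):
        if kernel.requires_grad or kernel._parents:
            kernel._accum(np.einsum("nchwij,nohw->ocij", win, g, optimize=True))
        if x.requires_grad or x._parents:
            # transpose conv: correlate g with spatially flipped, swapped kernel
            kT = kernel.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            gp = np.pad(g, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
            gwin = sliding_window_view(gp, (kh, kw), axis=(2, 3))
            x._accum(np.einsum("nohwij,coij->nchw", gwin, kT, optimize=True))

    return _node(data, (x, kernel), backward)


def conv1x1(x: Tensor, weight: Tensor) -> Tensor:
    """Pointwise channel projection; ``weight`` is (Cout, Cin)."""
    x, weight = _as_tensor(x), _as_tensor(weight)
    data = np.einsum("oc,nchw->nohw", weight.data, x.data, optimize=True)

    def backward(g):
        if weight.requires_grad or weight._parents:
            weight._accum(np.einsum("nohw,nchw->oc", g, x.data, optimize=True))
        if x.requires_grad or x._parents:
            x._accum(np.einsum("oc,nohw->nchw", weight.data, g, optimize=True))

    return _node(data, (x, weight), backward)


def fidelity_step(x: Tensor, alpha: Tensor, op, y: np.ndarray) -> Tensor:
    """Gradient-descent step on the data-fidelity term with learnable step size.

    Computes ``x - alpha * A^H (A x - y)`` (real part for complex operators).
    ``op`` supplies batched forward / gram products; ``y`` is a constant
    (N, m) measurement batch.
    """
    x, alpha = _as_tensor(x), _as_tensor(alpha)
    gradf = op.batch_gradient(x.data, y)  # real, shape of x
    data = x.data - alpha.data * gradf

    def backward(g):
        if x.requires_grad or x._parents:
            x._accum(g - alpha.data * op.batch_gram(g))
        alpha._accum(-np.sum(g * gradf).reshape(alpha.data.shape))

    return _node(data, (x, alpha), backward)


# ---------------------------------------------------------------------------
# attention ops
# ---------------------------------------------------------------------------

def flatten_hw(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C, H*W)."""
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    data = x.data.reshape(n, c, h * w)

    def backward(g):
        x._accum(g.reshape(n, c, h, w))

    return _node(data, (x,), backward)


def unflatten_hw(x: Tensor, h: int, w: int) -> Tensor:
    """(N, C, H*W) -> (N, C, H, W)."""
    x = _as_tensor(x)
    n, c, _ = x.data.shape
    data = x.data.reshape(n, c, h, w)

    def backward(g):
        x._accum(g.reshape(n, c, h * w))

    return _node(data, (x,), backward)


def pairwise_logits(a: Tensor, b: Tensor) -> Tensor:
    """Embedded dot products: (N,C,P) x (N,C,P) -> (N,P,P); out[n,i,j] = <a_i, b_j>."""
    a, b = _as_tensor(a), _as_tensor(b)
    data = np.einsum("nci,ncj->nij", a.data, b.data, optimize=True)

    def backward(g):
        if a.requires_grad or a._parents:
            a._accum(np.einsum("nij,ncj->nci", g, b.data, optimize=True))
        if b.requires_grad or b._parents:
            b._accum(np.einsum("nij,nci->ncj", g, a.data, optimize=True))

    return _node(data, (a, b), backward)


def softmax_last(x: Tensor) -> Tensor:
    """Softmax over the last axis with row-max subtraction for stability."""
    x = _as_tensor(x)
    shifted = x.data - np.max(x.data, axis=-1, keepdims=True)
    e = np.exp(shifted)
    s = e / np.sum(e, axis=-1, keepdims=True)

    def backward(g):
        dot = np.sum(g * s, axis=-1, keepdims=True)
        x._accum(s * (g - dot))

    return _node(s, (x,), backward)


def attend(w: Tensor, p: Tensor) -> Tensor:
    """Row-stochastic aggregation: out[n,c,i] = sum_j w[n,i,j] p[n,c,j]."""
    w, p = _as_tensor(w), _as_tensor(p)
    data = np.einsum("nij,ncj->nci", w.data, p.data, optimize=True)

    def backward(g):
        if w.requires_grad or w._parents:
            w._accum(np.einsum("nci,ncj->nij", g, p.data, optimize=True))
        if p.requires_grad or p._parents:
            p._accum(np.einsum("nci,nij->ncj", g, w.data, optimize=True))

    return _node(data, (w, p), backward)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    """Pixelwise channel concatenation of two (N, C, H, W) maps."""
    a, b = _as_tensor(a), _as_tensor(b)
    ca = a.data.shape[1]
    data = np.concatenate([a.data, b.data], axis=1)

    def backward(g):
        a._accum(g[:, :ca])
        b._accum(g[:, ca:])

    return _node(data, (a, b), backward)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean over the batch of the squared Euclidean distance to the target."""
    pred = _as_tensor(pred)
    target = np.asarray(target, dtype=np.float64)
    n = pred.data.shape[0]
    diff = pred.data - target
    data = np.array(np.sum(diff * diff) / n)

    def backward(g):
        pred._accum((2.0 / n) * diff * g)

    return _node(data, (pred,), backward)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with bias correction (moments 0.9 / 0.999, eps 1e-8)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
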