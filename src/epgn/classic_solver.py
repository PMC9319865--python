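"""Accelerated extra proximal-gradient algorithm with pluggable prox rules.

One iteration performs six sub-steps: a Nesterov-style momentum
extrapolation, a gradient step on the data fidelity, and a proximal step —
then repeats the three with the just-computed half iterate, giving a
predictor–corrector ("extra" gradient) structure:

    x~    = x_k + gamma_k (x_k - x_{k-1/2})
    b     = x~ - alpha_k grad f(x~; y)
    x_1/2 = prox_{alpha_k g}(b)
    x^    = x_1/2 + gamma_k (x_1/2 - x_k)
    b'    = x^ - beta_k grad f(x^; y)
    x_{k+1} = prox_{beta_k g}(b')

ISTA and FISTA solvers for the l1-synthesis (LASSO-type) problem are
included as high-precision testing oracles.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Sequence

import numpy as np

from .sensing import SensingOperator, fidelity_gradient

__all__ = [
    "SolverState",
    "StepSchedule",
    "ProxRule",
    "soft_shrink",
    "identity_prox",
    "l1_transform_prox",
    "extra_prox_step",
    "solve",
    "ista_reference",
    "fista_reference",
    "DivergenceError",
]


class DivergenceError(RuntimeError):
    """Raised when an iterate becomes non-finite or blows up."""


@dataclasses.dataclass
class SolverState:
    """Iterate bookkeeping: current x_k, previous half iterate x_{k-1/2}."""
    x_current: np.ndarray
    x_half_prev: np.ndarray
    k: int = 0


@dataclasses.dataclass
class StepSchedule:
    """Per-iteration step sizes alpha_k, beta_k > 0 and momentum gamma_k >= 0.

    Scalars mean constant schedules; sequences are indexed by the iterate.
    """
    alpha: float | Sequence[float]
    beta: float | Sequence[float]
    gamma: float | Sequence[float] = 0.0

    def at(self, k: int) -> tuple[float, float, float]:
        def pick(v):
            return float(v[k]) if np.ndim(v) > 0 else float(v)
        a, b, g = pick(self.alpha), pick(self.beta), pick(self.gamma)
        if a <= 0 or b <= 0:
            raise ValueError("step sizes must be strictly positive")
        return a, b, g


@dataclasses.dataclass
class ProxRule:
    """A regularizer g and its proximal map prox(b, scale) = argmin_x
    1/2 ||x - b||^2 + scale * g(x).  Must satisfy prox(b, 0) = b."""
    g_value: Callable[[np.ndarray], float]
    prox: Callable[[np.ndarray, float], np.ndarray]


def soft_shrink(z: np.ndarray, theta) -> np.ndarray:
    """Componentwise soft shrinkage max(|z| - theta, 0) * sign(z).

    The proximal operator of theta * ||.||_1; zero where |z_i| <= theta_i,
    with the 0/|0| convention resolved to 0.
    """
    z = np.asarray(z, dtype=float)
    return np.sign(z) * np.maximum(np.abs(z) - theta, 0.0)


identity_prox = ProxRule(g_value=lambda x: 0.0, prox=lambda b, s: b)


def l1_transform_prox(w: np.ndarray, lam: float) -> ProxRule:
    """Prox rule for g(x) = lam * ||W x||_1 with orthonormal W (W^T W = I).

    prox(b, s) = W^T soft_shrink(W b, s * lam); exact only for orthonormal
    W (a warning is emitted otherwise).  Arrays are flattened through W.
    """
    w = np.asarray(w, dtype=float)
    if not np.allclose(w.T @ w, np.eye(w.shape[1]), atol=1e-8):
        warnings.warn("transform is not orthonormal; prox will be inexact",
                      stacklevel=2)

    def g_value(x):
        return float(lam * np.abs(w @ np.ravel(x)).sum())

    def prox(b, scale):
        shape = np.shape(b)
        z = soft_shrink(w @ np.ravel(b), scale * lam)
        return (w.T @ z).reshape(shape)

    return ProxRule(g_value=g_value, prox=prox)


def _check_finite(x: np.ndarray, step: str, norm0: float) -> None:
    if not np.all(np.isfinite(x)):
        raise DivergenceError(f"non-finite iterate after sub-step {step}")
    if norm0 > 0 and np.linalg.norm(x) > 1e6 * norm0:
        raise DivergenceError(f"iterate norm blew up after sub-step {step}")


def extra_prox_step(state: SolverState, op: SensingOperator, y: np.ndarray,
                    sched: StepSchedule, prox: ProxRule) -> SolverState:
    """One full iteration (momentum / gradient / prox, twice)."""
    a, b_step, g = sched.at(state.k)
    norm0 = float(np.linalg.norm(state.x_current))
    xk, xhp = state.x_current, state.x_half_prev

    x_tilde = xk + g * (xk - xhp)                                # (6a)
    b_half = x_tilde - a * fidelity_gradient(op, x_tilde, y)     # (6b)
    _check_finite(b_half, "gradient-1", norm0)
    x_half = prox.prox(b_half, a)                                # (6c)
    _check_finite(x_half, "prox-1", norm0)
    x_hat = x_half + g * (x_half - xk)                           # (6d)
    b_next = x_hat - b_step * fidelity_gradient(op, x_hat, y)    # (6e)
    _check_finite(b_next, "gradient-2", norm0)
    x_next = prox.prox(b_next, b_step)                           # (6f)
    _check_finite(x_next, "prox-2", norm0)

    return SolverState(x_current=x_next, x_half_prev=x_half, k=state.k + 1)


def solve(op: SensingOperator, y: np.ndarray, sched: StepSchedule,
          prox: ProxRule, iters: int,
          x0: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Run ``iters`` accelerated extra proximal-gradient iterations.

    Starts from ``x0`` (default: the adjoint reconstruction A^H y, with
    x_{-1/2} = x_0).  Returns the final iterate and the objective trace
    f + g evaluated at each x_k.
    """
    if iters < 1:
        raise ValueError("iters must be >= 1")
    if x0 is None:
        x0 = np.real(op.adjoint(y))
    state = SolverState(x_current=np.asarray(x0, dtype=float),
                        x_half_prev=np.asarray(x0, dtype=float))

    def objective(x):
        r = op.forward(x) - y
        return float(0.5 * np.real(np.vdot(r, r)) + prox.g_value(x))

    trace = np.empty(iters)
    for i in range(iters):
        state = extra_prox_step(state, op, y, sched, prox)
        trace[i] = objective(state.x_current)
    return state.x_current, trace


# ---------------------------------------------------------------------------
# reference solvers (testing oracles)
# ---------------------------------------------------------------------------

def ista_reference(op: SensingOperator, y: np.ndarray, lam: float,
                   w: np.ndarray | None, iters: int, step: float = 1.0,
                   x0: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Plain proximal-gradient (ISTA) for f + lam ||W x||_1; oracle use."""
    prox = identity_prox if lam == 0 else l1_transform_prox(
        w if w is not None else np.eye(op.n), lam)
    if x0 is None:
        x0 = np.real(op.adjoint(y))
    x = np.asarray(x0, dtype=float)
    trace = np.empty(iters)
    for i in range(iters):
        x = prox.prox(x - step * fidelity_gradient(op, x, y), step)
        r = op.forward(x) - y
        trace[i] = 0.5 * np.real(np.vdot(r, r)) + prox.g_value(x)
    return x, trace


def fista_reference(op: SensingOperator, y: np.ndarray, lam: float,
                    w: np.ndarray | None, iters: int, step: float = 1.0,
                    x0: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """FISTA with the standard t-sequence momentum; high-precision oracle."""
    prox = identity_prox if lam == 0 else l1_transform_prox(
        w if w is not None else np.eye(op.n), lam)
    if x0 is None:
        x0 = np.real(op.adjoint(y))
    x = np.asarray(x0, dtype=float)
    z = x.copy()
    t = 1.0
    trace = np.empty(iters)
    for i in range(iters):
        x_new = prox.prox(z - step * fidelity_gradient(op, z, y), step)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        z = x_new + ((t - 1.0) / t_new) * (x_new - x)
        x, t = x_new, t_new
        r = op.forward(x) - y
        trace[i] = 0.5 * np.real(np.vdot(r, r)) + prox.g_value(x)
    return x, trace
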