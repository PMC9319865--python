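"""The unrolled K-phase extra proximal-gradient network (EPGN / NL-EPGN).

Each phase imitates one iteration of the accelerated extra proximal-gradient
algorithm: the momentum and gradient sub-steps are kept as exact linear
layers with learnable scalars (gamma_k, alpha_k, beta_k), while the two
proximal sub-steps are replaced by a learned residual update

    x = b + Gtil( S( G(b) ) )            (EPGN)
    x = b + Gtil( N( S( G(b) ) ) )       (NL-EPGN)

with encoder G = B o ReLU o A o D (three bias-free 3x3 convolutions,
receptive field 7x7), channel-wise soft shrinkage S with learned per-channel
thresholds, optional embedded-Gaussian nonlocal operator N, and decoder
Gtil = Dtil o Atil o ReLU o Btil mapping the Nf feature channels back to one
image channel.  The two stages inside a phase share one parameter set;
distinct phases do not share parameters.

Parameter budget at Nf = 32: 37,475 scalars per EPGN phase and 41,571 per
NL-EPGN phase (the nonlocal operator adds 4,096).
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .nonlocal_block import NonlocalParams, fuse_local_nonlocal
from .sensing import SensingOperator

__all__ = [
    "NetworkConfig",
    "PhaseParams",
    "Network",
    "encode",
    "channel_shrink",
    "decode",
    "residual_update",
    "phase_forward",
    "network_forward",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
    "PhaseDivergenceError",
]


class PhaseDivergenceError(RuntimeError):
    """Raised when a phase produces non-finite values."""


@dataclasses.dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    K: number of unrolled phases (9 for EPGN, 7 for NL-EPGN in the
    reference configuration); Nf: feature channels (32 by default, must be
    even so the nonlocal bottleneck can use Nf/2); nonlocal: include the
    embedded-Gaussian nonlocal operator in every phase.
    """
    K: int
    Nf: int = 32
    nonlocal_: bool = False

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.Nf % 2 != 0:
            raise ValueError("Nf must be even (nonlocal bottleneck uses Nf/2)")


@dataclasses.dataclass
class PhaseParams:
    """All learnable quantities of one phase.

    3x3 bias-free convolution kernels for the encoder (D: Nf<-1, A: Nf<-Nf,
    B: Nf<-Nf) and decoder (Btil: Nf<-Nf, Atil: Nf<-Nf, Dtil: 1<-Nf),
    per-channel shrinkage thresholds theta (length Nf), momentum gamma and
    step sizes alpha, beta (scalars).  ``nonlocal_params`` is present only
    in the NL variant.
    """
    D: Tensor
    A: Tensor
    B: Tensor
    Btil: Tensor
    Atil: Tensor
    Dtil: Tensor
    theta: Tensor
    gamma: Tensor
    alpha: Tensor
    beta: Tensor
    nonlocal_params: NonlocalParams | None = None

    def tensors(self) -> dict[str, Tensor]:
        out = {"D": self.D, "A": self.A, "B": self.B, "Btil": self.Btil,
               "Atil": self.Atil, "Dtil": self.Dtil, "theta": self.theta,
               "gamma": self.gamma, "alpha": self.alpha, "beta": self.beta}
        if self.nonlocal_params is not None:
            out.update(self.nonlocal_params.tensors())
        return out

    def n_parameters(self) -> int:
        return sum(t.data.size for t in self.tensors().values())


def zero_phase_params(config: NetworkConfig) -> PhaseParams:
    """A phase with all kernels/thresholds zero and gamma=alpha=beta=0.

    Such a phase is the identity map on its input — useful as a neutral
    starting point and in equivalence checks against the classical solver.
    """
    nf = config.Nf
    nl = None
    if config.nonlocal_:
        half = nf // 2
        nl = NonlocalParams(
            Walpha=Tensor(np.zeros((half, nf)), requires_grad=True),
            Wbeta=Tensor(np.zeros((half, nf)), requires_grad=True),
            Wphi=Tensor(np.zeros((half, nf)), requires_grad=True),
            Wexp=Tensor(np.zeros((nf, half)), requires_grad=True),
            Ck=Tensor(np.zeros((nf, 2 * nf)), requires_grad=True),
        )
    return PhaseParams(
        D=Tensor(np.zeros((nf, 1, 3, 3)), requires_grad=True),
        A=Tensor(np.zeros((nf, nf, 3, 3)), requires_grad=True),
        B=Tensor(np.zeros((nf, nf, 3, 3)), requires_grad=True),
        Btil=Tensor(np.zeros((nf, nf, 3, 3)), requires_grad=True),
        Atil=Tensor(np.zeros((nf, nf, 3, 3)), requires_grad=True),
        Dtil=Tensor(np.zeros((1, nf, 3, 3)), requires_grad=True),
        theta=Tensor(np.zeros(nf), requires_grad=True),
        gamma=Tensor(np.array(0.0), requires_grad=True),
        alpha=Tensor(np.array(0.0), requires_grad=True),
        beta=Tensor(np.array(0.0), requires_grad=True),
        nonlocal_params=nl,
    )


# ---------------------------------------------------------------------------
# phase computation
# ---------------------------------------------------------------------------

def _wrap4(x) -> Tensor:
    """Coerce an image / batch into a (N, 1, H, W) Tensor."""
    if isinstance(x, Tensor):
        return x
    x = np.asarray(x, dtype=float)
    if x.ndim == 2:
        x = x[None, None]
    elif x.ndim == 3:
        x = x[:, None]
    return Tensor(x)


def encode(params: PhaseParams, x) -> Tensor:
    """Feature extraction G(x) = B ReLU(A D x); Nf channels, 7x7 receptive field."""
    x = _wrap4(x)
    return ad.conv2d(ad.relu(ad.conv2d(ad.conv2d(x, params.D), params.A)), params.B)


def channel_shrink(z, theta) -> Tensor:
    """Soft shrinkage applied per feature channel with thresholds theta_j."""
    z = z if isinstance(z, Tensor) else Tensor(np.asarray(z, dtype=float))
    theta = theta if isinstance(theta, Tensor) else Tensor(np.asarray(theta, dtype=float))
    return ad.soft_shrink_op(z, theta)


def decode(params: PhaseParams, z) -> Tensor:
    """Residual resembling Gtil(z) = Dtil Atil ReLU(Btil z); back to one channel."""
    z = z if isinstance(z, Tensor) else Tensor(np.asarray(z, dtype=float))
    return ad.conv2d(ad.conv2d(ad.relu(ad.conv2d(z, params.Btil)), params.Atil), params.Dtil)


def residual_update(params: PhaseParams, b, nonlocal_op: bool | None = None) -> Tensor:
    """Learned proximal surrogate: b + Gtil(S(G(b))), optionally with the
    nonlocal operator inserted between S and Gtil."""
    b = _wrap4(b)
    z = channel_shrink(encode(params, b), params.theta)
    use_nl = params.nonlocal_params is not None if nonlocal_op is None else nonlocal_op
    if use_nl:
        z = fuse_local_nonlocal(params.nonlocal_params, z)
    return ad.add(b, decode(params, z))


def phase_forward(params: PhaseParams, x_k, x_half_prev,
                  op: SensingOperator, y: np.ndarray,
                  phase_index: int = 0) -> tuple[Tensor, Tensor]:
    """One unrolled phase: two momentum/gradient/residual stages sharing params.

    Returns (x_next, x_half); both stages use the same parameter set.
    """
    x_k, x_half_prev = _wrap4(x_k), _wrap4(x_half_prev)
    y = np.asarray(y)
    if y.ndim == 1:
        y = y[None]
    x_tilde = ad.lincomb(x_k, x_half_prev, params.gamma)
    b_half = ad.fidelity_step(x_tilde, params.alpha, op, y)
    x_half = residual_update(params, b_half)
    x_hat = ad.lincomb(x_half, x_k, params.gamma)
    b_next = ad.fidelity_step(x_hat, params.beta, op, y)
    x_next = residual_update(params, b_next)
    if not np.all(np.isfinite(x_next.data)):
        raise PhaseDivergenceError(f"non-finite values in phase {phase_index}")
    return x_next, x_half


def network_forward(config: NetworkConfig, phases: list[PhaseParams],
                    op: SensingOperator, y: np.ndarray,
                    x0: np.ndarray | None = None) -> Tensor:
    """Run the K-phase network; x0 defaults to the adjoint reconstruction A^H y.

    The initial half iterate equals x0.  Accepts a single measurement
    (m,) or a batch (N, m); returns the (N, 1, H, W) output Tensor.
    """
    if len(phases) != config.K:
        raise ValueError(f"expected {config.K} phases, got {len(phases)}")
    y = np.asarray(y)
    if y.ndim == 1:
        y = y[None]
    if x0 is None:
        x0 = op.batch_adjoint(y)
    x = _wrap4(x0)
    if x.data.shape[2:] != op.image_shape:
        raise ValueError(f"x0 shape {x.data.shape[2:]} != operator image "
                         f"shape {op.image_shape}")
    x_half_prev = x
    for k, params in enumerate(phases):
        x, x_half_prev = phase_forward(params, x, x_half_prev, op, y,
                                       phase_index=k)
    return x


# ---------------------------------------------------------------------------
# parameter audit
# ---------------------------------------------------------------------------

def count_parameters(config: NetworkConfig) -> tuple[int, int]:
    """Analytic count of learnable scalars: (per_phase, total).

    Per phase: encoder Nf*9*(1 + 2*Nf) + decoder Nf*9*(2*Nf + 1) kernel
    weights, one momentum scalar, two step sizes, Nf thresholds; the
    nonlocal operator adds 3 * (Nf/2 * Nf) + Nf * Nf/2 + Nf * 2*Nf.
    """
    nf = config.Nf
    enc = nf * 9 * (1 + 2 * nf)       # D (Nf*9) + A, B (Nf*Nf*9 each)
    dec = nf * 9 * (2 * nf + 1)       # Btil, Atil + Dtil
    per_phase = enc + dec + 1 + 2 + nf
    if config.nonlocal_:
        half = nf // 2
        per_phase += 3 * half * nf + nf * half + nf * 2 * nf
    return per_phase, per_phase * config.K


class Network:
    """Convenience bundle of a config and its per-phase parameter list."""

    def __init__(self, config: NetworkConfig, phases: list[PhaseParams]):
        if len(phases) != config.K:
            raise ValueError("phase count mismatch")
        self.config = config
        self.phases = phases

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for p in self.phases:
            out.extend(p.tensors().values())
        return out

    def n_parameters(self) -> int:
        return sum(p.n_parameters() for p in self.phases)

    def forward(self, op: SensingOperator, y: np.ndarray,
                x0: np.ndarray | None = None) -> Tensor:
        return network_forward(self.config, self.phases, op, y, x0)

    def reconstruct(self, op: SensingOperator, y: np.ndarray) -> np.ndarray:
        """Feed-forward reconstruction of a single measurement vector."""
        out = self.forward(op, y)
        return out.data[0, 0]


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, network: Network) -> None:
    """NPZ container with the config and every named tensor per phase."""
    cfg = network.config
    arrays = {"_config": np.frombuffer(json.dumps(
        {"K": cfg.K, "Nf": cfg.Nf, "nonlocal": cfg.nonlocal_}).encode(),
        dtype=np.uint8)}
    for k, phase in enumerate(network.phases):
        for name, t in phase.tensors().items():
            arrays[f"phase{k}/{name}"] = t.data
    np.savez(path, **arrays)


def load_checkpoint(path) -> Network:
    with np.load(path, allow_pickle=False) as f:
        cfg_json = json.loads(bytes(f["_config"]).decode())
        config = NetworkConfig(K=cfg_json["K"], Nf=cfg_json["Nf"],
                               nonlocal_=cfg_json["nonlocal"])
        phases = []
        for k in range(config.K):
            def t(name):
                return Tensor(f[f"phase{k}/{name}"], requires_grad=True)
            nl = None
            if config.nonlocal_:
                nl = NonlocalParams(Walpha=t("Walpha"), Wbeta=t("Wbeta"),
                                    Wphi=t("Wphi"), Wexp=t("Wexp"), Ck=t("Ck"))
            phases.append(PhaseParams(
                D=t("D"), A=t("A"), B=t("B"), Btil=t("Btil"), Atil=t("Atil"),
                Dtil=t("Dtil"), theta=t("theta"), gamma=t("gamma"),
                alpha=t("alpha"), beta=t("beta"), nonlocal_params=nl))
    return Network(config, phases)
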