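"""End-to-end training of the unrolled network.

The loss is the mean over training pairs of the squared Euclidean distance
between the network output and the ground-truth image,

    L(Theta) = (1/N) sum_i || x_K(y_i; Theta) - x_i ||_2^2 .

Convolution kernels are Glorot (Xavier) initialized; shrinkage thresholds
start at 0.01 per channel, momentum at 0 and both step sizes at 1, so the
untrained network is already a plain proximal-gradient scheme with a small
random residual.  Optimization uses Adam with learning rate 1e-4 for 200
epochs by default (tiny desk-scale runs use far less).
"""

from __future__ import annotations

import csv
import dataclasses
import pathlib

import numpy as np

from ._autodiff import Adam, Tensor, mse_loss
from .epgn_core import Network, NetworkConfig, PhaseParams
from .nonlocal_block import NonlocalParams
from .sensing import SensingOperator

__all__ = [
    "TrainConfig",
    "LossHistory",
    "loss",
    "init_parameters",
    "train",
]


@dataclasses.dataclass
class TrainConfig:
    """Optimization settings; defaults follow the reference configuration
    (Adam, learning rate 1e-4, 200 epochs) with desk-scale overrides."""
    learning_rate: float = 1e-4
    epochs: int = 200
    batch_size: int = 64
    seed: int = 0
    checkpoint_dir: str | None = None
    checkpoint_every: int = 0  # 0 = only final

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning rate must be nonnegative")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclasses.dataclass
class LossHistory:
    """Per-epoch mean training loss and optional validation PSNR."""
    train_loss: list[float]
    val_psnr: list[float] | None = None

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            header = ["epoch", "train_loss"]
            if self.val_psnr is not None:
                header.append("val_psnr")
            w.writerow(header)
            for i, tl in enumerate(self.train_loss):
                row = [i + 1, tl]
                if self.val_psnr is not None:
                    row.append(self.val_psnr[i])
                w.writerow(row)


def loss(network: Network, op: SensingOperator, x_true: np.ndarray,
         y: np.ndarray) -> float:
    """Mean squared-Euclidean training loss on a paired batch.

    ``x_true`` is (N, H, W); ``y`` is (N, m).
    """
    out = network.forward(op, y)
    n = x_true.shape[0]
    diff = out.data[:, 0] - x_true
    return float(np.sum(diff * diff) / n)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_parameters(config: NetworkConfig, seed: int) -> Network:
    """Glorot-initialized network; theta = 0.01, gamma = 0, alpha = beta = 1.

    Deterministic: equal seeds give bit-identical parameters.
    """
    rng = np.random.default_rng(seed)
    nf = config.Nf
    phases = []
    for _ in range(config.K):
        def conv(co, ci):
            return Tensor(_glorot(rng, (co, ci, 3, 3), ci * 9, co * 9),
                          requires_grad=True)

        nl = None
        if config.nonlocal_:
            half = nf // 2

            def proj(co, ci):
                return Tensor(_glorot(rng, (co, ci), ci, co), requires_grad=True)

            nl = NonlocalParams(Walpha=proj(half, nf), Wbeta=proj(half, nf),
                                Wphi=proj(half, nf), Wexp=proj(nf, half),
                                Ck=proj(nf, 2 * nf))
        phases.append(PhaseParams(
            D=conv(nf, 1), A=conv(nf, nf), B=conv(nf, nf),
            Btil=conv(nf, nf), Atil=conv(nf, nf), Dtil=conv(1, nf),
            theta=Tensor(np.full(nf, 0.01), requires_grad=True),
            gamma=Tensor(np.array(0.0), requires_grad=True),
            alpha=Tensor(np.array(1.0), requires_grad=True),
            beta=Tensor(np.array(1.0), requires_grad=True),
            nonlocal_params=nl))
    return Network(config, phases)


def train(network: Network, x_train: np.ndarray, op: SensingOperator,
          config: TrainConfig,
          x_val: np.ndarray | None = None) -> tuple[Network, LossHistory]:
    """Stochastic first-order training with measurements simulated on the fly.

    ``x_train`` is a stack (N, H, W) of ground-truth images; each batch is
    measured with the operator (y = A x) before the forward pass, so no
    measurement set needs to be stored.  Shuffling is deterministic given
    the config seed.  Aborts on a non-finite loss, returning the last good
    state.
    """
    from .epgn_core import save_checkpoint  # local import to avoid cycle
    from .evaluation import psnr

    if len(x_train) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    opt = Adam(network.parameters(), lr=config.learning_rate)
    n = len(x_train)
    bs = min(config.batch_size, n)
    history = LossHistory(train_loss=[],
                          val_psnr=[] if x_val is not None else None)
    ckdir = pathlib.Path(config.checkpoint_dir) if config.checkpoint_dir else None
    if ckdir is not None:
        ckdir.mkdir(parents=True, exist_ok=True)

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            xb = x_train[idx]
            yb = op.batch_forward(xb[:, None])
            opt.zero_grad()
            out = network.forward(op, yb)
            lval = mse_loss(out, xb[:, None])
            if not np.isfinite(lval.data):
                if ckdir is not None:
                    save_checkpoint(ckdir / "last_good.npz", network)
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch + 1}")
            lval.backward()
            opt.step()
            epoch_losses.append(float(lval.data))
        history.train_loss.append(float(np.mean(epoch_losses)))
        if x_val is not None:
            psnrs = []
            yv = op.batch_forward(x_val[:, None])
            out = network.forward(op, yv).data[:, 0]
            for xi, ri in zip(x_val, out):
                psnrs.append(psnr(ri, xi))
            history.val_psnr.append(float(np.mean(psnrs)))
        if ckdir is not None and config.checkpoint_every and \
                (epoch + 1) % config.checkpoint_every == 0:
            save_checkpoint(ckdir / f"epoch{epoch + 1:04d}.npz", network)
    if ckdir is not None:
        save_checkpoint(ckdir / "final.npz", network)
    return network, history
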