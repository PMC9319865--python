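"""Embedded-Gaussian nonlocal operator with bottleneck and fusion layer.

The nonlocal block computes, for every spatial position i of a feature map
z, a response that is a softmax-weighted average over all positions j:

    w_ij = exp(<W_a z_i, W_b z_j>) / sum_j exp(<W_a z_i, W_b z_j>)
    v_i  = sum_j w_ij (W_phi z)_j

W_a, W_b, W_phi are bias-free 1x1 convolutions into an Nf/2 bottleneck (to
reduce the cost of the (HW)^2 attention); an expansion 1x1 convolution maps
the aggregate back to Nf channels.  A fusion layer concatenates the local
input with the nonlocal response pixelwise and projects the 2*Nf channels
back to Nf through a learnable 1x1 convolution followed by ReLU.
"""

from __future__ import annotations

import dataclasses
import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor

__all__ = [
    "NonlocalParams",
    "nonlocal_weights",
    "nonlocal_block_forward",
    "fuse_local_nonlocal",
]


@dataclasses.dataclass
class NonlocalParams:
    """1x1 projection weights of one nonlocal operator (all bias-free).

    For Nf channels the bottleneck uses Nf/2; parameter shapes are
    Walpha, Wbeta, Wphi: (Nf/2, Nf); Wexp: (Nf, Nf/2); Ck: (Nf, 2*Nf) —
    4,096 scalars at Nf = 32.
    """
    Walpha: Tensor
    Wbeta: Tensor
    Wphi: Tensor
    Wexp: Tensor
    Ck: Tensor

    def tensors(self) -> dict[str, Tensor]:
        return {"Walpha": self.Walpha, "Wbeta": self.Wbeta,
                "Wphi": self.Wphi, "Wexp": self.Wexp, "Ck": self.Ck}

    def n_parameters(self) -> int:
        return sum(t.data.size for t in self.tensors().values())


def _wrap(z) -> Tensor:
    return z if isinstance(z, Tensor) else Tensor(np.asarray(z, dtype=float))


def nonlocal_weights(walpha, wbeta, z) -> np.ndarray:
    """Attention matrix (HW x HW) of embedded-Gaussian weights for one map.

    ``z`` is (Nf, H, W) or (1, Nf, H, W).  Row i holds the softmax over j of
    the embedded dot products; every row sums to one.  Computed with
    row-max subtraction for numerical stability.
    """
    walpha = np.asarray(walpha.data if isinstance(walpha, Tensor) else walpha)
    wbeta = np.asarray(wbeta.data if isinstance(wbeta, Tensor) else wbeta)
    z = np.asarray(z.data if isinstance(z, Tensor) else z, dtype=float)
    if z.ndim == 4:
        z = z[0]
    c, h, w = z.shape
    zf = z.reshape(c, h * w)
    a = walpha @ zf           # (C/2, HW)
    b = wbeta @ zf
    logits = a.T @ b          # (HW, HW): logits[i, j] = <a_i, b_j>
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def nonlocal_block_forward(params: NonlocalParams, z) -> Tensor:
    """Bottleneck attention aggregate, expanded back to Nf channels.

    v_i = sum_j w_ij (Wphi z)_j in the Nf/2 bottleneck, then a 1x1
    expansion to Nf channels; spatial shape is unchanged.
    """
    z = _wrap(z)
    n, c, h, w = z.data.shape
    zf = ad.flatten_hw(z)
    a = ad.flatten_hw(ad.conv1x1(z, params.Walpha))
    b = ad.flatten_hw(ad.conv1x1(z, params.Wbeta))
    p = ad.flatten_hw(ad.conv1x1(z, params.Wphi))
    weights = ad.softmax_last(ad.pairwise_logits(a, b))  # (N, HW, HW)
    v = ad.attend(weights, p)                            # (N, C/2, HW)
    v = ad.unflatten_hw(v, h, w)
    return ad.conv1x1(v, params.Wexp)


def fuse_local_nonlocal(params: NonlocalParams, z) -> Tensor:
    """Full nonlocal operator: ReLU(Ck [z, M(z)]) with pixelwise concatenation."""
    z = _wrap(z)
    v = nonlocal_block_forward(params, z)
    cat = ad.concat_channels(z, v)
    return ad.relu(ad.conv1x1(cat, params.Ck))
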