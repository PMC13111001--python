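"""Gamma-gated query/key/value attention over convolutional feature maps.

One block serves both attention flavours used in the network:

* hierarchical self-attention (HA1, HA2) — queries, keys and values all come
  from the same stage's feature map, refining within-stage spatial
  dependencies;
* multi-scale cross-attention (CA23, CA34) — queries come from the deeper
  stage, keys/values from a channel-matched and spatially resampled copy of
  the shallower stage, fusing fine detail into abstract features.

Given query source X and key/value source Y, both (B, C, H, W):

    Q = Wq * X,  K = Wk * Y,  V = Wv * Y          (1x1 convolutions, C -> C/8 for Q, K)
    E = Q'^T K'                                    (energies over the N = H*W positions)
    A = softmax(E / sqrt(d_k), last axis)          (d_k = C/8; row-stochastic)
    O = reshape(V' A^T)
    Out = gamma * O + X

``gamma`` is a learnable scalar initialized to exactly zero, so a freshly
constructed block is the identity map — attention is grown into the network
during training rather than imposed at initialization.

The energy matrix is (N x N) per batch item; a configurable position cap
raises a clear error instead of silently approximating when N exceeds it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import ConfigurationError, DimensionError, NumericError
from .nn import Conv2d, Module

#: Default upper bound on H*W before the quadratic energy matrix is refused.
#: 4096 admits the 56x56 first-stage map of the default 224-pixel configuration.
DEFAULT_POSITIONS_CAP = 4096


@dataclass
class AttentionTrace:
    """Intermediates of one attention application (numpy views, no grad)."""

    Q: np.ndarray  # (B, C/8, H, W)
    K: np.ndarray  # (B, C/8, H, W)
    V: np.ndarray  # (B, C, H, W)
    E: np.ndarray  # (B, N, N) raw energies (before 1/sqrt(d_k) scaling)
    A: np.ndarray  # (B, N, N) row-stochastic attention weights
    O: np.ndarray  # (B, C, H, W) weighted values


def attention_weights(E: np.ndarray, d_k: int) -> np.ndarray:
    """Row softmax of energies scaled by 1/sqrt(d_k) over the last axis."""
    E = np.asarray(E, dtype=np.float64)
    if not np.all(np.isfinite(E)):
        raise NumericError("energy matrix contains non-finite entries")
    if d_k < 1:
        raise ConfigurationError(f"d_k must be >= 1, got {d_k}")
    scaled = E / np.sqrt(d_k)
    shifted = scaled - scaled.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


class AttentionBlock(Module):
    """The shared attention block; ``C`` must be divisible by 8 (d_k = C/8)."""

    def __init__(self, channels: int, rng: np.random.Generator | None = None,
                 positions_cap: int = DEFAULT_POSITIONS_CAP):
        super().__init__()
        if channels % 8 != 0 or channels < 8:
            raise ConfigurationError(
                f"attention requires channels divisible by 8 (C/8 >= 1), got C={channels}"
            )
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.d_k = channels // 8
        self.positions_cap = positions_cap
        self.query = Conv2d(channels, self.d_k, 1, rng=rng)
        self.key = Conv2d(channels, self.d_k, 1, rng=rng)
        self.value = Conv2d(channels, channels, 1, rng=rng)
        self.gamma = Tensor(np.float32(0.0), requires_grad=True)

    def forward(self, x: Tensor, y: Tensor | None = None, return_trace: bool = False):
        y = x if y is None else y
        if x.data.shape != y.data.shape:
            raise DimensionError(
                f"query map shape {x.data.shape} != key/value map shape {y.data.shape}"
            )
        B, C, H, W = x.data.shape
        if C != self.channels:
            raise DimensionError(
                f"input has {C} channels, block configured for {self.channels}"
            )
        n = H * W
        if n > self.positions_cap:
            raise ConfigurationError(
                f"H*W = {n} exceeds the attention position cap {self.positions_cap}; "
                "the dense energy matrix would be too large — raise positions_cap "
                "explicitly to compute it anyway"
            )
        q = self.query(x)
        k = self.key(y)
        v = self.value(y)
        qf = ad.reshape(q, (B, self.d_k, n))
        kf = ad.reshape(k, (B, self.d_k, n))
        vf = ad.reshape(v, (B, C, n))
        energy = ad.matmul(ad.transpose(qf, (0, 2, 1)), kf)  # (B, N, N)
        scaled = ad.mul(energy, np.float32(1.0 / np.sqrt(self.d_k)))
        attn = ad.softmax_lastdim(scaled)
        weighted = ad.matmul(vf, ad.transpose(attn, (0, 2, 1)))  # (B, C, N)
        o = ad.reshape(weighted, (B, C, H, W))
        out = ad.add(ad.mul(self.gamma, o), x)
        if return_trace:
            trace = AttentionTrace(
                Q=q.data, K=k.data, V=v.data, E=energy.data, A=attn.data, O=o.data
            )
            return out, trace
        return out


def attend(x, y, block: AttentionBlock, return_trace: bool = False):
    """Functional wrapper: apply ``block`` to query map x and key/value map y."""
    tx = x if isinstance(x, Tensor) else Tensor(x)
    ty = y if isinstance(y, Tensor) else Tensor(y)
    return block(tx, ty, return_trace=return_trace)


class ChannelMatchResample(Module):
    """Adapter mapping a shallow stage onto a deeper stage's geometry:
    1x1 convolution to the target channel count, then bilinear resampling
    (corner alignment off; constants are preserved exactly)."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.match = Conv2d(in_channels, out_channels, 1, rng=rng)
        self.out_channels = out_channels

    def forward(self, x: Tensor, target_hw: tuple[int, int]) -> Tensor:
        th, tw = target_hw
        if th <= 0 or tw <= 0:
            raise ConfigurationError(f"target spatial size must be positive, got {target_hw}")
        return ad.bilinear_resize(self.match(x), (th, tw))


def channel_match_resample(
    f: np.ndarray,
    target_channels: int,
    target_hw: tuple[int, int],
    weights: np.ndarray,
    bias: np.ndarray | None = None,
) -> np.ndarray:
    """Functional form with explicit 1x1-convolution weights
    (``weights`` shape (target_channels, in_channels, 1, 1) or 2-D)."""
    f = np.asarray(f, dtype=np.float32)
    w = np.asarray(weights, dtype=np.float32)
    if w.ndim == 2:
        w = w[:, :, None, None]
    if w.shape[0] != target_channels or w.shape[1] != f.shape[1]:
        raise DimensionError(
            f"weights {w.shape} do not map {f.shape[1]} -> {target_channels} channels"
        )
    th, tw = target_hw
    if th <= 0 or tw <= 0:
        raise ConfigurationError(f"target spatial size must be positive, got {target_hw}")
    with ad.no_grad():
        out = ad.conv2d(Tensor(f), Tensor(w), None if bias is None else Tensor(bias))
    return ad.bilinear_resize_array(out.data, (th, tw))
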