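"""Channel and spatial attention blocks: GCT and CBAM.

Two attention families are implemented:

* **Gated Channel Transformation (GCT)** — three stages per channel ``c``:

  1. global context embedding, an L2-norm pooling scaled by a learnable
     embedding weight:  ``s_c = alpha_c * (sum_{i,j} x_c[i,j]^2 + eps)^(1/2)``
  2. cross-channel L2 normalization, which models competition between
     channels:  ``s_hat_c = sqrt(C) * s_c / (sum_c s_c^2 + eps)^(1/2)``
  3. a tanh gate with learnable gain and bias:
     ``x_hat_c = x_c * (1 + tanh(gamma_c * s_hat_c + beta_c))``

  With ``gamma = beta = 0`` the gate factor is exactly 1, so a freshly
  initialized GCT block is the identity — inserting it anywhere in a
  network leaves the forward pass bit-identical until training moves the
  gate parameters.

* **CBAM** — sequential channel attention (CAM: global max + average
  pooling through a shared two-layer MLP, sigmoid gate) followed by
  spatial attention (SAM: channel-wise max and mean maps, a k x k
  convolution, sigmoid gate).

All operations accept ``(C, H, W)`` or ``(N, C, H, W)`` inputs, run on the
package's autodiff tensors, and are therefore differentiable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Module, Parameter, Tensor, astensor

__all__ = [
    "GCTParams", "CAMParams", "SAMParams",
    "gct_embed", "gct_normalize", "gct_gate", "gct_forward",
    "cam_forward", "sam_forward", "cbam_forward",
    "GCT", "CAM", "SAM", "CBAM",
]

DEFAULT_EPSILON = 1e-5


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class GCTParams:
    """Per-channel GCT parameters: embedding weight, gate gain, gate bias."""

    alpha: np.ndarray | Tensor
    gamma: np.ndarray | Tensor
    beta: np.ndarray | Tensor
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self):
        na = _length(self.alpha)
        if not (na == _length(self.gamma) == _length(self.beta)):
            raise ValueError("alpha, gamma, beta must share channel count")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")

    @classmethod
    def identity(cls, channels: int, epsilon: float = DEFAULT_EPSILON) -> "GCTParams":
        """Identity initialization: alpha=1, gamma=beta=0."""
        return cls(np.ones(channels), np.zeros(channels), np.zeros(channels), epsilon)


@dataclass
class CAMParams:
    """Channel-attention parameters: shared 2-layer MLP (C -> C/r -> C)."""

    reduction_ratio: int
    w1: np.ndarray | Tensor  # (C, C/r)
    b1: np.ndarray | Tensor  # (C/r,)
    w2: np.ndarray | Tensor  # (C/r, C)
    b2: np.ndarray | Tensor  # (C,)

    @classmethod
    def zeros(cls, channels: int, reduction_ratio: int = 16) -> "CAMParams":
        if channels % reduction_ratio or channels // reduction_ratio < 1:
            raise ValueError(
                f"reduction ratio {reduction_ratio} must divide channels {channels}")
        hidden = channels // reduction_ratio
        return cls(reduction_ratio, np.zeros((channels, hidden)), np.zeros(hidden),
                   np.zeros((hidden, channels)), np.zeros(channels))


@dataclass
class SAMParams:
    """Spatial-attention parameters: one (1, 2, k, k) convolution."""

    kernel_size: int
    weight: np.ndarray | Tensor  # (1, 2, k, k)
    bias: np.ndarray | Tensor    # (1,)

    def __post_init__(self):
        if self.kernel_size % 2 == 0 or self.kernel_size < 1:
            raise ValueError("kernel_size must be odd and positive")

    @classmethod
    def zeros(cls, kernel_size: int = 7) -> "SAMParams":
        return cls(kernel_size, np.zeros((1, 2, kernel_size, kernel_size)),
                   np.zeros(1))


def _length(v) -> int:
    return astensor(v).shape[0]


def _batched(x) -> tuple[Tensor, bool]:
    x = astensor(x)
    if x.ndim == 3:
        return x.reshape((1,) + x.shape), True
    if x.ndim == 4:
        return x, False
    raise ValueError(f"expected (C,H,W) or (N,C,H,W) input, got shape {x.shape}")


def _debatch(t: Tensor, squeeze: bool) -> Tensor:
    return t.reshape(t.shape[1:]) if squeeze else t


# ---------------------------------------------------------------------------
# GCT
# ---------------------------------------------------------------------------

def gct_embed(x, p: GCTParams) -> Tensor:
    """Global context embedding: s_c = alpha_c * sqrt(sum x_c^2 + eps).

    Returns a per-channel vector, shape (C,) (or (N, C) for batched input).
    """
    xb, squeeze = _batched(x)
    alpha = astensor(p.alpha)
    if xb.shape[1] != alpha.shape[0]:
        raise ValueError(
            f"channel mismatch: input has {xb.shape[1]} channels, "
            f"params have {alpha.shape[0]}")
    sq = (xb * xb).sum(axis=(2, 3))
    s = alpha * (sq + p.epsilon).sqrt()
    return s.reshape(s.shape[1:]) if squeeze else s


def gct_normalize(s, epsilon: float = DEFAULT_EPSILON) -> Tensor:
    """Cross-channel L2 normalization: s_hat = sqrt(C) * s / ||s||_2.

    The sqrt(C) factor makes a constant embedding normalize to exactly 1.
    """
    st = astensor(s)
    flat = st.reshape((1,) + st.shape) if st.ndim == 1 else st
    c = flat.shape[1]
    if c == 0:
        raise ValueError("empty channel vector")
    norm = ((flat * flat).sum(axis=1, keepdims=True) + epsilon).sqrt()
    out = flat * (float(np.sqrt(c)) / norm)
    return out.reshape(out.shape[1:]) if st.ndim == 1 else out


def gct_gate(x, s_hat, p: GCTParams) -> Tensor:
    """Gating: x_hat_c = x_c * (1 + tanh(gamma_c * s_hat_c + beta_c))."""
    xb, squeeze = _batched(x)
    sh = astensor(s_hat)
    if sh.ndim == 1:
        sh = sh.reshape((1,) + sh.shape)
    if xb.shape[1] != sh.shape[1]:
        raise ValueError("channel mismatch between input and gate vector")
    gate = 1.0 + (astensor(p.gamma) * sh + astensor(p.beta)).tanh()
    out = xb * gate.reshape(gate.shape + (1, 1))
    return _debatch(out, squeeze)


def gct_forward(x, p: GCTParams) -> Tensor:
    """Full GCT: embed -> normalize -> gate."""
    xb, squeeze = _batched(x)
    s = gct_embed(xb, p)
    s_hat = gct_normalize(s, p.epsilon)
    return _debatch(gct_gate(xb, s_hat, p), squeeze)


class GCT(Module):
    """GCT layer.  Initializes to the identity (alpha=1, gamma=beta=0)."""

    def __init__(self, channels: int, epsilon: float = DEFAULT_EPSILON):
        super().__init__()
        self.channels = channels
        self.epsilon = epsilon
        self.alpha = Parameter(np.ones(channels))
        self.gamma = Parameter(np.zeros(channels))
        self.beta = Parameter(np.zeros(channels))

    def reset_parameters(self, rng: np.random.Generator) -> None:
        # identity init draws nothing from the rng by design: inserting a
        # GCT block must not perturb the init stream of surrounding layers
        self.alpha.data = np.ones(self.channels)
        self.gamma.data = np.zeros(self.channels)
        self.beta.data = np.zeros(self.channels)

    @property
    def params(self) -> GCTParams:
        return GCTParams(self.alpha, self.gamma, self.beta, self.epsilon)

    def forward(self, x: Tensor) -> Tensor:
        return gct_forward(x, self.params)


# ---------------------------------------------------------------------------
# CBAM
# ---------------------------------------------------------------------------

def cam_forward(x, p: CAMParams) -> tuple[Tensor, Tensor]:
    """Channel attention: sigmoid(MLP(maxpool) + MLP(avgpool)).

    Returns (gate M_c of shape (N, C) or (C,), reweighted features).
    """
    xb, squeeze = _batched(x)
    n, c = xb.shape[:2]
    if c % p.reduction_ratio:
        raise ValueError(f"reduction ratio {p.reduction_ratio} does not divide {c}")
    w1, b1 = astensor(p.w1), astensor(p.b1)
    w2, b2 = astensor(p.w2), astensor(p.b2)
    if w1.shape[0] != c:
        raise ValueError("MLP width does not match channel count")

    def mlp(v: Tensor) -> Tensor:
        return (v @ w1 + b1).relu() @ w2 + b2

    mx = xb.reshape(n, c, -1).max(axis=2)
    av = xb.reshape(n, c, -1).mean(axis=2)
    gate = (mlp(mx) + mlp(av)).sigmoid()
    out = xb * gate.reshape(n, c, 1, 1)
    return _debatch(gate, squeeze), _debatch(out, squeeze)


def sam_forward(x, p: SAMParams) -> tuple[Tensor, Tensor]:
    """Spatial attention: sigmoid(conv([max_c; mean_c])) applied pointwise.

    Returns (gate M_s of shape (N, H, W) or (H, W), reweighted features).
    """
    xb, squeeze = _batched(x)
    n, c, h, w = xb.shape
    mx = xb.max(axis=1, keepdims=True)
    av = xb.mean(axis=1, keepdims=True)
    stacked = nn.concat([mx, av], axis=1)
    logits = nn.conv2d(stacked, astensor(p.weight), astensor(p.bias),
                       stride=1, padding=p.kernel_size // 2)
    gate = logits.sigmoid()  # (N, 1, H, W)
    out = xb * gate
    gate_map = gate.reshape((h, w)) if squeeze else gate.reshape((n, h, w))
    return gate_map, _debatch(out, squeeze)


def cbam_forward(x, cam: CAMParams, sam: SAMParams) -> Tensor:
    """Sequential CBAM: channel attention first, spatial attention second."""
    _, refined = cam_forward(x, cam)
    _, out = sam_forward(refined, sam)
    return out


class CAM(Module):
    def __init__(self, channels: int, reduction_ratio: int = 16):
        super().__init__()
        if channels % reduction_ratio or channels // reduction_ratio < 1:
            raise ValueError(
                f"reduction ratio {reduction_ratio} must divide channels {channels}")
        self.channels = channels
        self.reduction_ratio = reduction_ratio
        hidden = channels // reduction_ratio
        self.w1 = Parameter(np.zeros((channels, hidden)))
        self.b1 = Parameter(np.zeros(hidden))
        self.w2 = Parameter(np.zeros((hidden, channels)))
        self.b2 = Parameter(np.zeros(channels))

    def reset_parameters(self, rng: np.random.Generator) -> None:
        # first layer random, output layer zero: the gate starts at the
        # constant sigmoid(0) = 0.5 so a fresh block adds no sample noise
        hidden = self.channels // self.reduction_ratio
        self.w1.data = rng.normal(0, np.sqrt(2.0 / self.channels),
                                  (self.channels, hidden))
        self.b1.data = np.zeros(hidden)
        self.w2.data = np.zeros((hidden, self.channels))
        self.b2.data = np.zeros(self.channels)

    @property
    def params(self) -> CAMParams:
        return CAMParams(self.reduction_ratio, self.w1, self.b1, self.w2, self.b2)

    def forward(self, x: Tensor) -> Tensor:
        return cam_forward(x, self.params)[1]


class SAM(Module):
    def __init__(self, kernel_size: int = 7):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        self.kernel_size = kernel_size
        self.weight = Parameter(np.zeros((1, 2, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(1))

    def reset_parameters(self, rng: np.random.Generator) -> None:
        # zero init: spatial gate starts flat at 0.5 (see CAM.reset_parameters)
        self.weight.data = np.zeros(self.weight.shape)
        self.bias.data = np.zeros(1)

    @property
    def params(self) -> SAMParams:
        return SAMParams(self.kernel_size, self.weight, self.bias)

    def forward(self, x: Tensor) -> Tensor:
        return sam_forward(x, self.params)[1]


class CBAM(Module):
    """Channel-then-spatial attention block."""

    def __init__(self, channels: int, reduction_ratio: int = 16,
                 spatial_kernel: int = 7):
        super().__init__()
        self.cam = CAM(channels, reduction_ratio)
        self.sam = SAM(spatial_kernel)

    def forward(self, x: Tensor) -> Tensor:
        return self.sam(self.cam(x))
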