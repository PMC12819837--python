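"""Spatial-edge adaptive feature enhancement convolution (SEAFEC).

The operator is a drop-in replacement for a k x k convolution, built
from two branches that are fused by a learnable sigmoid gate:

* **SCARF** (spatial-channel adaptive receptive-field attention):
  a per-position softmax over the k^2 receptive-field samples,

      A_rf = Softmax_k2( GroupConv_1x1^{C -> C k^2}( AvgPool_k(X) ) )

  modulates grouped multi-receptive-field features

      F_rf = ECA( relu( BN( GroupConv_kxk^{C -> C k^2}(X) ) ) ),

  and the weighted samples are rearranged into a (kH x kW) mosaic that a
  stride-k convolution collapses back to the input resolution.  ECA is
  channel recalibration through global pooling, a 1-D cross-channel
  convolution of adaptive odd width, and a sigmoid gate.

* **MEFE** (multi-scale edge feature enhancement): a pyramid of adaptive
  average poolings; each scale is channel-reduced, passed through a
  depthwise-separable convolution, upsampled, and sharpened by a
  learnable high-pass step

      E_i = F_i - AvgPool_3x3(F_i),        F_i^ = F_i + phi(E_i)

  with phi a bias-free residual refinement stack.  All scales are
  concatenated and fused by a 1x1 convolution.

* **Fusion**:  Y = alpha * F_SCARF + (1 - alpha) * F_MEFE, with
  alpha = sigmoid(alpha_logit) a learnable scalar in (0, 1).

The high-pass step and branch convolutions keep constant feature maps
constant (replicate padding, count-normalised pooling), so the edge
response of a flat region is exactly zero everywhere, borders included.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import yaml

from . import nn
from . import tensor as T
from .tensor import Tensor

__all__ = [
    "ConfigError",
    "ContractError",
    "SCARFSpec",
    "MEFESpec",
    "SEAFECSpec",
    "eca_kernel_size",
    "ECAGate",
    "edge_response",
    "DepthwiseSeparable",
    "SCARF",
    "MEFE",
    "SEAFEC",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 42

_ACTIVATIONS = {"relu": nn.ReLU, "sigmoid": nn.Sigmoid, "identity": nn.Identity}


class ConfigError(ValueError):
    """Invalid operator configuration."""


class ContractError(ValueError):
    """Input violates an operator's call contract."""


def _check_rank4(x: Tensor, who: str):
    if not isinstance(x, Tensor):
        raise ContractError(f"{who} expects a Tensor feature map, got {type(x).__name__}")
    if x.ndim != 4:
        raise ContractError(f"{who} expects a rank-4 (B, C, H, W) feature map, got rank {x.ndim}")


# ----------------------------------------------------------------------
# specs
# ----------------------------------------------------------------------

@dataclass
class SCARFSpec:
    """Configuration of the receptive-field attention branch."""

    in_channels: int
    out_channels: int
    kernel_size: int = 3
    stride: int = 1
    attention_groups: int | None = None  # None -> depthwise (groups = C)
    activation: str = "relu"
    eca_gamma: float = 2.0
    eca_b: float = 1.0

    def __post_init__(self):
        if self.kernel_size < 3 or self.kernel_size % 2 == 0:
            raise ConfigError(f"kernel_size must be odd and >= 3, got {self.kernel_size}")
        if self.stride < 1:
            raise ConfigError("stride must be >= 1")
        g = self.attention_groups if self.attention_groups is not None else self.in_channels
        if self.in_channels % g:
            raise ConfigError(
                f"attention_groups={g} does not divide in_channels={self.in_channels}"
            )
        if self.activation not in _ACTIVATIONS:
            raise ConfigError(f"unknown activation {self.activation!r}")


@dataclass
class MEFESpec:
    """Configuration of the multi-scale edge-enhancement branch.

    ``pool_sizes`` are target output sizes of the adaptive pooling
    pyramid; sizes larger than the incoming feature map are clamped at
    call time.
    """

    in_channels: int
    out_channels: int
    pool_sizes: tuple[int, ...] = (20, 18, 8)
    reduction_ratio: int = 4
    refinement_depth: int = 2
    stride: int = 1

    def __post_init__(self):
        self.pool_sizes = tuple(int(s) for s in self.pool_sizes)
        if len(self.pool_sizes) < 1 or any(s < 1 for s in self.pool_sizes):
            raise ConfigError(f"pool_sizes must be >= 1, got {self.pool_sizes}")
        if self.reduction_ratio < 1:
            raise ConfigError("reduction_ratio must be >= 1")
        if self.in_channels % self.reduction_ratio:
            raise ConfigError(
                f"reduction_ratio={self.reduction_ratio} does not divide "
                f"in_channels={self.in_channels}"
            )
        if self.stride < 1:
            raise ConfigError("stride must be >= 1")


@dataclass
class SEAFECSpec:
    """Full dual-branch operator configuration."""

    scarf: SCARFSpec
    mefe: MEFESpec
    alpha_init: float = 0.6

    def __post_init__(self):
        if isinstance(self.scarf, dict):
            self.scarf = SCARFSpec(**self.scarf)
        if isinstance(self.mefe, dict):
            self.mefe = MEFESpec(**self.mefe)
        if not (0.0 < self.alpha_init < 1.0):
            raise ConfigError(f"alpha_init must lie in (0, 1), got {self.alpha_init}")
        for attr in ("in_channels", "out_channels", "stride"):
            if getattr(self.scarf, attr) != getattr(self.mefe, attr):
                raise ConfigError(
                    f"branch mismatch on {attr}: scarf={getattr(self.scarf, attr)} "
                    f"mefe={getattr(self.mefe, attr)}"
                )

    @classmethod
    def create(
        cls,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        pool_sizes: tuple[int, ...] = (20, 18, 8),
        reduction_ratio: int = 4,
        alpha_init: float = 0.6,
        stride: int = 1,
        **kw,
    ) -> "SEAFECSpec":
        scarf_kw = {k: kw[k] for k in ("attention_groups", "activation", "eca_gamma", "eca_b") if k in kw}
        mefe_kw = {k: kw[k] for k in ("refinement_depth",) if k in kw}
        return cls(
            scarf=SCARFSpec(in_channels, out_channels, kernel_size, stride, **scarf_kw),
            mefe=MEFESpec(in_channels, out_channels, tuple(pool_sizes), reduction_ratio,
                          stride=stride, **mefe_kw),
            alpha_init=alpha_init,
        )

    # flat YAML round-trip with stable key names
    def to_yaml(self) -> str:
        d = {
            "in_channels": self.scarf.in_channels,
            "out_channels": self.scarf.out_channels,
            "kernel_size": self.scarf.kernel_size,
            "stride": self.scarf.stride,
            "pool_sizes": list(self.mefe.pool_sizes),
            "reduction_ratio": self.mefe.reduction_ratio,
            "alpha_init": self.alpha_init,
            "attention_groups": self.scarf.attention_groups,
            "activation": self.scarf.activation,
            "eca_gamma": self.scarf.eca_gamma,
            "eca_b": self.scarf.eca_b,
            "refinement_depth": self.mefe.refinement_depth,
        }
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SEAFECSpec":
        d = yaml.safe_load(text)
        return cls.create(**d)


# ----------------------------------------------------------------------
# ECA channel recalibration
# ----------------------------------------------------------------------

def eca_kernel_size(channels: int, gamma: float = 2.0, b: float = 1.0) -> int:
    """Adaptive 1-D kernel width: |log2(C)/gamma + b/gamma|, forced odd, >= 3."""
    if channels < 1:
        raise ConfigError("channels must be >= 1")
    t = int(abs(math.log2(channels) / gamma + b / gamma))
    k = t if t % 2 == 1 else t + 1
    return max(k, 3)


class ECAGate(nn.Module):
    """Efficient channel attention: global pooling, 1-D cross-channel
    convolution of adaptive odd width, sigmoid gate."""

    def __init__(self, channels: int, gamma: float = 2.0, b: float = 1.0,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(DEFAULT_SEED)
        self.channels = channels
        self.kernel_size = eca_kernel_size(channels, gamma, b)
        k = self.kernel_size
        bound = 1.0 / math.sqrt(k)
        self.weight = nn.Parameter(rng.uniform(-bound, bound, size=(1, 1, 1, k)))

    def forward(self, x: Tensor) -> Tensor:
        _check_rank4(x, "eca_gate")
        B, C, H, W = x.shape
        if C != self.channels:
            raise ContractError(f"eca_gate built for {self.channels} channels, got {C}")
        pooled = T.adaptive_avg_pool2d(x, 1)                       # (B, C, 1, 1)
        seq = T.reshape(pooled, (B, 1, 1, C))                      # channels as a 1-D signal
        conv = T.conv2d(seq, self.weight, padding=(0, self.kernel_size // 2))
        gate = T.sigmoid(T.reshape(conv, (B, C, 1, 1)))
        return T.mul(x, gate)


# ----------------------------------------------------------------------
# edge response (data-driven high-pass primitive)
# ----------------------------------------------------------------------

def edge_response(f: Tensor | np.ndarray) -> Tensor:
    """High-frequency response ``f - AvgPool_3x3(f)`` (stride 1).

    Border averages use only valid taps, so a constant map yields an
    exactly-zero response everywhere, including at the borders.
    """
    if not isinstance(f, Tensor):
        f = Tensor(f)
    _check_rank4(f, "edge_response")
    if not np.isfinite(f.data).all():
        raise ContractError("edge_response requires finite input")
    smooth = T.avg_pool2d(f, kernel=3, stride=1, padding=1, count_include_pad=False)
    return T.add(f, T.mul(smooth, -1.0))


# ----------------------------------------------------------------------
# branch modules
# ----------------------------------------------------------------------

class DepthwiseSeparable(nn.Module):
    """3x3 depthwise followed by 1x1 pointwise convolution.

    Replicate padding in the depthwise step keeps spatially constant
    maps constant, which the edge-enhancement invariants rely on.
    """

    def __init__(self, in_channels: int, out_channels: int, bias: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.depthwise = nn.Conv2d(in_channels, in_channels, 3, padding=1,
                                   groups=in_channels, bias=bias,
                                   padding_mode="replicate", rng=rng)
        self.pointwise = nn.Conv2d(in_channels, out_channels, 1, bias=bias, rng=rng)

    def forward(self, x):
        return self.pointwise(self.depthwise(x))


class SCARF(nn.Module):
    """Receptive-field attention convolution (drop-in k x k conv)."""

    def __init__(self, spec: SCARFSpec, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(DEFAULT_SEED)
        self.spec = spec
        C, k = spec.in_channels, spec.kernel_size
        groups = spec.attention_groups if spec.attention_groups is not None else C
        self.attn_conv = nn.Conv2d(C, C * k * k, 1, groups=groups, bias=True, rng=rng)
        self.attn_conv.bias.data[:] = 0.0  # equal logits at init -> uniform attention
        self.feat_conv = nn.Conv2d(C, C * k * k, k, stride=spec.stride, padding=k // 2,
                                   groups=C, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(C * k * k)
        self.act = _ACTIVATIONS[spec.activation]()
        self.eca = ECAGate(C * k * k, spec.eca_gamma, spec.eca_b, rng=rng)
        self.fuse = nn.Conv2d(C, spec.out_channels, k, stride=k, bias=True, rng=rng)

    # -- attention path ------------------------------------------------
    def attention(self, x: Tensor) -> Tensor:
        """Softmax-normalised (B, C, k^2, H', W') receptive-field attention."""
        _check_rank4(x, "scarf_attention")
        B, C, H, W = x.shape
        spec = self.spec
        if C != spec.in_channels:
            raise ContractError(f"expected {spec.in_channels} channels, got {C}")
        k = spec.kernel_size
        pooled = T.avg_pool2d(x, kernel=k, stride=spec.stride, padding=k // 2,
                              count_include_pad=False)
        logits = self.attn_conv(pooled)
        _, _, Ho, Wo = logits.shape
        logits = T.reshape(logits, (B, C, k * k, Ho, Wo))
        return T.softmax(logits, axis=2)

    def forward(self, x: Tensor) -> Tensor:
        _check_rank4(x, "scarf_forward")
        B, C, H, W = x.shape
        spec = self.spec
        k = spec.kernel_size
        attn = self.attention(x)
        feats = self.eca(self.act(self.bn(self.feat_conv(x))))
        _, _, Ho, Wo = feats.shape
        if attn.shape[3:] != (Ho, Wo):
            raise ContractError(
                f"attention grid {attn.shape[3:]} does not match feature grid {(Ho, Wo)}"
            )
        feats = T.reshape(feats, (B, C, k * k, Ho, Wo))
        weighted = T.mul(attn, feats)
        # row-major mosaic: sample u*k+v of cell (i, j) lands at (i*k+u, j*k+v)
        mosaic = T.reshape(weighted, (B, C, k, k, Ho, Wo))
        mosaic = T.transpose(mosaic, (0, 1, 4, 2, 5, 3))
        mosaic = T.reshape(mosaic, (B, C, k * Ho, k * Wo))
        return self.fuse(mosaic)


class MEFE(nn.Module):
    """Multi-scale learnable edge enhancement (drop-in conv)."""

    def __init__(self, spec: MEFESpec, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(DEFAULT_SEED)
        self.spec = spec
        C, r = spec.in_channels, spec.reduction_ratio
        mid = C // r
        self.reduces = nn.Sequential(
            *[nn.Conv2d(C, mid, 1, bias=False, rng=rng) for _ in spec.pool_sizes]
        )
        self.dsconvs = nn.Sequential(
            *[DepthwiseSeparable(mid, mid, bias=False, rng=rng) for _ in spec.pool_sizes]
        )
        self.refiners = nn.Sequential(*[
            self._make_refiner(mid, spec.refinement_depth, rng) for _ in spec.pool_sizes
        ])
        self.fuse = nn.Conv2d(mid * len(spec.pool_sizes), spec.out_channels, 1,
                              bias=True, rng=rng)

    @staticmethod
    def _make_refiner(channels: int, depth: int, rng) -> nn.Module:
        layers: list[nn.Module] = []
        for i in range(depth):
            if i:
                layers.append(nn.ReLU())
            layers.append(DepthwiseSeparable(channels, channels, bias=False, rng=rng))
        return nn.Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        _check_rank4(x, "mefe_forward")
        B, C, H, W = x.shape
        spec = self.spec
        if C != spec.in_channels:
            raise ContractError(f"expected {spec.in_channels} channels, got {C}")
        enhanced = []
        for s, reduce, ds, refine in zip(spec.pool_sizes, self.reduces, self.dsconvs, self.refiners):
            se = min(s, H, W)
            if se < s:
                warnings.warn(
                    f"pool size {s} exceeds feature map {H}x{W}; clamped to {se}",
                    stacklevel=2,
                )
            f = ds(reduce(T.adaptive_avg_pool2d(x, se)))
            f = T.upsample_bilinear(f, (H, W))
            e = edge_response(f)
            enhanced.append(T.add(f, refine(e)))
        y = self.fuse(T.concat(enhanced, axis=1))
        if spec.stride > 1:
            y = T.avg_pool2d(y, kernel=spec.stride, stride=spec.stride)
        return y


class SEAFEC(nn.Module):
    """Sigmoid-gated fusion of the SCARF and MEFE branches."""

    def __init__(self, spec: SEAFECSpec, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(DEFAULT_SEED)
        self.spec = spec
        self.scarf = SCARF(spec.scarf, rng=rng)
        self.mefe = MEFE(spec.mefe, rng=rng)
        a = spec.alpha_init
        self.alpha_logit = nn.Parameter(np.float32(math.log(a / (1.0 - a))))

    @property
    def alpha(self) -> float:
        """Current fusion weight sigmoid(alpha_logit), strictly in (0, 1)."""
        return float(1.0 / (1.0 + np.exp(-self.alpha_logit.data)))

    def forward(self, x: Tensor) -> Tensor:
        ys = self.scarf(x)
        ym = self.mefe(x)
        if ys.shape != ym.shape:
            raise ContractError(f"branch outputs disagree: {ys.shape} vs {ym.shape}")
        a = T.sigmoid(self.alpha_logit)
        return T.add(T.mul(ys, a), T.mul(ym, T.add(T.mul(a, -1.0), 1.0)))
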