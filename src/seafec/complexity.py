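"""Structural parameter and multiply-accumulate accounting.

Counting is purely structural: parameters are the learnable scalars of
the model (convolution/linear weights and biases, normalisation affine
pairs), and MACs are tallied during a single shape-propagating forward
pass over convolution and linear layers only — one MAC per
multiply-add; normalisation, pooling and activations are excluded.
Under this convention the canonical 1000-class ResNet-18 measures
11.69M parameters and 1.81G MACs at a 3x224x224 input.  "FLOPs" figures
quoted in G for such backbones conventionally refer to this MAC count.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from . import tensor as T
from .tensor import Tensor

__all__ = ["ComplexityReport", "count_parameters", "count_macs", "compare"]


@dataclass
class ComplexityReport:
    model: str
    params: int
    macs: int | None = None
    input_shape: tuple[int, ...] | None = None
    baseline: str | None = None
    delta_params_pct: float | None = None
    delta_macs_pct: float | None = None
    convention: str = "params = learnable scalars; macs = conv+linear multiply-accumulates"

    @property
    def params_m(self) -> float:
        return self.params / 1e6

    @property
    def macs_g(self) -> float | None:
        return None if self.macs is None else self.macs / 1e9

    def to_dict(self) -> dict:
        d = asdict(self)
        d["params_M"] = round(self.params_m, 2)
        if self.macs is not None:
            d["macs_G"] = round(self.macs_g, 2)
        return d


def count_parameters(model: nn.Module) -> int:
    """Exact number of learnable scalars in the model."""
    return int(sum(p.data.size for p in model.parameters()))


def count_macs(model: nn.Module, input_shape: tuple[int, int, int]) -> int:
    """Multiply-accumulate count for one input of shape (C, H, W).

    Computed by running a single inference-mode forward pass with the
    layer-level MAC tally armed; the count depends only on the
    architecture and input shape, never on weight values.
    """
    C, H, W = input_shape
    x = Tensor(np.zeros((1, C, H, W), dtype=np.float32))
    mode = model.training
    model.eval()
    import warnings

    try:
        with T.no_grad(), nn.tally_macs() as tally, warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model(x)
    finally:
        model.train(mode)
    return int(tally[0])


def compare(
    variants: dict[str, nn.Module],
    baseline: str,
    input_shape: tuple[int, int, int] | None = None,
) -> dict[str, ComplexityReport]:
    """Profile several models against a named baseline.

    Deltas are signed percentages 100 * (variant - baseline) / baseline.
    """
    if baseline not in variants:
        raise KeyError(f"baseline {baseline!r} not among variants {list(variants)}")
    reports: dict[str, ComplexityReport] = {}
    base_params = count_parameters(variants[baseline])
    base_macs = count_macs(variants[baseline], input_shape) if input_shape else None
    for name, model in variants.items():
        params = base_params if name == baseline else count_parameters(model)
        macs = None
        if input_shape is not None:
            macs = base_macs if name == baseline else count_macs(model, input_shape)
        rep = ComplexityReport(model=name, params=params, macs=macs,
                               input_shape=(1, *input_shape) if input_shape else None,
                               baseline=baseline)
        if name != baseline:
            rep.delta_params_pct = 100.0 * (params - base_params) / base_params
            if macs is not None and base_macs:
                rep.delta_macs_pct = 100.0 * (macs - base_macs) / base_macs
        reports[name] = rep
    return reports
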