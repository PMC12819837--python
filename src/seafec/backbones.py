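"""Backbone construction and convolution-replacement surgery.

Provides the two host networks the dual-branch operator is evaluated
in — a ResNet-18 classifier in which the first 3x3 convolution of every
BasicBlock can be swapped for SCARF / MEFE / SEAFEC, and a
DeepLabV3-ResNet-50 segmenter (atrous pyramid head, no auxiliary
classifier) whose final-stage bottleneck 3x3 convolutions can be
swapped — together with a generic ``replace_convs`` hook for arbitrary
models built on this package's layer system.

Replacements always preserve the replaced convolution's in/out channel
counts and stride, so the host's downsampling schedule is untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import nn
from . import tensor as T
from .modules import (
    MEFE,
    SCARF,
    SEAFEC,
    ConfigError,
    MEFESpec,
    SCARFSpec,
    SEAFECSpec,
    DEFAULT_SEED,
)
from .tensor import Tensor

__all__ = [
    "BasicBlock",
    "Bottleneck",
    "ResNet",
    "DeepLabV3",
    "SurgeryPlan",
    "SurgeryError",
    "build_resnet18",
    "build_seafec_resnet18",
    "build_seafec_deeplabv3",
    "build_model",
    "replace_convs",
    "select_basicblock_first_conv",
    "select_stage4_bottleneck_conv",
    "VARIANTS",
    "TASK_DEFAULTS",
]

VARIANTS = ("baseline", "scarf", "mefe", "seafec")

# per-task operator defaults: (pool_sizes, alpha_init)
TASK_DEFAULTS = {
    "classification": {"pool_sizes": (20, 18, 8), "alpha_init": 0.6},
    "detection": {"pool_sizes": (18, 14, 8), "alpha_init": 0.5},
    "segmentation": {"pool_sizes": (20, 15, 8), "alpha_init": 0.4},
}


class SurgeryError(RuntimeError):
    """A convolution replacement failed or was applied twice."""


# ----------------------------------------------------------------------
# residual blocks
# ----------------------------------------------------------------------

class BasicBlock(nn.Module):
    expansion = 1

    def __init__(self, in_planes: int, planes: int, stride: int = 1,
                 downsample: nn.Module | None = None, rng=None):
        super().__init__()
        self.conv1 = nn.Conv2d(in_planes, planes, 3, stride=stride, padding=1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(planes)
        self.relu = nn.ReLU()
        self.conv2 = nn.Conv2d(planes, planes, 3, padding=1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(planes)
        self.downsample = downsample if downsample is not None else nn.Identity()

    def forward(self, x):
        out = self.relu(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        return T.relu(T.add(out, self.downsample(x)))


class Bottleneck(nn.Module):
    expansion = 4

    def __init__(self, in_planes: int, planes: int, stride: int = 1,
                 downsample: nn.Module | None = None, dilation: int = 1, rng=None):
        super().__init__()
        self.conv1 = nn.Conv2d(in_planes, planes, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(planes)
        self.conv2 = nn.Conv2d(planes, planes, 3, stride=stride, padding=dilation,
                               dilation=dilation, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(planes)
        self.conv3 = nn.Conv2d(planes, planes * 4, 1, bias=False, rng=rng)
        self.bn3 = nn.BatchNorm2d(planes * 4)
        self.relu = nn.ReLU()
        self.downsample = downsample if downsample is not None else nn.Identity()

    def forward(self, x):
        out = self.relu(self.bn1(self.conv1(x)))
        out = self.relu(self.bn2(self.conv2(out)))
        out = self.bn3(self.conv3(out))
        return T.relu(T.add(out, self.downsample(x)))


class ResNet(nn.Module):
    """ResNet-18/50 trunk with optional stride->dilation conversion."""

    def __init__(self, block, layers: list[int], num_classes: int = 1000,
                 replace_stride_with_dilation=(False, False, False),
                 include_head: bool = True, rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(DEFAULT_SEED)
        self.in_planes = 64
        self.dilation = 1
        self.conv1 = nn.Conv2d(3, 64, 7, stride=2, padding=3, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(64)
        self.relu = nn.ReLU()
        self.maxpool = nn.MaxPool2d(3, 2, 1)
        self.layer1 = self._make_layer(block, 64, layers[0], 1, False, rng)
        self.layer2 = self._make_layer(block, 128, layers[1], 2, replace_stride_with_dilation[0], rng)
        self.layer3 = self._make_layer(block, 256, layers[2], 2, replace_stride_with_dilation[1], rng)
        self.layer4 = self._make_layer(block, 512, layers[3], 2, replace_stride_with_dilation[2], rng)
        self.include_head = include_head
        if include_head:
            self.avgpool = nn.AdaptiveAvgPool2d(1)
            self.fc = nn.Linear(512 * block.expansion, num_classes, rng=rng)

    def _make_layer(self, block, planes, blocks, stride, dilate, rng):
        downsample = None
        prev_dilation = self.dilation
        if dilate:
            self.dilation *= stride
            stride = 1
        if stride != 1 or self.in_planes != planes * block.expansion:
            downsample = nn.Sequential(
                nn.Conv2d(self.in_planes, planes * block.expansion, 1, stride=stride,
                          bias=False, rng=rng),
                nn.BatchNorm2d(planes * block.expansion),
            )
        kw = {"dilation": prev_dilation} if block is Bottleneck else {}
        mods = [block(self.in_planes, planes, stride, downsample, rng=rng, **kw)]
        self.in_planes = planes * block.expansion
        for _ in range(1, blocks):
            kw = {"dilation": self.dilation} if block is Bottleneck else {}
            mods.append(block(self.in_planes, planes, rng=rng, **kw))
        return nn.Sequential(*mods)

    def features(self, x: Tensor) -> Tensor:
        x = self.maxpool(self.relu(self.bn1(self.conv1(x))))
        return self.layer4(self.layer3(self.layer2(self.layer1(x))))

    def forward(self, x: Tensor) -> Tensor:
        x = self.features(x)
        if not self.include_head:
            return x
        x = self.avgpool(x)
        B = x.shape[0]
        return self.fc(T.reshape(x, (B, -1)))


# ----------------------------------------------------------------------
# DeepLabV3
# ----------------------------------------------------------------------

class _ConvBNReLU(nn.Module):
    def __init__(self, cin, cout, k, dilation=1, rng=None):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, k, padding=(k // 2) * dilation,
                              dilation=dilation, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(cout)
        self.relu = nn.ReLU()

    def forward(self, x):
        return self.relu(self.bn(self.conv(x)))


class _ASPPPooling(nn.Module):
    def __init__(self, cin, cout, rng=None):
        super().__init__()
        self.pool = nn.AdaptiveAvgPool2d(1)
        self.conv = _ConvBNReLU(cin, cout, 1, rng=rng)

    def forward(self, x):
        size = x.shape[2:]
        y = self.conv(self.pool(x))
        return T.upsample_bilinear(y, size)


class ASPP(nn.Module):
    """Atrous spatial pyramid pooling head (rates 12/24/36 + image pool)."""

    def __init__(self, in_channels: int = 2048, out_channels: int = 256,
                 rates=(12, 24, 36), rng=None):
        super().__init__()
        self.b0 = _ConvBNReLU(in_channels, out_channels, 1, rng=rng)
        self.b1 = _ConvBNReLU(in_channels, out_channels, 3, dilation=rates[0], rng=rng)
        self.b2 = _ConvBNReLU(in_channels, out_channels, 3, dilation=rates[1], rng=rng)
        self.b3 = _ConvBNReLU(in_channels, out_channels, 3, dilation=rates[2], rng=rng)
        self.pool = _ASPPPooling(in_channels, out_channels, rng=rng)
        self.project = _ConvBNReLU(out_channels * 5, out_channels, 1, rng=rng)

    def forward(self, x):
        ys = [self.b0(x), self.b1(x), self.b2(x), self.b3(x), self.pool(x)]
        return self.project(T.concat(ys, axis=1))


class DeepLabV3(nn.Module):
    """Dense prediction at input resolution; ResNet-50 output stride 8."""

    def __init__(self, num_classes: int = 3, rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(DEFAULT_SEED)
        self.backbone = ResNet(Bottleneck, [3, 4, 6, 3],
                               replace_stride_with_dilation=(False, True, True),
                               include_head=False, rng=rng)
        self.aspp = ASPP(2048, 256, rng=rng)
        self.head = _ConvBNReLU(256, 256, 3, rng=rng)
        self.classifier = nn.Conv2d(256, num_classes, 1, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        size = x.shape[2:]
        y = self.classifier(self.head(self.aspp(self.backbone.features(x))))
        return T.upsample_bilinear(y, size)


# ----------------------------------------------------------------------
# surgery
# ----------------------------------------------------------------------

@dataclass
class SurgeryPlan:
    target_model: str = "resnet18"  # resnet18 | deeplabv3_resnet50
    variant: str = "seafec"         # baseline | scarf | mefe | seafec
    num_classes: int | None = None
    module_spec: SEAFECSpec | None = None
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if self.target_model not in ("resnet18", "deeplabv3_resnet50"):
            raise ConfigError(f"unknown target model {self.target_model!r}")
        if self.variant not in VARIANTS:
            raise ConfigError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.num_classes is None:
            self.num_classes = 1000 if self.target_model == "resnet18" else 3


def select_basicblock_first_conv(path: str, module: nn.Module) -> bool:
    """First 3x3 convolution of every residual BasicBlock."""
    parts = path.split(".")
    return parts[-1] == "conv1" and any(p.startswith("layer") for p in parts)


def select_stage4_bottleneck_conv(path: str, module: nn.Module) -> bool:
    """3x3 convolution of every final-stage bottleneck block."""
    return "layer4" in path and path.endswith(".conv2")


def _module_factory(variant: str, task: str, spec: SEAFECSpec | None,
                    rng: np.random.Generator) -> Callable[[int, int, int], nn.Module]:
    defaults = TASK_DEFAULTS[task]

    def make(cin: int, cout: int, stride: int) -> nn.Module:
        if spec is not None and spec.scarf.in_channels == cin and \
                spec.scarf.out_channels == cout and spec.scarf.stride == stride:
            full = spec
        else:
            full = SEAFECSpec.create(
                cin, cout, stride=stride,
                pool_sizes=defaults["pool_sizes"], alpha_init=defaults["alpha_init"],
            )
        if variant == "scarf":
            return SCARF(full.scarf, rng=rng)
        if variant == "mefe":
            return MEFE(full.mefe, rng=rng)
        if variant == "seafec":
            return SEAFEC(full, rng=rng)
        raise ConfigError(f"no module factory for variant {variant!r}")

    return make


def replace_convs(
    model: nn.Module,
    selector: Callable[[str, nn.Module], bool],
    factory: Callable[[int, int, int], nn.Module],
    verify: bool = True,
) -> tuple[nn.Module, int]:
    """Replace every selected ``Conv2d`` with ``factory(C_in, C_out, stride)``.

    Returns the surgered model and the replacement count.  Matching a
    layer that is no longer a plain convolution (e.g. because the same
    surgery already ran) raises :class:`SurgeryError`, as does a factory
    module that breaks the output-shape contract of the layer it
    replaces.
    """
    matches = [(path, mod) for path, mod in model.named_modules() if path and selector(path, mod)]
    count = 0
    for path, mod in matches:
        if not isinstance(mod, nn.Conv2d):
            raise SurgeryError(
                f"selected layer {path!r} is a {type(mod).__name__}, not a convolution "
                "(surgery already applied?)"
            )
        new = factory(mod.in_channels, mod.out_channels, mod.stride)
        if verify:
            _verify_contract(path, mod, new)
        model.set_submodule(path, new)
        count += 1
    return model, count


def _verify_contract(path: str, old: nn.Conv2d, new: nn.Module):
    h = max(2 * old.stride, 4)
    probe = Tensor(np.zeros((1, old.in_channels, h, h), dtype=np.float32))
    import warnings as _w

    with T.no_grad(), _w.catch_warnings():
        _w.simplefilter("ignore")
        mode = new.training
        try:
            got = new.eval()(probe).shape
        except Exception as exc:  # noqa: BLE001
            raise SurgeryError(f"replacement for {path!r} failed a probe forward: {exc}") from exc
        finally:
            new.train(mode)
        want = old(probe).shape
    if got != want:
        raise SurgeryError(f"replacement for {path!r} returns {got}, expected {want}")


def build_resnet18(num_classes: int = 1000, seed: int = DEFAULT_SEED) -> ResNet:
    return ResNet(BasicBlock, [2, 2, 2, 2], num_classes=num_classes,
                  rng=np.random.default_rng(seed))


def build_seafec_resnet18(plan: SurgeryPlan) -> ResNet:
    """ResNet-18 with the first 3x3 conv of each of the 8 BasicBlocks replaced."""
    if plan.target_model != "resnet18":
        raise ConfigError(f"plan targets {plan.target_model!r}, not resnet18")
    rng = np.random.default_rng(plan.seed)
    model = ResNet(BasicBlock, [2, 2, 2, 2], num_classes=plan.num_classes, rng=rng)
    if plan.variant == "baseline":
        return model
    factory = _module_factory(plan.variant, "classification", plan.module_spec, rng)
    model, count = replace_convs(model, select_basicblock_first_conv, factory)
    if count != 8:
        raise SurgeryError(f"expected 8 BasicBlock replacements, made {count}")
    return model


def build_seafec_deeplabv3(plan: SurgeryPlan) -> DeepLabV3:
    """DeepLabV3-ResNet-50 (no aux head) with final-stage bottleneck 3x3
    convolutions replaced for non-baseline variants."""
    if plan.target_model != "deeplabv3_resnet50":
        raise ConfigError(f"plan targets {plan.target_model!r}, not deeplabv3_resnet50")
    rng = np.random.default_rng(plan.seed)
    model = DeepLabV3(num_classes=plan.num_classes, rng=rng)
    if plan.variant == "baseline":
        return model
    factory = _module_factory(plan.variant, "segmentation", plan.module_spec, rng)
    model, count = replace_convs(model, select_stage4_bottleneck_conv, factory)
    if count != 3:
        raise SurgeryError(f"expected 3 bottleneck replacements, made {count}")
    return model


def build_model(plan: SurgeryPlan) -> nn.Module:
    if plan.target_model == "resnet18":
        return build_seafec_resnet18(plan)
    return build_seafec_deeplabv3(plan)
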