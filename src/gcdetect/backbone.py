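"""Residual bottleneck backbone with GCT placement, CBAM hooks, and FPN.

The feature extractor is a ResNet-style stack of bottleneck blocks
(1x1 -> 3x3 -> 1x1 convolutions with a shortcut) in four stages at
strides 4/8/16/32.  Its attention hooks:

* ``gct_placement`` — "none", "layer23" (a GCT block before the last two
  convolutions of every bottleneck) or "layer123" (before all three).
  GCT blocks initialize to the identity, so a freshly built attention
  variant produces bit-identical features to the plain baseline.
* ``cbam_locations`` — stage outputs (C2..C5) that receive a CBAM block
  before entering the FPN lateral connections.

Two presets are provided: ``resnet50`` (3/4/6/3 blocks, widths
256/512/1024/2048) and ``tiny`` (one block per stage, widths
16/32/64/128) which preserves the stage/stride structure at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import nn
from .attention import CBAM, GCT
from .nn import Module, Tensor

__all__ = [
    "BackboneConfig", "Bottleneck", "Backbone", "FPN", "BackboneWithFPN",
    "build_bottleneck", "insert_cbam",
]

GCT_PLACEMENTS = ("none", "layer23", "layer123")
STAGE_NAMES = ("C2", "C3", "C4", "C5")

_PRESETS = {
    # blocks per stage, stage output widths, stem width, fpn width, cbam reduction
    "resnet50": dict(blocks=(3, 4, 6, 3), widths=(256, 512, 1024, 2048),
                     stem=64, fpn=256, reduction=16),
    "tiny": dict(blocks=(1, 1, 1, 1), widths=(16, 32, 64, 128),
                 stem=16, fpn=64, reduction=8),
}


@dataclass
class BackboneConfig:
    preset: str = "resnet50"
    gct_placement: str = "none"
    cbam_locations: tuple[str, ...] = ()
    fpn_channels: int | None = None       # default: preset value
    cbam_reduction: int | None = None
    sam_kernel: int = 7

    def __post_init__(self):
        if self.preset not in _PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.gct_placement not in GCT_PLACEMENTS:
            raise ValueError(
                f"unknown gct_placement {self.gct_placement!r}; one of {GCT_PLACEMENTS}")
        bad = set(self.cbam_locations) - set(STAGE_NAMES)
        if bad:
            raise ValueError(f"unknown cbam locations {sorted(bad)}")
        self.cbam_locations = tuple(self.cbam_locations)
        spec = _PRESETS[self.preset]
        if self.fpn_channels is None:
            self.fpn_channels = spec["fpn"]
        if self.cbam_reduction is None:
            self.cbam_reduction = spec["reduction"]

    @property
    def stage_widths(self) -> tuple[int, ...]:
        return _PRESETS[self.preset]["widths"]


class Bottleneck(Module):
    """1x1 -> 3x3 -> 1x1 residual block with optional GCT insertions."""

    def __init__(self, in_ch: int, mid_ch: int, out_ch: int, stride: int = 1,
                 gct_placement: str = "none"):
        super().__init__()
        if gct_placement not in GCT_PLACEMENTS:
            raise ValueError(f"unknown gct_placement {gct_placement!r}")
        self.gct_placement = gct_placement
        if gct_placement == "layer123":
            self.gct1 = GCT(in_ch)
        if gct_placement in ("layer23", "layer123"):
            self.gct2 = GCT(mid_ch)
            self.gct3 = GCT(mid_ch)
        self.conv1 = nn.Conv2d(in_ch, mid_ch, 1, bias=False)
        self.bn1 = nn.BatchNorm2d(mid_ch)
        self.conv2 = nn.Conv2d(mid_ch, mid_ch, 3, stride=stride, padding=1, bias=False)
        self.bn2 = nn.BatchNorm2d(mid_ch)
        self.conv3 = nn.Conv2d(mid_ch, out_ch, 1, bias=False)
        self.bn3 = nn.BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.down_conv = nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False)
            self.down_bn = nn.BatchNorm2d(out_ch)
        else:
            self.down_conv = None

    def gct_modules(self) -> list[GCT]:
        return [m for m in (getattr(self, n, None) for n in ("gct1", "gct2", "gct3"))
                if m is not None]

    def forward(self, x: Tensor) -> Tensor:
        identity = x
        h = x
        if self.gct_placement == "layer123":
            h = self.gct1(h)
        h = self.bn1(self.conv1(h)).relu()
        if self.gct_placement != "none":
            h = self.gct2(h)
        h = self.bn2(self.conv2(h)).relu()
        if self.gct_placement != "none":
            h = self.gct3(h)
        h = self.bn3(self.conv3(h))
        if self.down_conv is not None:
            identity = self.down_bn(self.down_conv(x))
        return (h + identity).relu()


def build_bottleneck(in_ch: int, mid_ch: int, out_ch: int, stride: int = 1,
                     gct_placement: str = "none") -> Bottleneck:
    """Construct one residual bottleneck with the requested GCT placement."""
    return Bottleneck(in_ch, mid_ch, out_ch, stride, gct_placement)


class Backbone(Module):
    """Stem plus four bottleneck stages producing C2..C5 feature maps."""

    def __init__(self, config: BackboneConfig):
        super().__init__()
        self.config = config
        spec = _PRESETS[config.preset]
        stem = spec["stem"]
        self.stem_conv = nn.Conv2d(3, stem, 7, stride=2, padding=3, bias=False)
        self.stem_bn = nn.BatchNorm2d(stem)
        self.stem_pool = nn.MaxPool2d(3, 2, 1)
        self.stages = nn.ModuleList()
        in_ch = stem
        for si, (n_blocks, out_ch) in enumerate(zip(spec["blocks"], spec["widths"])):
            mid = max(out_ch // 4, 4)
            blocks = []
            for bi in range(n_blocks):
                stride = 2 if (bi == 0 and si > 0) else 1
                blocks.append(Bottleneck(in_ch, mid, out_ch, stride,
                                         config.gct_placement))
                in_ch = out_ch
            self.stages.append(nn.Sequential(*blocks))

    def forward(self, x: Tensor) -> dict[str, Tensor]:
        if x.shape[-1] < 32 or x.shape[-2] < 32:
            raise ValueError(f"input spatial size {x.shape[-2:]}; minimum is 32x32")
        h = self.stem_pool(self.stem_bn(self.stem_conv(x)).relu())
        feats: dict[str, Tensor] = {}
        for name, stage in zip(STAGE_NAMES, self.stages):
            h = stage(h)
            feats[name] = h
        return feats


def insert_cbam(features: dict[str, Tensor],
                cbam_modules: dict[str, CBAM]) -> dict[str, Tensor]:
    """Apply CBAM at named stage outputs; other maps pass through unchanged."""
    return {name: (cbam_modules[name](feat) if name in cbam_modules else feat)
            for name, feat in features.items()}


class FPN(Module):
    """Top-down feature pyramid: lateral 1x1, nearest upsample + add, 3x3 smooth.

    P6 is a stride-2 subsampling of P5, giving five levels at strides
    4, 8, 16, 32, 64 with a shared channel width.
    """

    def __init__(self, in_channels: tuple[int, ...], out_channels: int):
        super().__init__()
        self.out_channels = out_channels
        self.laterals = nn.ModuleList(
            [nn.Conv2d(c, out_channels, 1) for c in in_channels])
        self.outputs = nn.ModuleList(
            [nn.Conv2d(out_channels, out_channels, 3, padding=1)
             for _ in in_channels])

    def forward(self, feats: dict[str, Tensor]) -> dict[str, Tensor]:
        names = [n for n in STAGE_NAMES if n in feats]
        if len(names) != len(self.laterals):
            raise ValueError("stage/lateral count mismatch")
        laterals = [lat(feats[n]) for lat, n in zip(self.laterals, names)]
        for i in range(len(laterals) - 2, -1, -1):
            up = nn.upsample_nearest(laterals[i + 1],
                                     laterals[i].shape[2], laterals[i].shape[3])
            laterals[i] = laterals[i] + up
        pyramid = {f"P{i + 2}": out(lat)
                   for i, (out, lat) in enumerate(zip(self.outputs, laterals))}
        pyramid["P6"] = nn.max_pool2d(pyramid["P5"], 1, 2)
        return pyramid


class BackboneWithFPN(Module):
    """Backbone -> (CBAM at configured stages) -> FPN."""

    def __init__(self, config: BackboneConfig):
        super().__init__()
        self.config = config
        self.body = Backbone(config)
        self.cbam = nn.ModuleList()
        self._cbam_names = tuple(n for n in STAGE_NAMES if n in config.cbam_locations)
        widths = dict(zip(STAGE_NAMES, config.stage_widths))
        for name in self._cbam_names:
            self.cbam.append(CBAM(widths[name], config.cbam_reduction,
                                  config.sam_kernel))
        self.fpn = FPN(config.stage_widths, config.fpn_channels)
        # capture buffer for activation-map visualization
        self.captured: dict[str, Tensor] = {}
        self.capture_layers: tuple[str, ...] = ()

    def cbam_modules(self) -> dict[str, CBAM]:
        return dict(zip(self._cbam_names, self.cbam))

    def forward(self, x: Tensor) -> dict[str, Tensor]:
        feats = self.body(x)
        feats = insert_cbam(feats, self.cbam_modules())
        if self.capture_layers:
            self.captured = {n: feats[n] for n in self.capture_layers if n in feats}
        return self.fpn(feats)
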