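"""Buildable layer graphs for SD-UNet, the baseline U-Net, and the
ablation variants.

The topology is the widely used 4-pool U-Net: five encoder levels with two
3x3 convolutions each (channels doubling ``base_filters`` .. ``16 x
base_filters``), dropout at the two deepest levels, and a decoder of x2
nearest-neighbour upsampling + 2x2 convolution + skip concatenation + two
3x3 convolutions per level, finishing with a 3x3 convolution to a thin
prediction stem and a 1x1 output convolution.  SD-UNet keeps the very
first convolution standard and makes every other convolution depthwise
separable; one group-normalization layer sits at the end of each
convolution block and every depthwise 3x3 kernel is weight-standardized.

At 256 x 256 x 1 input and ``base_filters=64`` this graph counts 3.9M
trainable parameters for SD-UNet and 31M for the all-standard baseline
(7.8M vs. 62.0M FLOPs under the kernel-weight accounting convention of
:mod:`sdunet.cost_model`).

Variants (the ablation grid):

===============  ==========  =============  ====
name             convs       normalization  WS
===============  ==========  =============  ====
``unet``         standard    none           no
``unet_gn``      standard    group norm     no
``unet_dw_bn``   separable   batch norm     no
``unet_dw_gn``   separable   group norm     no
``sd_unet_bn_ws`` separable  batch norm     yes
``sd_unet``      separable   group norm     yes
===============  ==========  =============  ====

The four separable variants share one topology, so their parameter counts
differ only through normalization affines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

from .layers import resolve_num_groups

__all__ = [
    "ModelConfig",
    "LayerSpec",
    "LayerGraph",
    "VARIANTS",
    "build_sd_unet",
    "build_unet",
    "build_variant",
]

# variant -> (separable convs, normalization kind, weight standardization)
VARIANTS: dict[str, tuple[bool, str | None, bool]] = {
    "unet": (False, None, False),
    "unet_gn": (False, "gn", False),
    "unet_dw_bn": (True, "bn", False),
    "unet_dw_gn": (True, "gn", False),
    "sd_unet_bn_ws": (True, "bn", True),
    "sd_unet": (True, "gn", True),
}

N_POOLS = 4


@dataclass(frozen=True)
class ModelConfig:
    """Configuration of a buildable segmentation model."""

    input_height: int = 256
    input_width: int = 256
    input_channels: int = 1
    base_filters: int = 64
    variant: str = "sd_unet"
    num_groups: int = 32
    dropout_rate: float = 0.5
    output_channels: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; choose from {sorted(VARIANTS)}")
        div = 2 ** N_POOLS
        if self.input_height % div or self.input_width % div:
            raise ValueError(
                f"input sides must be divisible by {div} "
                f"({N_POOLS} 2x poolings), got "
                f"{self.input_height} x {self.input_width}")
        for name in ("input_height", "input_width", "input_channels",
                     "base_filters", "num_groups", "output_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass
class LayerSpec:
    """One record of a layer graph.

    ``kernel``/``in_channels``/``out_channels`` are set for convolutions,
    ``num_groups`` for group norm, ``rate`` for dropout.  ``out_shape`` is
    the resolved (H, W, C) of the layer output for batch size 1.
    """

    name: str
    kind: str                       # input|conv|sep_conv|group_norm|batch_norm|
                                    # relu|sigmoid|softmax|maxpool|upsample|
                                    # dropout|concat
    inputs: tuple[str, ...] = ()
    kernel: tuple[int, int] | None = None
    in_channels: int | None = None
    out_channels: int | None = None
    use_bias: bool = False
    weight_standardized: bool = False
    num_groups: int | None = None
    rate: float | None = None
    out_shape: tuple[int, int, int] | None = None


@dataclass
class LayerGraph:
    """Ordered, named, shape-resolved layer records of one model."""

    config: ModelConfig
    layers: list[LayerSpec] = field(default_factory=list)
    _by_name: dict[str, LayerSpec] = field(default_factory=dict, repr=False)

    def __iter__(self):
        return iter(self.layers)

    def __len__(self):
        return len(self.layers)

    def __getitem__(self, name: str) -> LayerSpec:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def output_name(self) -> str:
        return self.layers[-1].name

    def add(self, spec: LayerSpec) -> LayerSpec:
        if spec.name in self._by_name:
            raise ValueError(f"duplicate layer name {spec.name!r}")
        for dep in spec.inputs:
            if dep not in self._by_name:
                raise ValueError(
                    f"layer {spec.name!r} references unknown input {dep!r}")
        self.layers.append(spec)
        self._by_name[spec.name] = spec
        return spec

    def to_dict(self) -> dict:
        cfg = vars(self.config).copy()
        recs = []
        for l in self.layers:
            r = {k: v for k, v in vars(l).items() if v not in (None, ())}
            recs.append(r)
        return {"config": cfg, "layers": recs}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def summary(self) -> str:
        lines = [f"{'name':<22}{'kind':<12}{'output shape':<18}{'params':>10}"]
        from .cost_model import _layer_cost
        total = 0
        for l in self.layers:
            cost = _layer_cost(l)
            p = cost.params if cost else 0
            total += p
            shape = "x".join(str(s) for s in l.out_shape)
            lines.append(f"{l.name:<22}{l.kind:<12}{shape:<18}{p:>10,}")
        lines.append("-" * len(lines[0]))
        lines.append(f"total trainable parameters: {total:,} "
                     f"({round(total / 1e6, 1)}M)")
        return "\n".join(lines)


class _Builder:
    """Emits the shared U-Net topology for one variant."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        self.graph = LayerGraph(config=cfg)
        self.separable, self.norm, self.ws = VARIANTS[cfg.variant]
        self._first_conv_done = False

    # -- low-level emitters -------------------------------------------
    def _conv(self, name, src, width, kernel=(3, 3), force_standard=False,
              use_bias=True):
        g = self.graph
        h, w, c = g[src].out_shape
        standard = force_standard or not self.separable or not self._first_conv_done
        self._first_conv_done = True
        if standard:
            spec = LayerSpec(name, "conv", (src,), kernel=kernel,
                             in_channels=c, out_channels=width,
                             use_bias=use_bias, out_shape=(h, w, width))
        else:
            ws = self.ws and kernel == (3, 3)
            spec = LayerSpec(name, "sep_conv", (src,), kernel=kernel,
                             in_channels=c, out_channels=width,
                             use_bias=use_bias, weight_standardized=ws,
                             out_shape=(h, w, width))
        g.add(spec)
        return name

    def _relu(self, name, src):
        shape = self.graph[src].out_shape
        self.graph.add(LayerSpec(name, "relu", (src,), out_shape=shape))
        return name

    def _norm(self, name, src):
        if self.norm is None:
            return src
        h, w, c = self.graph[src].out_shape
        if self.norm == "gn":
            groups = resolve_num_groups(self.cfg.num_groups, c)
            self.graph.add(LayerSpec(name, "group_norm", (src,),
                                     out_channels=c, num_groups=groups,
                                     out_shape=(h, w, c)))
        else:
            self.graph.add(LayerSpec(name, "batch_norm", (src,),
                                     out_channels=c, out_shape=(h, w, c)))
        return name

    def _pool(self, name, src):
        h, w, c = self.graph[src].out_shape
        self.graph.add(LayerSpec(name, "maxpool", (src,),
                                 out_shape=(h // 2, w // 2, c)))
        return name

    def _dropout(self, name, src):
        if self.cfg.dropout_rate <= 0:
            return src
        shape = self.graph[src].out_shape
        self.graph.add(LayerSpec(name, "dropout", (src,),
                                 rate=self.cfg.dropout_rate, out_shape=shape))
        return name

    def _upsample(self, name, src):
        h, w, c = self.graph[src].out_shape
        self.graph.add(LayerSpec(name, "upsample", (src,),
                                 out_shape=(h * 2, w * 2, c)))
        return name

    def _concat(self, name, srcs):
        shapes = [self.graph[s].out_shape for s in srcs]
        h, w = shapes[0][:2]
        if any(s[:2] != (h, w) for s in shapes):
            raise ValueError(f"concat {name!r} joins unequal spatial dims: {shapes}")
        c = sum(s[2] for s in shapes)
        self.graph.add(LayerSpec(name, "concat", tuple(srcs),
                                 out_shape=(h, w, c)))
        return name

    # -- blocks --------------------------------------------------------
    def _conv_block(self, tag, src, width, with_dropout=False):
        x = self._conv(f"{tag}_conv1", src, width)
        x = self._relu(f"{tag}_relu1", x)
        x = self._conv(f"{tag}_conv2", x, width)
        x = self._relu(f"{tag}_relu2", x)
        x = self._norm(f"{tag}_norm", x)
        if with_dropout:
            x = self._dropout(f"{tag}_drop", x)
        return x

    def build(self) -> LayerGraph:
        cfg = self.cfg
        b = cfg.base_filters
        self.graph.add(LayerSpec(
            "input", "input",
            out_shape=(cfg.input_height, cfg.input_width, cfg.input_channels)))

        widths = [b, 2 * b, 4 * b, 8 * b, 16 * b]
        skips = []
        x = "input"
        for i, w in enumerate(widths, start=1):
            x = self._conv_block(f"enc{i}", x, w, with_dropout=i >= 4)
            if i < 5:
                skips.append(x)
                x = self._pool(f"enc{i}_pool", x)

        for i, w in enumerate(reversed(widths[:-1]), start=6):
            skip = skips.pop()
            x = self._upsample(f"dec{i}_up", x)
            x = self._conv(f"dec{i}_upconv", x, w, kernel=(2, 2))
            x = self._relu(f"dec{i}_uprelu", x)
            x = self._concat(f"dec{i}_concat", [skip, x])
            x = self._conv(f"dec{i}_conv1", x, w)
            x = self._relu(f"dec{i}_relu1", x)
            x = self._conv(f"dec{i}_conv2", x, w)
            x = self._relu(f"dec{i}_relu2", x)
            x = self._norm(f"dec{i}_norm", x)

        # thin prediction stem, then the 1x1 output convolution
        stem = 2 if cfg.output_channels == 1 else cfg.output_channels
        x = self._conv("stem_conv", x, stem)
        x = self._relu("stem_relu", x)
        x = self._conv("out_conv", x, cfg.output_channels, kernel=(1, 1),
                       force_standard=True)
        act = "sigmoid" if cfg.output_channels == 1 else "softmax"
        shape = self.graph[x].out_shape
        self.graph.add(LayerSpec("output", act, (x,), out_shape=shape))
        return self.graph


def build_sd_unet(cfg: ModelConfig) -> LayerGraph:
    """SD-UNet: first conv standard, all others depthwise separable,
    group normalization per block, WS on depthwise 3x3 kernels."""
    if cfg.variant != "sd_unet":
        cfg = replace(cfg, variant="sd_unet")
    return _Builder(cfg).build()


def build_unet(cfg: ModelConfig) -> LayerGraph:
    """Baseline U-Net: all standard convolutions, no normalization."""
    if cfg.variant != "unet":
        cfg = replace(cfg, variant="unet")
    return _Builder(cfg).build()


def build_variant(name: str, cfg: ModelConfig) -> LayerGraph:
    """Build any ablation variant by name (see :data:`VARIANTS`)."""
    if name not in VARIANTS:
        raise ValueError(f"unknown variant {name!r}; choose from {sorted(VARIANTS)}")
    return _Builder(replace(cfg, variant=name)).build()
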