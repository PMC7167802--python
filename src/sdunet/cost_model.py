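"""Analytic cost accounting for standard vs. depthwise separable convolutions.

Two conventions are reported side by side and must not be confused:

* ``mult_adds`` — the textbook per-output-pixel count: a standard
  convolution costs ``Dk * Dk * M * N * Df * Df`` multiply–accumulates and
  its depthwise separable factorization costs
  ``Dk * Dk * M * Df * Df + M * N * Df * Df``.
* ``paper_flops`` — the accounting used in the source model-size tables,
  where a model's FLOPs equal two operations (one multiply, one add) per
  convolution kernel weight, each kernel counted once: FLOPs =
  ``2 x (kernel weights, excluding biases and normalization affines)``.
  Under this convention a 31.0M-parameter U-Net is a 62.0M-FLOP model and
  its 3.9M-parameter separable counterpart a 7.8M-FLOP one.

``model_accounting`` consumes any layer graph whose records expose
``name``, ``kind``, ``kernel``, ``in_channels``, ``out_channels``,
``use_bias`` and ``out_shape`` (see :mod:`sdunet.architectures`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

__all__ = [
    "ConvCostSpec",
    "CostReport",
    "LayerCost",
    "standard_conv_cost",
    "separable_conv_cost",
    "cost_reduction_ratio",
    "model_accounting",
]

BYTES_PER_PARAM = 4  # float32 weights-only serialization


@dataclass(frozen=True)
class ConvCostSpec:
    """Square-kernel, square-feature-map convolution cost inputs.

    Dk: kernel side; M: input channels; N: output channels; Df: feature-map
    side.
    """

    Dk: int
    M: int
    N: int
    Df: int = 1

    def __post_init__(self):
        for name in ("Dk", "M", "N", "Df"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")


def standard_conv_cost(s: ConvCostSpec) -> int:
    """Multiplications of a standard conv: Dk^2 * M * N * Df^2."""
    return s.Dk * s.Dk * s.M * s.N * s.Df * s.Df


def separable_conv_cost(s: ConvCostSpec) -> int:
    """Multiplications of the factorized conv: depthwise + pointwise terms."""
    depthwise = s.Dk * s.Dk * s.M * s.Df * s.Df
    pointwise = s.M * s.N * s.Df * s.Df
    return depthwise + pointwise


def cost_reduction_ratio(s: ConvCostSpec) -> float:
    """Standard / separable cost; Df and M cancel: Dk^2 * N / (Dk^2 + N).

    Monotonically increasing in N and bounded above by Dk^2 — hence the
    familiar "8 or 9 times" reduction for 3x3 kernels at large widths.
    """
    return standard_conv_cost(s) / separable_conv_cost(s)


# ----------------------------------------------------------------------
# whole-model accounting
# ----------------------------------------------------------------------

@dataclass
class LayerCost:
    name: str
    kind: str
    params: int         # trainable parameters: kernels + biases + affines
    kernel_weights: int  # convolution kernel entries only
    mult_adds: int      # per-output-pixel multiply-accumulates
    paper_flops: int    # 2 x kernel_weights


@dataclass
class CostReport:
    rows: list[LayerCost] = field(default_factory=list)

    @property
    def total_params(self) -> int:
        return sum(r.params for r in self.rows)

    @property
    def total_kernel_weights(self) -> int:
        return sum(r.kernel_weights for r in self.rows)

    @property
    def total_mult_adds(self) -> int:
        return sum(r.mult_adds for r in self.rows)

    @property
    def total_paper_flops(self) -> int:
        return sum(r.paper_flops for r in self.rows)

    @property
    def params_millions(self) -> float:
        return round(self.total_params / 1e6, 1)

    @property
    def paper_flops_millions(self) -> float:
        return round(self.total_paper_flops / 1e6, 1)

    @property
    def size_in_memory_mb(self) -> float:
        return round(self.total_params * BYTES_PER_PARAM / 2 ** 20, 1)

    def ratio_to(self, other: "CostReport") -> dict:
        """Fold reductions of ``other`` relative to this report."""
        return {
            "params": other.total_params / self.total_params,
            "paper_flops": other.total_paper_flops / self.total_paper_flops,
            "mult_adds": other.total_mult_adds / self.total_mult_adds,
        }

    def to_dict(self) -> dict:
        return {
            "layers": [vars(r) for r in self.rows],
            "totals": {
                "params": self.total_params,
                "params_millions": self.params_millions,
                "kernel_weights": self.total_kernel_weights,
                "paper_flops": self.total_paper_flops,
                "paper_flops_millions": self.paper_flops_millions,
                "mult_adds": self.total_mult_adds,
                "size_in_memory_mb": self.size_in_memory_mb,
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_text(self) -> str:
        lines = [f"{'layer':<22}{'kind':<12}{'params':>12}{'mult-adds':>16}{'paper-FLOPs':>14}"]
        for r in self.rows:
            lines.append(f"{r.name:<22}{r.kind:<12}{r.params:>12,}"
                         f"{r.mult_adds:>16,}{r.paper_flops:>14,}")
        lines.append("-" * len(lines[0]))
        lines.append(
            f"{'total':<34}{self.total_params:>12,}"
            f"{self.total_mult_adds:>16,}{self.total_paper_flops:>14,}")
        lines.append(
            f"params: {self.params_millions}M   paper FLOPs: "
            f"{self.paper_flops_millions}M   size: {self.size_in_memory_mb} MB")
        return "\n".join(lines)


def _layer_cost(layer) -> LayerCost | None:
    kind = layer.kind
    h, w = layer.out_shape[0], layer.out_shape[1]
    if kind == "conv":
        kh, kw = layer.kernel
        kernel = kh * kw * layer.in_channels * layer.out_channels
        params = kernel + (layer.out_channels if layer.use_bias else 0)
        mult_adds = kernel * h * w
    elif kind == "sep_conv":
        kh, kw = layer.kernel
        kernel = kh * kw * layer.in_channels + layer.in_channels * layer.out_channels
        params = kernel + (layer.out_channels if layer.use_bias else 0)
        mult_adds = kernel * h * w
    elif kind in ("group_norm", "batch_norm"):
        # gamma + beta; BN running statistics are not trainable
        params = 2 * layer.out_channels
        kernel = 0
        mult_adds = 0
    else:
        return None
    return LayerCost(layer.name, kind, params, kernel, mult_adds, 2 * kernel)


def model_accounting(graph) -> CostReport:
    """Per-layer and total parameter / FLOP accounting of a layer graph.

    Raises ``ValueError`` on a graph whose shapes are not resolved.
    """
    rows = []
    for layer in graph:
        if getattr(layer, "out_shape", None) is None:
            raise ValueError(f"layer {layer.name!r} has no resolved output shape")
        row = _layer_cost(layer)
        if row is not None:
            rows.append(row)
    return CostReport(rows=rows)
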