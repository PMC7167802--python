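"""Runnable, trainable models built from a :class:`~sdunet.architectures.LayerGraph`.

A :class:`Model` owns one autodiff :class:`~sdunet.autodiff.Tensor` per
trainable array (He-uniform kernels, zero biases/beta, unit gamma, all
drawn from a seeded generator) and executes the graph as a composition of
autodiff primitives, so a single ``backward()`` on the loss yields exact
gradients for every parameter.  Weight standardization is applied inside
every forward pass as a reparameterization of the raw depthwise kernels —
the optimizer always steps the unstandardized weights.

Batch normalization keeps running mean/variance buffers (momentum 0.99,
the Keras default); group normalization and weight standardization have
no state.  All computation is float64 numpy on CPU.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .architectures import LayerGraph
from .layers import DEFAULT_EPS

__all__ = ["Model"]

BN_MOMENTUM = 0.99


def _he_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape)


def _ws(w: ad.Tensor, axes: tuple, eps: float) -> ad.Tensor:
    """Differentiable weight standardization: (W - mu) / (sigma + eps),
    population sigma over ``axes``."""
    mu = ad.mean_(w, axis=axes, keepdims=True)
    centered = w - mu
    var = ad.mean_(centered * centered, axis=axes, keepdims=True)
    return centered / (ad.sqrt(var) + eps)


class Model:
    """A seeded, executable instance of a layer graph."""

    def __init__(self, graph: LayerGraph, seed: int | None = None,
                 eps: float = DEFAULT_EPS):
        self.graph = graph
        self.eps = eps
        self.seed = graph.config.seed if seed is None else seed
        rng = np.random.default_rng(self.seed)
        self.params: dict[str, ad.Tensor] = {}
        self.state: dict[str, np.ndarray] = {}  # BN running statistics
        for layer in graph:
            self._init_layer(layer, rng)

    # ------------------------------------------------------------------
    def _add_param(self, name: str, value: np.ndarray) -> None:
        self.params[name] = ad.Tensor(value, requires_grad=True, name=name)

    def _init_layer(self, layer, rng) -> None:
        kind = layer.kind
        if kind == "conv":
            kh, kw = layer.kernel
            fan_in = kh * kw * layer.in_channels
            self._add_param(f"{layer.name}.w", _he_uniform(
                rng, (kh, kw, layer.in_channels, layer.out_channels), fan_in))
            if layer.use_bias:
                self._add_param(f"{layer.name}.b", np.zeros(layer.out_channels))
        elif kind == "sep_conv":
            kh, kw = layer.kernel
            self._add_param(f"{layer.name}.dw", _he_uniform(
                rng, (kh, kw, layer.in_channels), kh * kw))
            self._add_param(f"{layer.name}.pw", _he_uniform(
                rng, (1, 1, layer.in_channels, layer.out_channels),
                layer.in_channels))
            if layer.use_bias:
                self._add_param(f"{layer.name}.b", np.zeros(layer.out_channels))
        elif kind in ("group_norm", "batch_norm"):
            c = layer.out_channels
            self._add_param(f"{layer.name}.gamma", np.ones(c))
            self._add_param(f"{layer.name}.beta", np.zeros(c))
            if kind == "batch_norm":
                self.state[f"{layer.name}.mean"] = np.zeros(c)
                self.state[f"{layer.name}.var"] = np.ones(c)

    # ------------------------------------------------------------------
    @property
    def num_parameters(self) -> int:
        return sum(int(p.value.size) for p in self.params.values())

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    # ------------------------------------------------------------------
    def forward(self, x, training: bool = False,
                rng: np.random.Generator | None = None) -> ad.Tensor:
        """Run the graph; returns the output activation Tensor.

        ``rng`` drives dropout and must be supplied when ``training`` and
        the graph contains dropout layers (keeps runs seed-reproducible).
        """
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        acts: dict[str, ad.Tensor] = {}
        for layer in self.graph:
            kind = layer.kind
            if kind == "input":
                cfg = self.graph.config
                expect = (cfg.input_height, cfg.input_width, cfg.input_channels)
                if x.shape[1:] != expect:
                    raise ValueError(
                        f"input shape {x.shape[1:]} does not match the graph's "
                        f"expected {expect}")
                acts[layer.name] = ad.Tensor(x)
                continue
            src = acts[layer.inputs[0]] if layer.inputs else None
            if kind == "conv":
                w = self.params[f"{layer.name}.w"]
                b = self.params.get(f"{layer.name}.b")
                acts[layer.name] = ad.conv2d(src, w, b)
            elif kind == "sep_conv":
                dw = self.params[f"{layer.name}.dw"]
                if layer.weight_standardized:
                    dw = _ws(dw, axes=(0, 1), eps=self.eps)
                mid = ad.depthwise_conv2d(src, dw)
                pw = self.params[f"{layer.name}.pw"]
                b = self.params.get(f"{layer.name}.b")
                acts[layer.name] = ad.conv2d(mid, pw, b)
            elif kind == "group_norm":
                acts[layer.name] = self._group_norm(layer, src)
            elif kind == "batch_norm":
                acts[layer.name] = self._batch_norm(layer, src, training)
            elif kind == "relu":
                acts[layer.name] = ad.relu(src)
            elif kind == "sigmoid":
                acts[layer.name] = ad.sigmoid(src)
            elif kind == "softmax":
                acts[layer.name] = ad.softmax(src)
            elif kind == "maxpool":
                acts[layer.name] = ad.maxpool2x2(src)
            elif kind == "upsample":
                acts[layer.name] = ad.upsample2x2(src)
            elif kind == "dropout":
                if training and rng is None:
                    raise ValueError("training-mode dropout needs an rng")
                acts[layer.name] = ad.dropout(src, layer.rate, rng,
                                              training=training)
            elif kind == "concat":
                acts[layer.name] = ad.concat(
                    [acts[n] for n in layer.inputs], axis=-1)
            else:  # pragma: no cover - builder emits only known kinds
                raise ValueError(f"unknown layer kind {kind!r}")
        return acts[self.graph.output_name]

    def _group_norm(self, layer, src: ad.Tensor) -> ad.Tensor:
        n, h, w, c = src.shape
        g = layer.num_groups
        xg = ad.reshape(src, (n, h, w, g, c // g))
        mu = ad.mean_(xg, axis=(1, 2, 4), keepdims=True)
        centered = xg - mu
        var = ad.mean_(centered * centered, axis=(1, 2, 4), keepdims=True)
        xhat = ad.reshape(centered / ad.sqrt(var + self.eps), (n, h, w, c))
        gamma = self.params[f"{layer.name}.gamma"]
        beta = self.params[f"{layer.name}.beta"]
        return xhat * gamma + beta

    def _batch_norm(self, layer, src: ad.Tensor, training: bool) -> ad.Tensor:
        gamma = self.params[f"{layer.name}.gamma"]
        beta = self.params[f"{layer.name}.beta"]
        if training:
            mu = ad.mean_(src, axis=(0, 1, 2), keepdims=True)
            centered = src - mu
            var = ad.mean_(centered * centered, axis=(0, 1, 2), keepdims=True)
            xhat = centered / ad.sqrt(var + self.eps)
            m = BN_MOMENTUM
            self.state[f"{layer.name}.mean"] = (
                m * self.state[f"{layer.name}.mean"] + (1 - m) * mu.value.ravel())
            self.state[f"{layer.name}.var"] = (
                m * self.state[f"{layer.name}.var"] + (1 - m) * var.value.ravel())
        else:
            mu = self.state[f"{layer.name}.mean"]
            var = self.state[f"{layer.name}.var"]
            xhat = (src - mu) / np.sqrt(var + self.eps)
        return xhat * gamma + beta

    # ------------------------------------------------------------------
    def predict(self, x) -> np.ndarray:
        """Inference-mode forward pass returning a plain array."""
        return self.forward(x, training=False).value

    # ------------------------------------------------------------------
    def save_weights(self, path) -> None:
        arrays = {f"param/{k}": p.value for k, p in self.params.items()}
        arrays.update({f"state/{k}": v for k, v in self.state.items()})
        np.savez(path, **arrays)

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            for key in data.files:
                scope, name = key.split("/", 1)
                if scope == "param":
                    if name not in self.params:
                        raise KeyError(f"unexpected parameter {name!r}")
                    if self.params[name].value.shape != data[key].shape:
                        raise ValueError(f"shape mismatch for {name!r}")
                    self.params[name].value = data[key].astype(np.float64)
                else:
                    self.state[name] = data[key].astype(np.float64)
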