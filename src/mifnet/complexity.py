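"""Analytic complexity accounting over a layer graph.

Implements the standard convolutional geometry calculus —

* output size   ``v_out = (v_in + 2p - k) / s + 1`` (floor for convolutions,
  ceil for the 2x2 poolings, forced by the 25 -> 13 trajectory),
* jump (accumulated stride)  ``c_l = c_{l-1} * s``,
* receptive field  ``r_l = r_{l-1} + (k - 1) * prod(previous strides)``,

together with trainable-parameter, FLOP and serialized-size accounting.

FLOPs follow a frozen convention: one multiply-accumulate per unit,
convolution and dense layers only; batch norm, activations and pooling are
counted as zero.  Model size assumes 4 bytes (float32) per parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

from .graph import LayerGraph, LayerSpec


class GeometryError(ValueError):
    """Raised when layer geometry produces an empty output."""


@dataclass
class ReceptiveFieldState:
    """Geometry state propagated along a layer chain.

    Attributes
    ----------
    v : output spatial size in pixels
    c : jump (accumulated stride product) in pixels
    r : receptive-field side length in pixels
    """

    v: int
    c: int = 1
    r: int = 1

    def step(self, kernel: int, stride: int, padding: int = 0,
             rounding_mode: str = "floor") -> "ReceptiveFieldState":
        """Advance through one layer of the given kernel/stride/padding."""
        v = conv_output_size(self.v, kernel, padding, stride, rounding_mode)
        r = self.r + (kernel - 1) * self.c
        c = jump(self.c, stride)
        return ReceptiveFieldState(v=v, c=c, r=r)


def conv_output_size(v_in: int, kernel: int, padding: int, stride: int,
                     rounding_mode: str = "floor") -> int:
    """Spatial output size of a convolution or pooling layer."""
    if min(v_in, kernel, stride) < 1 or padding < 0:
        raise GeometryError(
            f"invalid geometry: v_in={v_in} kernel={kernel} "
            f"padding={padding} stride={stride}")
    num = v_in + 2 * padding - kernel
    if rounding_mode == "floor":
        v_out = num // stride + 1
    elif rounding_mode == "ceil":
        v_out = -(-num // stride) + 1
    else:
        raise ValueError(f"rounding_mode must be floor or ceil, "
                         f"got {rounding_mode!r}")
    if v_out < 1:
        raise GeometryError(
            f"kernel {kernel} with padding {padding} does not fit into "
            f"input of size {v_in}")
    return v_out


def jump(previous_jump: int, stride: int) -> int:
    """Accumulated stride: the jump multiplies by each layer's stride."""
    return previous_jump * stride


def receptive_field(layer_chain: Sequence[Tuple[int, int]]) -> int:
    """Receptive-field side length of a chain of (kernel, stride) layers.

    The empty prefix sees a single pixel (r = 1); each layer adds
    ``(kernel - 1) * prod(previous strides)``.  Two stacked 3x3 stride-1
    convolutions therefore see a 5x5 input patch.
    """
    if not layer_chain:
        raise ValueError("layer chain must be non-empty")
    r, c = 1, 1
    for kernel, stride in layer_chain:
        r += (kernel - 1) * c
        c *= stride
    return r


# -- per-layer accounting -------------------------------------------------

def layer_parameters(spec: LayerSpec) -> int:
    """Trainable parameters of one layer."""
    if spec.kind == "conv":
        p = spec.kernel ** 2 * spec.in_channels * spec.out_channels // spec.groups
        return p + (spec.out_channels if spec.bias else 0)
    if spec.kind == "batchnorm":
        return 2 * spec.out_channels  # scale + shift
    if spec.kind == "dense":
        return spec.in_channels * spec.out_channels + (
            spec.out_channels if spec.bias else 0)
    return 0


def layer_flops(spec: LayerSpec, out_spatial: int) -> int:
    """Multiply-accumulates of one layer at the given output spatial size."""
    if spec.kind == "conv":
        return (out_spatial ** 2 * spec.kernel ** 2
                * spec.in_channels * spec.out_channels // spec.groups)
    if spec.kind == "dense":
        return spec.in_channels * spec.out_channels
    return 0


def _spatial_sizes(graph: LayerGraph, input_size: int) -> List[int]:
    """Output spatial size of every node (square feature maps)."""
    sizes = [0] * len(graph)
    for i in graph.topological_order():
        spec = graph.nodes[i]
        parents = graph.parents[i]
        if not parents:
            sizes[i] = input_size
            continue
        v_in = sizes[parents[0]]
        if spec.kind == "conv":
            sizes[i] = conv_output_size(v_in, spec.kernel, spec.pad_amount,
                                        spec.stride, "floor")
        elif spec.kind in ("maxpool", "avgpool"):
            sizes[i] = conv_output_size(
                v_in, spec.kernel, spec.pad_amount, spec.stride,
                "ceil" if spec.ceil_mode else "floor")
        elif spec.kind in ("flatten", "dense", "softmax"):
            sizes[i] = 1
        else:
            sizes[i] = v_in
    return sizes


def count_parameters(graph: LayerGraph) -> int:
    """Total trainable parameters of a layer graph."""
    return sum(layer_parameters(spec) for spec in graph.nodes)


def count_flops(graph: LayerGraph, input_size: int) -> int:
    """Multiply-accumulate count of one forward pass at ``input_size``."""
    sizes = _spatial_sizes(graph, input_size)
    return sum(layer_flops(spec, sizes[i])
               for i, spec in enumerate(graph.nodes))


def model_size_mb(parameter_count: int, bytes_per_parameter: int = 4) -> float:
    """Serialized model size in MB (2**20 bytes)."""
    if parameter_count < 0:
        raise ValueError("parameter_count must be >= 0")
    return bytes_per_parameter * parameter_count / 2 ** 20


@dataclass
class ComplexityReport:
    """Totals plus a per-layer breakdown for one network at one input size."""

    parameter_count: int
    flops: int
    model_size_bytes: int
    input_size: int
    per_layer: List[dict] = field(default_factory=list)
    flop_convention: str = ("multiply-accumulates, conv+dense only; "
                            "BN/activation/pooling counted as zero")

    @property
    def model_size_mb(self) -> float:
        return self.model_size_bytes / 2 ** 20

    def to_table(self) -> str:
        """Per-layer breakdown as a tab-separated table."""
        lines = ["name\tkind\tin_ch\tout_ch\tout_size\tparams\tflops"]
        for row in self.per_layer:
            lines.append("\t".join(str(row[c]) for c in (
                "name", "kind", "in_channels", "out_channels",
                "out_size", "params", "flops")))
        lines.append(f"total\t\t\t\t\t{self.parameter_count}\t{self.flops}")
        return "\n".join(lines)


def analyze(graph: LayerGraph, input_size: int,
            bytes_per_parameter: int = 4) -> ComplexityReport:
    """Full complexity report; totals equal the sum of per-layer entries."""
    sizes = _spatial_sizes(graph, input_size)
    rows = []
    for i, spec in enumerate(graph.nodes):
        rows.append({
            "name": spec.name or f"node{i}",
            "kind": spec.kind,
            "in_channels": spec.in_channels,
            "out_channels": spec.out_channels,
            "out_size": sizes[i],
            "params": layer_parameters(spec),
            "flops": layer_flops(spec, sizes[i]),
        })
    params = sum(r["params"] for r in rows)
    flops = sum(r["flops"] for r in rows)
    return ComplexityReport(
        parameter_count=params,
        flops=flops,
        model_size_bytes=bytes_per_parameter * params,
        input_size=input_size,
        per_layer=rows,
    )


def stage_receptive_fields(graph: LayerGraph, input_size: int) -> List[dict]:
    """Receptive-field state at each pooling (stage) boundary.

    Propagates :class:`ReceptiveFieldState` along the deepest convolutional
    path of the graph (branches share geometry, so any branch is
    representative) and records the state after each pooling layer.
    """
    states: List[ReceptiveFieldState] = [None] * len(graph)  # type: ignore
    boundaries = []
    for i in graph.topological_order():
        spec = graph.nodes[i]
        parents = graph.parents[i]
        if not parents:
            states[i] = ReceptiveFieldState(v=input_size)
            continue
        prev = max((states[p] for p in parents), key=lambda s: s.r)
        if spec.kind == "conv":
            states[i] = prev.step(spec.kernel, spec.stride, spec.pad_amount)
        elif spec.kind in ("maxpool", "avgpool"):
            # ceil-mode implemented as implicit one-sided padding
            pad = spec.pad_amount
            if spec.ceil_mode:
                rem = (prev.v + 2 * pad - spec.kernel) % spec.stride
                pad_total = 2 * pad + (spec.stride - rem) % spec.stride
            else:
                pad_total = 2 * pad
            v = conv_output_size(prev.v + pad_total, spec.kernel, 0,
                                 spec.stride, "floor")
            states[i] = ReceptiveFieldState(
                v=v, c=jump(prev.c, spec.stride),
                r=prev.r + (spec.kernel - 1) * prev.c)
            boundaries.append({"layer": spec.name or f"node{i}",
                               "v": states[i].v, "c": states[i].c,
                               "r": states[i].r})
        else:
            states[i] = prev
    return boundaries
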