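"""Symbolic layer graph.

The architecture is first assembled as a directed acyclic graph of
:class:`LayerSpec` nodes.  Both the runnable NumPy network (:mod:`mifnet.nn`)
and the analytic complexity accounting (:mod:`mifnet.complexity`) are derived
from this single symbolic description, so parameter/FLOP counts and the
executed model can never drift apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

CONV_KINDS = {"conv"}
#: kinds with no trainable parameters
STATELESS_KINDS = {"relu", "maxpool", "avgpool", "dropout", "concat", "add",
                   "flatten", "softmax", "input"}
ALL_KINDS = CONV_KINDS | STATELESS_KINDS | {"batchnorm", "dense"}


class GraphError(ValueError):
    """Raised for structurally invalid layer graphs."""


@dataclass(frozen=True)
class LayerSpec:
    """One node of the layer graph.

    ``padding`` is either the string ``"same"`` (stride-1 size-preserving) or
    an explicit non-negative integer.  ``ceil_mode`` applies to pooling only;
    the published spatial trajectory 50 -> 25 -> 13 -> 7 forces ceil-mode
    2x2 stride-2 pooling.
    """

    kind: str
    in_channels: int = 0
    out_channels: int = 0
    kernel: int = 1
    stride: int = 1
    padding: object = 0
    groups: int = 1
    bias: bool = False
    rate: float = 0.0          # dropout rate
    ceil_mode: bool = True     # pooling rounding
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ALL_KINDS:
            raise GraphError(f"unknown layer kind {self.kind!r}")
        if self.kind == "conv":
            if self.in_channels % self.groups or self.out_channels % self.groups:
                raise GraphError(
                    f"conv {self.name or '?'}: channels "
                    f"({self.in_channels} -> {self.out_channels}) must be "
                    f"divisible by groups={self.groups}")
        if self.padding != "same" and (not isinstance(self.padding, int)
                                       or self.padding < 0):
            raise GraphError(f"invalid padding {self.padding!r}")

    @property
    def pad_amount(self) -> int:
        """Explicit pixel padding ('same' keeps stride-1 output size)."""
        if self.padding == "same":
            return (self.kernel - 1) // 2
        return self.padding


class LayerGraph:
    """Ordered DAG of layers with branch splits, shortcuts and fusion joins."""

    def __init__(self) -> None:
        self.nodes: List[LayerSpec] = []
        self.parents: List[List[int]] = []

    def add(self, spec: LayerSpec, parents: Sequence[int] = ()) -> int:
        """Append a node whose inputs are ``parents``; returns its id."""
        for p in parents:
            if not 0 <= p < len(self.nodes):
                raise GraphError(f"parent id {p} out of range")
        if spec.kind == "concat":
            total = sum(self.nodes[p].out_channels for p in parents)
            if spec.out_channels and spec.out_channels != total:
                raise GraphError(
                    f"concat output channels {spec.out_channels} != sum of "
                    f"inputs {total}")
            spec = LayerSpec(kind="concat", in_channels=total,
                             out_channels=total, name=spec.name)
        self.nodes.append(spec)
        self.parents.append(list(parents))
        return len(self.nodes) - 1

    def __len__(self) -> int:
        return len(self.nodes)

    def children(self) -> List[List[int]]:
        out: List[List[int]] = [[] for _ in self.nodes]
        for i, ps in enumerate(self.parents):
            for p in ps:
                out[p].append(i)
        return out

    @property
    def input_id(self) -> int:
        roots = [i for i, ps in enumerate(self.parents) if not ps]
        if len(roots) != 1:
            raise GraphError(f"expected exactly one input node, found {roots}")
        return roots[0]

    @property
    def output_id(self) -> int:
        ch = self.children()
        leaves = [i for i, c in enumerate(ch) if not c]
        if len(leaves) != 1:
            raise GraphError(f"expected exactly one output node, found {leaves}")
        return leaves[0]

    def validate(self) -> None:
        """Check acyclicity (by construction), IO uniqueness, concat sums."""
        _ = self.input_id, self.output_id
        for i, spec in enumerate(self.nodes):
            for p in self.parents[i]:
                if p >= i:
                    raise GraphError("graph edges must point forward")
            if spec.kind == "concat":
                total = sum(self.nodes[p].out_channels for p in self.parents[i])
                if spec.out_channels != total:
                    raise GraphError(
                        f"concat node {i}: output channels {spec.out_channels}"
                        f" != sum of inputs {total}")
            elif spec.kind == "add":
                chans = {self.nodes[p].out_channels for p in self.parents[i]}
                if len(chans) > 1:
                    raise GraphError(
                        f"add node {i}: mismatched input channels {chans}")

    def topological_order(self) -> List[int]:
        # nodes are appended with forward-pointing edges, so list order works
        return list(range(len(self.nodes)))
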