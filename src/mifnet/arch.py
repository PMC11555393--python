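"""MIFNet assembly: mini-blocks, interleaved channel fusion, MIF blocks.

The network is a stack of three stages.  Each stage opens with a 1x1 scaling
convolution that sets the stage width, holds one MIF block (three parallel
branches of ``k`` mini-blocks with cyclic interleaved channel fusion between
consecutive mini-blocks), and closes with a 2x2 stride-2 pooling plus dropout.
A mini-block is the atomic unit Conv(1x1) -> BN -> ReLU -> grouped Conv(3x3,
'same') -> BN -> ReLU.

Two fusion topologies are supported (see :class:`mifnet.config.NetworkConfig`):

``growth``
    The 3x3 width of every mini-block matches its fused input, so per-branch
    channels grow by a factor ``C`` per mini-block (repeated concatenation
    grows the feature dimension); the 3x3 group count scales with the width so
    the per-group width stays constant (capped by divisibility), and the block
    output is the element-wise integration (sum) of the three fused branch
    outputs, classified through a global average pool.  This is the calibrated
    topology behind the published complexity ladder.

``reduced``
    Widths stay at the stage width, the block output is the channel
    concatenation of the three branch outputs, and the final 7x7 map is
    flattened into the classifier.
"""

from __future__ import annotations

import math
from typing import List, Sequence, Tuple

import numpy as np

from .config import ConfigurationError, NetworkConfig
from .graph import GraphError, LayerGraph, LayerSpec


class FusionError(ValueError):
    """Raised when branch outputs cannot be fused."""


def fusion_groups(branches: int, fusion_channels: int) -> List[Tuple[int, ...]]:
    """Cyclic interleaving scheme: branch ``i`` fuses branches
    ``i, i+1, ..., i+C-1 (mod branches)``."""
    if not 1 <= fusion_channels <= branches:
        raise FusionError(
            f"fusion_channels must lie in [1, {branches}], got {fusion_channels}")
    return [tuple((i + d) % branches for d in range(fusion_channels))
            for i in range(branches)]


def interleave_fuse(branch_outputs: Sequence[np.ndarray],
                    fusion_channels: int) -> List[np.ndarray]:
    """Fuse branch feature maps by cyclic channel concatenation.

    Each branch's next-layer input is the channel-wise concatenation of its
    own output with the following ``C - 1`` branches' outputs (cyclically).
    ``C = 1`` routes every branch's own output through unchanged.

    Parameters
    ----------
    branch_outputs
        Feature maps of shape ``(..., channels, height, width)``, one per
        branch, sharing spatial size.
    fusion_channels
        Number of branch outputs concatenated per fused input.
    """
    spatial = {arr.shape[-2:] for arr in branch_outputs}
    if len(spatial) != 1:
        raise FusionError(f"mismatched spatial sizes: {sorted(spatial)}")
    groups = fusion_groups(len(branch_outputs), fusion_channels)
    if fusion_channels == 1:
        return [branch_outputs[i] for i in range(len(branch_outputs))]
    return [np.concatenate([branch_outputs[j] for j in idx], axis=-3)
            for idx in groups]


def _mini_block_groups(base_groups: int, bottleneck: int, out_channels: int,
                       block_index: int, fusion_channels: int,
                       grow: bool) -> int:
    """Group count of the 3x3 conv in mini-block ``block_index`` (0-based).

    In growth mode the group count scales with the fused width so the
    per-group width stays constant; divisibility caps it at the largest
    common divisor with the bottleneck and output widths.
    """
    g = base_groups * (fusion_channels ** block_index) if grow else base_groups
    if bottleneck % g or out_channels % g:
        g = math.gcd(g, math.gcd(bottleneck, out_channels))
    return max(g, 1)


def _append_mini_block(graph: LayerGraph, parent: int, in_channels: int,
                       bottleneck: int, out_channels: int, groups: int,
                       name: str, shortcut: int | None = None) -> int:
    """Append Conv(1x1)->BN->ReLU->Conv(3x3,g)->BN[->add shortcut]->ReLU."""
    if bottleneck % groups or out_channels % groups:
        raise ConfigurationError(
            f"{name}: bottleneck {bottleneck} / width {out_channels} not "
            f"divisible by groups {groups}")
    n = graph.add(LayerSpec("conv", in_channels, bottleneck, kernel=1,
                            padding=0, name=f"{name}.conv1x1"), [parent])
    n = graph.add(LayerSpec("batchnorm", bottleneck, bottleneck,
                            name=f"{name}.bn1"), [n])
    n = graph.add(LayerSpec("relu", bottleneck, bottleneck,
                            name=f"{name}.relu1"), [n])
    n = graph.add(LayerSpec("conv", bottleneck, out_channels, kernel=3,
                            padding="same", groups=groups,
                            name=f"{name}.conv3x3"), [n])
    n = graph.add(LayerSpec("batchnorm", out_channels, out_channels,
                            name=f"{name}.bn2"), [n])
    if shortcut is not None:
        n = graph.add(LayerSpec("add", out_channels, out_channels,
                                name=f"{name}.shortcut_add"), [n, shortcut])
    n = graph.add(LayerSpec("relu", out_channels, out_channels,
                            name=f"{name}.relu2"), [n])
    return n


def build_mini_block(in_channels: int, bottleneck: int, out_channels: int,
                     groups: int) -> LayerGraph:
    """Standalone mini-block fragment (with its own input node).

    The fragment is Conv(1x1, in->bottleneck) -> BN -> ReLU ->
    grouped Conv(3x3 'same', bottleneck->out) -> BN -> ReLU; with
    ``groups = 1`` the grouped convolution degenerates to a standard one.
    """
    graph = LayerGraph()
    root = graph.add(LayerSpec("input", in_channels, in_channels, name="input"))
    _append_mini_block(graph, root, in_channels, bottleneck, out_channels,
                       groups, "mini")
    return graph


def _append_fusion(graph: LayerGraph, branch_ids: Sequence[int],
                   fusion_channels: int, name: str) -> List[int]:
    """Symbolic counterpart of :func:`interleave_fuse`: concat nodes."""
    groups = fusion_groups(len(branch_ids), fusion_channels)
    if fusion_channels == 1:
        return list(branch_ids)
    return [graph.add(LayerSpec("concat", name=f"{name}.fuse{i}"),
                      [branch_ids[j] for j in idx])
            for i, idx in enumerate(groups)]


def _append_mif_block(graph: LayerGraph, parent: int, stage_index: int,
                      config: NetworkConfig) -> int:
    """Append one MIF block (three fused branches of k mini-blocks)."""
    if stage_index not in (1, 2, 3):
        raise ConfigurationError(f"stage_index must be 1..3, got {stage_index}")
    s = stage_index - 1
    w = config.stage_widths[s]
    b = config.bottleneck_widths[s]
    g0 = config.groups[s]
    k = config.mini_blocks_per_stage
    C = config.fusion_channels
    grow = config.fusion_mode == "growth"

    block_input = parent
    current = [parent] * config.branches  # fused input per branch
    in_ch = [w] * config.branches
    for j in range(k):
        outputs = []
        for i in range(config.branches):
            out_ch = in_ch[i] if grow else w
            groups = _mini_block_groups(g0, b, out_ch, j, C, grow)
            # identity shortcut from the block input where channels match,
            # added before the mini-block's final ReLU
            shortcut = block_input if out_ch == w else None
            outputs.append(_append_mini_block(
                graph, current[i], in_ch[i], b, out_ch, groups,
                f"stage{stage_index}.branch{i + 1}.mini{j + 1}",
                shortcut=shortcut))
        last = j == k - 1
        if last and not grow:
            # reduced topology: block output = concat of the branch outputs
            return graph.add(
                LayerSpec("concat", name=f"stage{stage_index}.block_out"),
                outputs)
        fused = _append_fusion(graph, outputs, C,
                               f"stage{stage_index}.mini{j + 1}")
        if last:
            # growth topology: integrate the three fused branch outputs
            if config.branches == 1:
                return fused[0]
            return graph.add(
                LayerSpec("add",
                          in_channels=graph.nodes[fused[0]].out_channels,
                          out_channels=graph.nodes[fused[0]].out_channels,
                          name=f"stage{stage_index}.block_out"),
                fused)
        current = fused
        in_ch = [graph.nodes[f].out_channels for f in fused]
    raise AssertionError("unreachable")


def build_mif_block(stage_index: int, config: NetworkConfig) -> LayerGraph:
    """Standalone MIF-block fragment for one stage (with its own input)."""
    if config.mini_blocks_per_stage < 1:
        raise ConfigurationError("mini_blocks_per_stage must be >= 1")
    if stage_index not in (1, 2, 3):
        raise ConfigurationError(f"stage_index must be 1..3, got {stage_index}")
    w = config.stage_widths[stage_index - 1]
    graph = LayerGraph()
    root = graph.add(LayerSpec("input", w, w, name="input"))
    _append_mif_block(graph, root, stage_index, config)
    return graph


def _pooled_size(size: int, times: int) -> int:
    for _ in range(times):
        size = -(-size // 2)  # ceil-mode 2x2 stride 2
    return size


def assemble_mifnet(config: NetworkConfig) -> LayerGraph:
    """Assemble the full network graph for one family member.

    Layout: [scale 1x1 -> MIF block -> 2x2 pool (max, then average) +
    dropout] x 3, then the classification head (global average pooling in
    growth mode, flatten of the 7x7 map in reduced mode) -> dense -> softmax.
    For a 50-pixel input the spatial trajectory across the three ceil-mode
    poolings is 50 -> 25 -> 13 -> 7.
    """
    graph = LayerGraph()
    node = graph.add(LayerSpec("input", config.input_channels,
                               config.input_channels, name="input"))
    in_ch = config.input_channels
    pool_kinds = ("maxpool", "avgpool", "avgpool")
    for s in range(3):
        w = config.stage_widths[s]
        node = graph.add(LayerSpec("conv", in_ch, w, kernel=1, padding=0,
                                   name=f"stage{s + 1}.scale"), [node])
        node = graph.add(LayerSpec("batchnorm", w, w,
                                   name=f"stage{s + 1}.scale_bn"), [node])
        node = graph.add(LayerSpec("relu", w, w,
                                   name=f"stage{s + 1}.scale_relu"), [node])
        node = _append_mif_block(graph, node, s + 1, config)
        ch = graph.nodes[node].out_channels
        node = graph.add(LayerSpec(pool_kinds[s], ch, ch, kernel=2, stride=2,
                                   ceil_mode=True,
                                   name=f"stage{s + 1}.pool"), [node])
        node = graph.add(LayerSpec("dropout", ch, ch,
                                   rate=config.dropout_rates[s],
                                   name=f"stage{s + 1}.dropout"), [node])
        in_ch = ch
    final_spatial = _pooled_size(config.input_size, 3)
    if config.fusion_mode == "growth":
        # classification head opens with a global average pool
        node = graph.add(LayerSpec("avgpool", in_ch, in_ch,
                                   kernel=final_spatial, stride=final_spatial,
                                   ceil_mode=False, name="head.gap"), [node])
        features = in_ch
    else:
        features = in_ch * final_spatial * final_spatial
    node = graph.add(LayerSpec("flatten", in_ch, features,
                               name="head.flatten"), [node])
    node = graph.add(LayerSpec("dense", features, config.num_classes,
                               bias=True, name="head.dense"), [node])
    graph.add(LayerSpec("softmax", config.num_classes, config.num_classes,
                        name="head.softmax"), [node])
    graph.validate()
    return graph
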