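"""Network-family configuration.

A :class:`NetworkConfig` pins down one member of the MIFNet family: a
three-stage CNN for 50x50 grayscale CT patches in which each stage holds a
multi-scale interleaved-fusion (MIF) block of three parallel branches.  The
family is indexed by the number of mini-blocks per stage ``k`` (nominal depth
``3 + 6k + 1``: three scaling layers, ``k`` mini-blocks x 2 conv layers x 3
stages, one classification layer), the per-stage widths and 1x1 bottleneck
widths, the 3x3 group counts, and the number of fusion channels ``C``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Tuple


class ConfigurationError(ValueError):
    """Raised when a configuration violates a structural invariant."""


@dataclass(frozen=True)
class NetworkConfig:
    """Full parameterization of one MIFNet family member.

    Parameters
    ----------
    stage_widths
        Channel count set by each stage's 1x1 scaling layer. The width doubles
        whenever the feature map is down-sampled.
    bottleneck_widths
        Output channels of the 1x1 reduction inside each mini-block.
    mini_blocks_per_stage
        ``k``, the number of stacked mini-blocks per branch in every stage.
    groups
        Base group count of the 3x3 grouped convolution, per stage.
    fusion_channels
        ``C``: how many branch outputs are concatenated (cyclically) to form
        each branch's next input. ``C = 1`` disables cross-branch mixing.
    fusion_mode
        ``"growth"`` (calibrated default): each mini-block's 3x3 width matches
        its concatenation-grown input, so per-branch channels grow by a factor
        ``C`` per mini-block and the block output is the element-wise
        integration of the three fused branches, classified through a global
        average pool.  ``"reduced"``: widths stay at the stage width, the block
        output is the channel concatenation of the three branches, and the 7x7
        map is flattened into the classifier.
    """

    stage_widths: Tuple[int, int, int] = (16, 32, 64)
    bottleneck_widths: Tuple[int, int, int] = (4, 8, 16)
    mini_blocks_per_stage: int = 3
    groups: Tuple[int, int, int] = (4, 4, 4)
    fusion_channels: int = 2
    branches: int = 3
    dropout_rates: Tuple[float, float, float] = (0.1, 0.2, 0.3)
    input_size: int = 50
    input_channels: int = 1
    num_classes: int = 2
    fusion_mode: str = "growth"

    def __post_init__(self) -> None:
        k = self.mini_blocks_per_stage
        if k < 1:
            raise ConfigurationError(
                f"mini_blocks_per_stage must be >= 1, got {k}")
        if self.fusion_channels < 1 or self.fusion_channels > self.branches:
            raise ConfigurationError(
                f"fusion_channels must lie in [1, {self.branches}], "
                f"got {self.fusion_channels}")
        if self.fusion_mode not in ("growth", "reduced"):
            raise ConfigurationError(
                f"unknown fusion_mode {self.fusion_mode!r}")
        for s, (w, b, g) in enumerate(
                zip(self.stage_widths, self.bottleneck_widths, self.groups),
                start=1):
            if w % g or b % g:
                raise ConfigurationError(
                    f"stage {s}: width {w} and bottleneck {b} must both be "
                    f"divisible by the group count {g}")
        # three ceil-mode 2x2 stride-2 poolings must leave >= 1 pixel
        size = self.input_size
        for _ in range(3):
            size = -(-size // 2)
        if self.input_size < 8 or size < 1:
            raise ConfigurationError(
                f"input_size {self.input_size} too small to survive three "
                f"2x2 stride-2 poolings")

    @property
    def nominal_depth(self) -> int:
        """Conv-layer depth: 3 scaling + 6k mini-block convs + 1 classifier."""
        return 3 + 6 * self.mini_blocks_per_stage + 1

    # -- flat key/value serialization ------------------------------------

    def to_file(self, path: str | Path) -> None:
        lines = []
        for key, value in asdict(self).items():
            if isinstance(value, tuple):
                value = ",".join(str(v) for v in value)
            lines.append(f"{key} = {value}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "NetworkConfig":
        kwargs = {}
        tuple_fields = {"stage_widths", "bottleneck_widths", "groups",
                        "dropout_rates"}
        int_fields = {"mini_blocks_per_stage", "fusion_channels", "branches",
                      "input_size", "input_channels", "num_classes"}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigurationError(
                    f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key in tuple_fields:
                cast = float if key == "dropout_rates" else int
                kwargs[key] = tuple(cast(v) for v in value.split(","))
            elif key in int_fields:
                kwargs[key] = int(value)
            elif key == "fusion_mode":
                kwargs[key] = value
            else:
                raise ConfigurationError(
                    f"{path}:{lineno}: unknown configuration key {key!r}")
        return cls(**kwargs)


def _preset(k: int, **overrides) -> NetworkConfig:
    return replace(NetworkConfig(mini_blocks_per_stage=k), **overrides)


#: Named presets covering the published depth ladder (nominal depths
#: 10..46 for k = 1, 3, 4, 5, 6, 7) plus the doubled-width 46-layer variant.
PRESETS = {
    "mifnet10": _preset(1),
    "mifnet22": _preset(3),
    "mifnet28": _preset(4),
    "mifnet34": _preset(5),
    "mifnet40": _preset(6),
    "mifnet46": _preset(7),
    "mifnet46_wide": _preset(7, stage_widths=(32, 64, 128)),
}


def get_preset(name: str) -> NetworkConfig:
    try:
        return PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
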