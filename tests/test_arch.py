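"""Architecture assembly: mini-blocks, fusion, MIF blocks, forward pass."""

import numpy as np
import pytest
from scipy.signal import correlate

from mifnet import (NetworkConfig, assemble_mifnet, build_mif_block,
                    build_mini_block, get_preset, interleave_fuse)
from mifnet.arch import FusionError, fusion_groups
from mifnet.config import ConfigurationError
from mifnet.graph import LayerGraph, LayerSpec
from mifnet.nn import Network
from mifnet.nn.layers import Conv2d


class TestMiniBlock:
    def test_structure(self):
        """(16,4,16,4): two conv layers, Conv->BN->ReLU twice, size kept."""
        frag = build_mini_block(16, 4, 16, 4)
        kinds = [n.kind for n in frag.nodes]
        assert kinds == ["input", "conv", "batchnorm", "relu",
                         "conv", "batchnorm", "relu"]
        convs = [n for n in frag.nodes if n.kind == "conv"]
        assert (convs[0].kernel, convs[0].in_channels,
                convs[0].out_channels) == (1, 16, 4)
        assert (convs[1].kernel, convs[1].groups,
                convs[1].padding) == (3, 4, "same")

    def test_groups_one_is_standard_conv(self):
        frag = build_mini_block(16, 4, 16, 1)
        conv3 = [n for n in frag.nodes if n.kind == "conv"][1]
        assert conv3.groups == 1

    def test_weight_counts(self):
        """(32,8,32,4): 1x1 holds 32*8=256 weights, 3x3 holds 9*8*32/4=576.

        Expected values frozen from brute-force enumeration of the weight
        tensor shapes (bias excluded)."""
        frag = build_mini_block(32, 8, 32, 4)
        net = Network(frag, seed=0)
        convs = [m for m in net.modules if isinstance(m, Conv2d)]
        assert convs[0].weight.value.size == 256
        assert convs[1].weight.value.size == 576

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ConfigurationError, match="groups"):
            build_mini_block(16, 6, 16, 4)


class TestInterleaveFuse:
    def test_cyclic_concatenation_c2(self):
        """Three 16-channel maps, C=2 -> three 32-channel fused inputs."""
        maps = [np.full((1, 16, 5, 5), i, dtype=float) for i in range(3)]
        fused = interleave_fuse(maps, 2)
        assert [f.shape[1] for f in fused] == [32, 32, 32]
        # branch i holds branches i and i+1 (mod 3)
        for i, f in enumerate(fused):
            assert np.all(f[:, :16] == i)
            assert np.all(f[:, 16:] == (i + 1) % 3)

    def test_c1_identity_routing(self):
        maps = [np.random.default_rng(i).random((2, 4, 3, 3))
                for i in range(3)]
        fused = interleave_fuse(maps, 1)
        for m, f in zip(maps, fused):
            np.testing.assert_array_equal(m, f)

    def test_c3_full_concat_branch_symmetric(self):
        """C=3 gives three 48-channel inputs with identical channel sets."""
        maps = [np.full((1, 16, 4, 4), i, dtype=float) for i in range(3)]
        fused = interleave_fuse(maps, 3)
        assert [f.shape[1] for f in fused] == [48, 48, 48]
        sets = [tuple(sorted(np.unique(f))) for f in fused]
        assert sets[0] == sets[1] == sets[2] == (0.0, 1.0, 2.0)

    def test_mismatched_spatial_sizes(self):
        maps = [np.zeros((1, 4, 5, 5)), np.zeros((1, 4, 4, 4)),
                np.zeros((1, 4, 5, 5))]
        with pytest.raises(FusionError, match="spatial"):
            interleave_fuse(maps, 2)

    def test_fusion_scheme_is_cyclic(self):
        assert fusion_groups(3, 2) == [(0, 1), (1, 2), (2, 0)]


class TestMifBlock:
    def test_reduced_block_output_channels(self):
        """Reduced topology, stage 1, k=3: block output 3 x 16 channels."""
        cfg = NetworkConfig(fusion_mode="reduced")
        frag = build_mif_block(1, cfg)
        out = frag.nodes[frag.output_id]
        assert out.kind == "concat"
        assert out.out_channels == 48
        convs3 = [n for n in frag.nodes
                  if n.kind == "conv" and n.kernel == 3]
        assert len(convs3) == 9  # 3 branches x 3 mini-blocks
        assert all(c.out_channels == 16 for c in convs3)

    def test_growth_block_channels_scale_with_fusion(self):
        """Growth topology: per-branch width multiplies by C per mini-block."""
        cfg = NetworkConfig(mini_blocks_per_stage=3)
        frag = build_mif_block(1, cfg)
        out = frag.nodes[frag.output_id]
        # final fused output: C * w * C^(k-1) = 2 * 16 * 4
        assert out.out_channels == 128

    def test_width_doubling_rule(self):
        """Per-stage widths double as the spatial size halves."""
        cfg = get_preset("mifnet22")
        for stage, w in ((1, 16), (2, 32), (3, 64)):
            frag = build_mif_block(stage, cfg)
            scale_in = [n for n in frag.nodes if n.kind == "conv"][0]
            assert scale_in.in_channels == w

    def test_bad_stage_index(self):
        with pytest.raises(ConfigurationError, match="stage_index"):
            build_mif_block(4, NetworkConfig())


class TestAssembledNetwork:
    @pytest.mark.parametrize("preset,depth", [("mifnet10", 10),
                                              ("mifnet22", 22),
                                              ("mifnet40", 40)])
    def test_depth_of_presets(self, preset, depth):
        assert get_preset(preset).nominal_depth == depth

    def test_forward_rows_sum_to_one(self):
        cfg = get_preset("mifnet10")
        net = Network(assemble_mifnet(cfg), seed=0, input_size=50)
        x = np.random.default_rng(0).random((3, 1, 50, 50))
        p = net.forward(x)
        assert p.shape == (3, 2)
        assert np.all(p >= 0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_classifier_gives_uniform_output(self):
        """All-zero image through a zeroed classifier -> (0.5, 0.5)."""
        cfg = get_preset("mifnet10")
        net = Network(assemble_mifnet(cfg), seed=0, input_size=50)
        from mifnet.nn.layers import Dense
        for m in net.modules:
            if isinstance(m, Dense):
                m.weight.value[...] = 0.0
        p = net.forward(np.zeros((1, 1, 50, 50)))
        np.testing.assert_allclose(p, [[0.5, 0.5]], atol=1e-12)

    def test_inference_is_deterministic(self):
        cfg = get_preset("mifnet10")
        net = Network(assemble_mifnet(cfg), seed=5, input_size=50)
        x = np.random.default_rng(2).random((2, 1, 50, 50))
        p1 = net.forward(x, train=False)
        p2 = net.forward(x, train=False)
        np.testing.assert_array_equal(p1, p2)

    def test_same_seed_same_weights(self):
        cfg = get_preset("mifnet10")
        a = Network(assemble_mifnet(cfg), seed=9, input_size=50)
        b = Network(assemble_mifnet(cfg), seed=9, input_size=50)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_wrong_spatial_size_rejected(self):
        from mifnet.nn.network import ShapeError
        cfg = get_preset("mifnet10")
        net = Network(assemble_mifnet(cfg), seed=0, input_size=50)
        with pytest.raises(ShapeError):
            net.forward(np.zeros((1, 1, 32, 32)))


class TestGroupConvEquivalence:
    def test_groups_one_matches_scipy_correlation(self):
        """A groups=1 conv equals plain cross-correlation (scipy oracle)."""
        rng = np.random.default_rng(0)
        conv = Conv2d(3, 5, kernel=3, stride=1, pad=1, groups=1, bias=True,
                      rng=rng)
        x = rng.random((2, 3, 8, 8))
        out = conv.forward([x], train=False)
        w = conv.weight.value
        expected = np.zeros_like(out)
        for n in range(2):
            for o in range(5):
                acc = np.zeros((8, 8))
                for c in range(3):
                    acc += correlate(x[n, c], w[o, c], mode="same",
                                     method="direct")
                expected[n, o] = acc + conv.bias.value[o]
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_grouped_equals_blockwise_standard(self):
        """A grouped conv equals independent standard convs per group."""
        rng = np.random.default_rng(1)
        g = Conv2d(4, 6, kernel=3, stride=1, pad=1, groups=2, bias=False,
                   rng=rng)
        x = rng.random((1, 4, 6, 6))
        out = g.forward([x], train=False)
        for gi in range(2):
            sub = Conv2d(2, 3, kernel=3, stride=1, pad=1, groups=1,
                         bias=False, rng=np.random.default_rng(0))
            sub.weight.value[...] = g.weight.value[gi * 3:(gi + 1) * 3]
            ref = sub.forward([x[:, gi * 2:(gi + 1) * 2]], train=False)
            np.testing.assert_allclose(out[:, gi * 3:(gi + 1) * 3], ref,
                                       atol=1e-10)


class TestShortcut:
    def test_zeroed_branch_passes_shortcut_signal(self):
        """Zeroing every conv weight makes the pre-ReLU block output equal
        the shortcut signal (identity skip soundness)."""
        cfg = NetworkConfig(mini_blocks_per_stage=1, fusion_mode="reduced")
        frag = build_mif_block(1, cfg)
        net = Network(frag, seed=0)
        for m in net.modules:
            if isinstance(m, Conv2d):
                m.weight.value[...] = 0.0
        x = np.random.default_rng(3).random((1, 16, 10, 10))
        out = net.forward(x, train=True)
        # block output concatenates the three branches; with zeroed convs and
        # BN(0)=0 each branch's add node passes ReLU(x + 0) = ReLU(x)
        expected = np.concatenate([np.maximum(x, 0)] * 3, axis=1)
        np.testing.assert_allclose(out, expected, atol=1e-12)
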