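"""Building blocks: DS conv oracle equivalence, attention, fusion inventory."""

import numpy as np
import pytest

import raman3d.nn.functional as F
from raman3d.errors import ConfigError, ShapeError
from raman3d.nn.autograd import Tensor
from raman3d.nn.layers import (
    ChannelAttention,
    Conv3d,
    DSConv3d,
    MultiScaleFusion,
    ResidualBlock,
)


def naive_ds_conv3d(x, dw, pw):
    """Brute-force nested-loop depthwise-then-pointwise oracle."""
    n, c_in, h, w, b = x.shape
    kh, kw, kb = dw.shape[1:]
    ph, pw_, pb = kh // 2, kw // 2, kb // 2
    xpad = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw_, pw_), (pb, pb)))
    depth = np.zeros_like(x)
    for nn in range(n):
        for c in range(c_in):
            for hh in range(h):
                for ww in range(w):
                    for bb in range(b):
                        acc = 0.0
                        for i in range(kh):
                            for j in range(kw):
                                for l in range(kb):
                                    acc += dw[c, i, j, l] * xpad[nn, c, hh + i, ww + j, bb + l]
                        depth[nn, c, hh, ww, bb] = acc
    c_out = pw.shape[0]
    out = np.zeros((n, c_out, h, w, b))
    for nn in range(n):
        for o in range(c_out):
            for c in range(c_in):
                out[nn, o] += pw[o, c] * depth[nn, c]
    return out


class TestDSConv:
    def test_identity_factorization(self):
        """Centered-delta depthwise kernels + identity pointwise = identity."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 3, 4, 5, 6)).astype(np.float32)
        dw = np.zeros((3, 3, 3, 3), dtype=np.float32)
        dw[:, 1, 1, 1] = 1.0
        pw = np.eye(3, dtype=np.float32)
        out = F.ds_conv3d(Tensor(x), Tensor(dw), Tensor(pw))
        np.testing.assert_allclose(out.data, x, atol=1e-6)

    @pytest.mark.parametrize("use_jit", [True, False])
    def test_matches_bruteforce_oracle(self, use_jit):
        """Random 2-channel 4×4×4 input against the naive-loop oracle."""
        prev = F.USE_JIT
        F.USE_JIT = use_jit
        try:
            rng = np.random.default_rng(3)
            x = rng.normal(size=(1, 2, 4, 4, 4))
            dw = rng.normal(size=(2, 3, 3, 3))
            pw = rng.normal(size=(3, 2))
            out = F.ds_conv3d(Tensor(x), Tensor(dw), Tensor(pw))
            expected = naive_ds_conv3d(x, dw, pw)
            assert np.max(np.abs(out.data - expected)) <= 1e-5
        finally:
            F.USE_JIT = prev

    def test_weight_count_factorization(self):
        """C_in=8, C_out=16, k=3: 8·27 + 8·16 = 344 vs 3456 standard."""
        layer = DSConv3d(8, 16, kernel=(3, 3, 3), rng=np.random.default_rng(0))
        assert layer.weight_count == 8 * 27 + 8 * 16 == 344
        assert DSConv3d.standard_weight_count(8, 16, (3, 3, 3)) == 3456

    def test_even_kernel_rejected(self):
        x = Tensor(np.zeros((1, 1, 4, 4, 4)))
        with pytest.raises(ShapeError):
            F.depthwise_conv3d(x, Tensor(np.zeros((1, 2, 2, 2))))


class TestResidualBlock:
    def test_zero_transform_passes_shortcut(self):
        block = ResidualBlock(2, 2, rng=np.random.default_rng(0))
        for _, p in block.named_parameters():
            if "bn.gamma" not in _ and "bn" not in _:
                p.data[...] = 0.0
        # zero conv weights -> transform output 0 -> out == identity shortcut
        block.transform.conv.depthwise.data[...] = 0.0
        block.transform.conv.pointwise.data[...] = 0.0
        block.transform.conv.bias.data[...] = 0.0
        x = np.random.default_rng(1).normal(size=(1, 2, 4, 4, 4)).astype(np.float32)
        out = block(Tensor(x))
        np.testing.assert_allclose(out.data, x, atol=1e-6)

    def test_matching_channels_no_projection(self):
        assert ResidualBlock(4, 4).shortcut is None
        assert ResidualBlock(4, 8).shortcut is not None

    def test_gradient_reaches_input(self):
        block = ResidualBlock(2, 2, rng=np.random.default_rng(5))
        x = Tensor(np.random.default_rng(2).normal(size=(1, 2, 2, 2, 2)).astype(np.float32),
                   requires_grad=True)
        loss = F.mean_all(F.square(block(x)))
        loss.backward()
        assert x.grad is not None and np.linalg.norm(x.grad) > 0


class TestChannelAttention:
    def test_identical_channels_equal_weights(self):
        """Channel symmetry: with channel-symmetric gate parameters,
        identical channels receive identical attention weights."""
        att = ChannelAttention(8, reduction=8, rng=np.random.default_rng(0))
        att.fc1.data[...] = att.fc1.data[:, :1]  # same weight for every channel
        att.fc2.data[...] = att.fc2.data[:1, :]
        att.b2.data[...] = 0.0
        x = np.tile(np.random.default_rng(1).normal(size=(1, 1, 2, 2, 2)), (1, 8, 1, 1, 1))
        weights = att.weights(Tensor(x.astype(np.float32))).data.ravel()
        np.testing.assert_allclose(weights, weights[0], rtol=1e-6)

    def test_gate_permutation_equivariance(self):
        """Permuting input channels and gate parameters together permutes
        the attention weights identically."""
        rng = np.random.default_rng(7)
        att = ChannelAttention(8, reduction=8, rng=np.random.default_rng(0))
        x = rng.normal(size=(1, 8, 2, 2, 2)).astype(np.float32)
        base = att.weights(Tensor(x)).data.ravel()
        perm = rng.permutation(8)
        att.fc1.data[...] = att.fc1.data[:, perm]
        att.fc2.data[...] = att.fc2.data[perm, :]
        att.b2.data[...] = att.b2.data[perm]
        permuted = att.weights(Tensor(x[:, perm])).data.ravel()
        np.testing.assert_allclose(permuted, base[perm], rtol=1e-5)

    def test_weights_strictly_in_unit_interval(self):
        att = ChannelAttention(8, reduction=8, rng=np.random.default_rng(2))
        x = np.random.default_rng(3).normal(size=(2, 8, 4, 4, 4)).astype(np.float32) * 100
        weights = att.weights(Tensor(x)).data
        assert np.all(weights > 0) and np.all(weights < 1)

    def test_matches_hand_rolled_oracle(self):
        att = ChannelAttention(2, reduction=1, rng=np.random.default_rng(4))
        x = np.random.default_rng(5).normal(size=(1, 2, 2, 2, 2))
        out = att(Tensor(x.astype(np.float64)))
        pooled = x.mean(axis=(2, 3, 4))[0]
        hidden = np.maximum(att.fc1.data @ pooled + att.b1.data, 0.0)
        gates = 1.0 / (1.0 + np.exp(-(att.fc2.data @ hidden + att.b2.data)))
        expected = x * gates.reshape(1, 2, 1, 1, 1)
        np.testing.assert_allclose(out.data, expected, atol=1e-6)

    def test_too_few_channels_rejected(self):
        with pytest.raises(ConfigError):
            ChannelAttention(4, reduction=8)


class TestMultiScaleFusion:
    def test_default_branch_inventory(self):
        """Two 3×3×1 + two 5×5×1 spatial; 1×1×3, 1×1×5, dilated 1×1×5 (rate 5),
        dilated 1×1×7 (rate 7) spectral branches."""
        fusion = MultiScaleFusion(8, rng=np.random.default_rng(0))
        inventory = fusion.branch_inventory()
        spatial = [(b["kernel"], b["dilation"]) for b in inventory if b["kind"] == "spatial"]
        spectral = [(b["kernel"][2], b["dilation"][2]) for b in inventory if b["kind"] == "spectral"]
        assert spatial == [((3, 3, 1), (1, 1, 1))] * 2 + [((5, 5, 1), (1, 1, 1))] * 2
        assert spectral == [(3, 1), (5, 1), (5, 5), (7, 7)]

    def test_dilation7_effective_span(self):
        """The dilated 1×1×7 branch spans (7−1)·7+1 = 43 spectral samples."""
        fusion = MultiScaleFusion(8, rng=np.random.default_rng(0))
        spans = [b["effective_span"][2] for b in fusion.branch_inventory()]
        assert max(spans) == (7 - 1) * 7 + 1 == 43

    def test_extent_and_width_preserved(self):
        fusion = MultiScaleFusion(8, rng=np.random.default_rng(1))
        x = np.random.default_rng(2).normal(size=(1, 8, 8, 8, 32)).astype(np.float32)
        assert fusion(Tensor(x)).shape == x.shape

    def test_indivisible_width_rejected(self):
        with pytest.raises(ConfigError):
            MultiScaleFusion(12)


class TestStandardConv:
    def test_dilated_spectral_conv_span_arithmetic(self):
        conv = Conv3d(1, 1, (1, 1, 7), dilation=(1, 1, 7))
        assert conv.effective_span == (1, 1, 43)
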