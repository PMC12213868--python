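"""Unit tests for the architectural blocks: contracts, edge cases, errors."""

import numpy as np
import pytest

from mixerseg.blocks import (
    CBGBlock,
    CEMHABlock,
    DecoderBlock,
    ECMBlock,
    ECNBlock,
    EncoderBlock,
    SEBlock,
    center_crop,
)
from mixerseg.exceptions import ConfigurationError, ShapeError


def test_cbg_zero_input_maps_to_zero(rng):
    """With zero bias and identity-affine inference BN, a zero map stays zero."""
    block = CBGBlock(1, 6, rng, dtype=np.float64)
    out = block(np.zeros((1, 8, 8, 1)), training=False)
    assert out.shape == (1, 8, 8, 6)
    np.testing.assert_array_equal(out, 0.0)


def test_cbg_shape_contract_under_same_padding(rng):
    block = CBGBlock(1, 16, rng)
    out = block(np.random.default_rng(0).normal(size=(3, 128, 128, 1)).astype(np.float32))
    assert out.shape == (3, 128, 128, 16)


def test_cbg_channel_mismatch_names_both_shapes(rng):
    block = CBGBlock(4, 8, rng)
    with pytest.raises(ShapeError, match=r"4 input channels.*\(2, 5, 5, 3\)"):
        block(np.zeros((2, 5, 5, 3)))


class TestSEBlock:
    def test_zero_input_yields_zero_output(self, rng):
        se = SEBlock(8, rng, dtype=np.float64)
        np.testing.assert_array_equal(se(np.zeros((2, 4, 4, 8))), 0.0)

    def test_zero_weights_halve_the_input(self, rng):
        """All-zero SE weights give sigmoid(0) = 0.5 gates exactly."""
        se = SEBlock(8, rng, dtype=np.float64)
        for p in se.params():
            p.value[...] = 0.0
        x = np.random.default_rng(3).normal(size=(2, 4, 4, 8))
        np.testing.assert_array_equal(se(x), 0.5 * x)

    def test_gates_strictly_inside_unit_interval(self, rng):
        se = SEBlock(8, rng)
        se(np.random.default_rng(4).normal(size=(3, 4, 4, 8)).astype(np.float32) * 10)
        gates = se.last_gates
        assert np.all(gates > 0.0) and np.all(gates < 1.0)

    def test_too_aggressive_reduction_is_a_config_error(self, rng):
        with pytest.raises(ConfigurationError, match="c/r < 1"):
            SEBlock(4, rng, reduction=8)


class TestECM:
    def test_zero_input_fixed_point(self, rng):
        ecm = ECMBlock(8, rng, dtype=np.float64)
        np.testing.assert_allclose(ecm(np.zeros((1, 4, 4, 8))), 0.0)

    def test_se_output_bounded_by_its_input(self, rng):
        """Sigmoid gates < 1 bound the pre-residual SE output elementwise."""
        ecm = ECMBlock(8, rng, dtype=np.float64)
        x = np.random.default_rng(5).normal(size=(1, 4, 4, 8))
        out = ecm(x)
        pre_residual = out - x
        # reconstruct O_IECM: the SE input equals pre_residual / gates
        gates = ecm.se.last_gates[:, None, None, :]
        o_iecm = pre_residual / gates
        assert np.all(np.abs(pre_residual) <= np.abs(o_iecm) + 1e-12)

    def test_residual_preserves_shape(self, rng):
        ecm = ECMBlock(16, rng)
        x = np.random.default_rng(6).normal(size=(2, 8, 8, 16)).astype(np.float32)
        assert ecm(x).shape == x.shape


class TestEncoderBlock:
    def test_constant_skip_pools_to_constant(self, rng):
        """Max pooling of a constant map returns the same constant."""
        enc = EncoderBlock(1, 8, rng, use_ecm=False, dtype=np.float64)
        down = enc.pool(np.full((1, 8, 8, 3), 0.3))
        np.testing.assert_array_equal(down, np.full((1, 4, 4, 3), 0.3))

    def test_halves_spatial_size_keeps_channels(self, rng):
        enc = EncoderBlock(1, 8, rng)
        skip, down = enc(np.zeros((1, 128, 128, 1), dtype=np.float32))
        assert skip.shape == (1, 128, 128, 8)
        assert down.shape == (1, 64, 64, 8)

    def test_odd_spatial_size_is_rejected(self, rng):
        enc = EncoderBlock(1, 8, rng)
        with pytest.raises(ShapeError, match="even"):
            enc(np.zeros((1, 7, 7, 1), dtype=np.float32))


class TestCEMHA:
    def test_single_token_attention_is_value_projection(self, rng):
        """With one token, softmax over one key is 1, so each head returns
        that token's value projection; the block output is the 1x1 projection
        of the concatenated heads plus the residual F."""
        block = CEMHABlock(4, 8, 2, rng, dtype=np.float64)
        x = np.random.default_rng(7).normal(size=(1, 1, 1, 4))
        out = block(x)
        f = block.cbg(x)
        values = (f.reshape(1, 1, 8) @ block.mha.wv.value).reshape(1, 1, 1, 8)
        expected = block.proj(values) + f
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_zero_query_weights_give_uniform_attention(self, rng):
        block = CEMHABlock(4, 8, 2, rng, dtype=np.float64)
        block.mha.wq.value[...] = 0.0
        block(np.random.default_rng(8).normal(size=(1, 4, 4, 4)))
        attn = block.last_attention
        np.testing.assert_allclose(attn, 1.0 / 16.0, atol=1e-12)

    def test_attention_rows_are_stochastic(self, rng):
        block = CEMHABlock(8, 16, 4, rng, dtype=np.float64)
        block(np.random.default_rng(9).normal(size=(2, 4, 4, 8)))
        np.testing.assert_allclose(block.last_attention.sum(axis=-1), 1.0, atol=1e-6)

    def test_indivisible_head_width_is_config_error(self, rng):
        with pytest.raises(ConfigurationError, match="divisible"):
            CEMHABlock(8, 10, 4, rng)

    def test_output_shape_matches_reduced_features(self, rng):
        block = CEMHABlock(16, 8, 4, rng)
        out = block(np.zeros((2, 4, 4, 16), dtype=np.float32))
        assert out.shape == (2, 4, 4, 8)


class TestECN:
    def test_zero_input_fixed_point(self, rng):
        ecn = ECNBlock(8, rng, dtype=np.float64)
        np.testing.assert_allclose(ecn(np.zeros((1, 4, 4, 8))), 0.0, atol=1e-12)

    def test_internal_channel_trace_with_expansion_four(self, rng):
        """For c=16 the widths run 16 -> 16 -> 16 -> (+x) 16 -> 64 -> 16 -> 16."""
        ecn = ECNBlock(16, rng)
        assert ecn.dw.weight.value.shape == (7, 7, 16)
        assert ecn.pw_in.weight.value.shape == (1, 1, 16, 16)
        assert ecn.pw_expand.weight.value.shape == (1, 1, 16, 64)
        assert ecn.pw_out.weight.value.shape == (1, 1, 64, 16)
        out = ecn(np.zeros((1, 8, 8, 16), dtype=np.float32))
        assert out.shape == (1, 8, 8, 16)

    def test_out_channels_override_for_decoder_fusion(self, rng):
        ecn = ECNBlock(16, rng, out_channels=8)
        assert ecn(np.zeros((1, 4, 4, 16), dtype=np.float32)).shape == (1, 4, 4, 8)


class TestDecoderBlock:
    def test_shape_arithmetic(self, rng):
        """Deep (1,4,4,256) + skip (1,8,8,128) -> concat 256ch -> out 128ch."""
        dec = DecoderBlock(256, 128, rng)
        x = np.zeros((1, 4, 4, 256), dtype=np.float32)
        skip = np.zeros((1, 8, 8, 128), dtype=np.float32)
        assert dec.forward(x, skip).shape == (1, 8, 8, 128)

    def test_center_crop_offset(self):
        x = np.arange(100, dtype=np.float64).reshape(1, 10, 10, 1)
        out = center_crop(x, 8, 8)
        np.testing.assert_array_equal(out, x[:, 1:9, 1:9, :])

    def test_center_crop_identity_when_sizes_match(self):
        x = np.random.default_rng(10).normal(size=(1, 6, 6, 2))
        out = center_crop(x, 6, 6)
        assert out.base is x or np.shares_memory(out, x)
        np.testing.assert_array_equal(out, x)

    def test_crop_cannot_enlarge(self):
        with pytest.raises(ShapeError, match="cannot crop"):
            center_crop(np.zeros((1, 4, 4, 1)), 8, 8)

    def test_backward_routes_gradients_to_both_inputs(self, rng):
        dec = DecoderBlock(16, 8, rng, dtype=np.float64)
        x = np.random.default_rng(11).normal(size=(1, 2, 2, 16))
        skip = np.random.default_rng(12).normal(size=(1, 4, 4, 8))
        out = dec.forward(x, skip)
        dx, dskip = dec.backward(np.ones_like(out))
        assert dx.shape == x.shape and dskip.shape == skip.shape
        assert np.any(dx != 0.0) and np.any(dskip != 0.0)


def test_blocks_preserve_batch_and_finiteness(rng):
    """Finite inputs map to finite outputs with the batch axis untouched."""
    x = np.random.default_rng(13).normal(size=(3, 8, 8, 8))
    for block in (
        CBGBlock(8, 8, rng, dtype=np.float64),
        ECMBlock(8, rng, dtype=np.float64),
        ECNBlock(8, rng, dtype=np.float64),
        SEBlock(8, rng, dtype=np.float64),
        CEMHABlock(8, 8, 2, rng, dtype=np.float64),
    ):
        out = block(x)
        assert out.shape[0] == 3
        assert np.all(np.isfinite(out))
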