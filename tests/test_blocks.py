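"""Building blocks: shape contracts, pass-through behavior, parameter
closed forms and determinism."""

import numpy as np
import pytest

from gpcyolo.nn import (C2f, ConvBNAct, GSConv, PConv, SimAM, SPPF,
                        Tensor, channel_shuffle, no_grad)
from gpcyolo.nn.layers import BatchNorm2d


@pytest.fixture
def rng():
    return np.random.default_rng(99)


def _x(rng, c, s=8, n=2):
    return Tensor(rng.normal(0, 1, (n, c, s, s)).astype(np.float32))


class TestParamClosedForms:
    """Module parameter counts equal hand-derived formulas."""

    @pytest.mark.parametrize("c1,c2,k,g", [(3, 16, 3, 1), (16, 32, 1, 1),
                                           (8, 8, 5, 8), (32, 64, 3, 1),
                                           (64, 64, 3, 2)])
    def test_conv_bn(self, rng, c1, c2, k, g):
        m = ConvBNAct(c1, c2, k, g=g, rng=rng)
        assert m.param_count() == k * k * (c1 // g) * c2 + 2 * c2

    @pytest.mark.parametrize("c1,c2,k", [(16, 32, 3), (32, 64, 3), (64, 64, 1),
                                         (128, 64, 1), (8, 16, 3)])
    def test_gsconv(self, rng, c1, c2, k):
        c_ = c2 // 2
        m = GSConv(c1, c2, k, rng=rng)
        expect = (k * k * c1 * c_ + 2 * c_) + (25 * c_ + 2 * c_)
        assert m.param_count() == expect

    def test_gsconv_32_to_64_matches_component_sum(self, rng):
        # SC half: 3*3*32*32 + 64 norm terms; DW half: 5*5*32 + 64
        m = GSConv(32, 64, 3, 2, rng=rng)
        assert m.param_count() == (9216 + 64) + (800 + 64)

    @pytest.mark.parametrize("c", [8, 16, 32, 64, 128])
    def test_pconv(self, rng, c):
        m = PConv(c, rng=rng)
        assert m.param_count() == 9 * (c // 4) ** 2

    @pytest.mark.parametrize("c1,c2,n,pc", [(32, 32, 1, False), (64, 64, 2, False),
                                            (128, 64, 1, True), (64, 128, 2, True),
                                            (96, 64, 3, True)])
    def test_c2f(self, rng, c1, c2, n, pc):
        c = c2 // 2
        m = C2f(c1, c2, n, pc=pc, rng=rng)
        expect = (c1 * 2 * c + 4 * c) + ((2 + n) * c * c2 + 2 * c2)
        expect += n * (2 * 9 * (c // 4) ** 2 if pc else 2 * (9 * c * c + 2 * c))
        assert m.param_count() == expect

    def test_c2f_pc_always_lighter_than_stock(self, rng):
        for c1, c2, n in [(64, 64, 2), (128, 128, 1), (96, 64, 3)]:
            stock = C2f(c1, c2, n, rng=np.random.default_rng(0))
            pc = C2f(c1, c2, n, pc=True, rng=np.random.default_rng(0))
            assert pc.param_count() < stock.param_count()


class TestForwardContracts:
    def test_gsconv_output_channels_and_stride(self, rng):
        m = GSConv(16, 32, 3, 2, rng=rng).eval()
        y = m(_x(rng, 16, 16))
        assert y.data.shape == (2, 32, 8, 8)

    def test_gsconv_rejects_wrong_channel_count(self, rng):
        m = GSConv(16, 32, 3, rng=rng).eval()
        with pytest.raises(ValueError, match="16"):
            m(_x(rng, 8))

    def test_channel_shuffle_is_a_permutation(self, rng):
        x = _x(rng, 8, 4)
        y = channel_shuffle(x, 2)
        assert sorted(x.data.ravel()) == sorted(y.data.ravel())
        # 2-group interleave: (0..3, 4..7) -> (0, 4, 1, 5, 2, 6, 3, 7)
        np.testing.assert_array_equal(
            y.data[:, 1], x.data[:, 4])

    def test_pconv_passes_untouched_channels_bit_identically(self, rng):
        m = PConv(16, rng=rng).eval()
        x = _x(rng, 16)
        y = m(x)
        assert y.data.shape == x.data.shape
        np.testing.assert_array_equal(y.data[:, 4:], x.data[:, 4:])

    def test_pconv_full_ratio_is_a_dense_conv(self, rng):
        m = PConv(8, ratio=1.0, rng=rng).eval()
        x = _x(rng, 8)
        ref = x.conv2d(m.weight, stride=1, padding=1)
        np.testing.assert_array_equal(m(x).data, ref.data)

    def test_pconv_rejects_indivisible_channels(self, rng):
        with pytest.raises(ValueError):
            PConv(6, ratio=0.25, rng=rng)

    def test_c2f_pc_is_a_drop_in_for_c2f(self, rng):
        x = _x(rng, 32)
        stock = C2f(32, 64, 2, rng=rng).eval()
        pc = C2f(32, 64, 2, pc=True, rng=rng).eval()
        assert stock(x).data.shape == pc(x).data.shape == (2, 64, 8, 8)

    def test_sppf_shape(self, rng):
        m = SPPF(64, 64, rng=rng).eval()
        assert m(_x(rng, 64)).data.shape == (2, 64, 8, 8)

    def test_forward_is_deterministic_in_eval_mode(self, rng):
        m = C2f(16, 32, 2, pc=True, rng=rng).eval()
        x = _x(rng, 16)
        with no_grad():
            a, b = m(x).data, m(x).data
        np.testing.assert_array_equal(a, b)


class TestSimAM:
    def test_contributes_zero_parameters(self):
        assert SimAM().param_count() == 0

    def test_preserves_shape_and_is_finite_on_constant_input(self):
        m = SimAM(lambda_reg=1e-4)
        x = Tensor(np.full((2, 3, 5, 5), 7.0, dtype=np.float32))
        y = m(x)
        assert y.data.shape == x.data.shape
        assert np.isfinite(y.data).all()
        # zero variance: energy = 0.5 everywhere -> weight sigmoid(0.5)
        np.testing.assert_allclose(
            y.data, 7.0 / (1 + np.exp(-0.5)), rtol=1e-5)

    def test_single_pixel_input_passes_through(self):
        x = Tensor(np.ones((1, 4, 1, 1), dtype=np.float32))
        assert SimAM()(x) is x

    def test_attention_emphasizes_outliers(self, rng):
        x = np.zeros((1, 1, 4, 4), dtype=np.float32)
        x[0, 0, 2, 2] = 5.0
        y = SimAM()(Tensor(x)).data
        w_out = y[0, 0, 2, 2] / 5.0
        assert 0.5 < w_out <= 1.0  # outlier kept with above-neutral weight

    def test_rejects_nonpositive_lambda(self):
        with pytest.raises(ValueError):
            SimAM(lambda_reg=0.0)


def test_batchnorm_eval_matches_single_calibration_batch(rng):
    """After one training pass, eval statistics reproduce that batch."""
    bn = BatchNorm2d(4)
    x = _x(rng, 4, 6, n=3)
    with no_grad():
        y_train = bn(x)          # training mode: batch statistics
        bn.eval()
        y_eval = bn(x)
    # eval uses the unbiased running variance, training the biased batch
    # variance, so agreement is up to the sqrt(n/(n-1)) factor
    np.testing.assert_allclose(y_train.data, y_eval.data, rtol=2e-2, atol=2e-2)


def test_block_flops_match_cost_law_oracles(rng):
    """Per-block profiled MACs agree with the closed-form cost laws."""
    from gpcyolo.flops import FlopsQuery, flops_pconv, flops_sc, flops_gsconv
    from gpcyolo.nn.layers import ACT_FLOPS_PER_ELEM, BN_FLOPS_PER_ELEM

    h = w = 20
    conv = ConvBNAct(16, 32, 3, rng=rng)
    f, _ = conv.flops(h, w)
    elems = 32 * h * w
    assert f - (BN_FLOPS_PER_ELEM + ACT_FLOPS_PER_ELEM) * elems \
        == 2 * flops_sc(FlopsQuery(w, h, 3, 3, 16, 32))

    pc = PConv(32, rng=rng)
    assert pc.flops(h, w)[0] == 2 * flops_pconv(
        FlopsQuery(w, h, 3, 3, 32, 32, Cp=8))

    # with the depthwise stage at the same kernel, GSConv matches its law
    gs = GSConv(16, 32, 3, rng=rng, dw_k=3)
    f, _ = gs.flops(h, w)
    assert f - (BN_FLOPS_PER_ELEM + ACT_FLOPS_PER_ELEM) * elems \
        == 2 * flops_gsconv(FlopsQuery(w, h, 3, 3, 16, 32))
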