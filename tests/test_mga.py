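"""Mask-guided attention algebra, variants and gradient flow."""

import numpy as np
import pytest

from mganet.autograd import Tensor
from mganet.mga import (ChannelMLP, MaskGuidedAttention, channel_attention,
                        mga_forward, mga_variant_forward, normalize_mask,
                        resize_mask, spatial_attention)


def const_mlp(value: float):
    """Stub channel gate returning a constant coefficient vector."""
    def mlp(pooled):
        return Tensor(np.full(pooled.shape, value)) + 0.0 * pooled
    return mlp


class TestResizeNormalize:
    def test_resize_identity_and_constant(self):
        m = np.random.default_rng(0).random((2, 1, 6, 6))
        np.testing.assert_allclose(resize_mask(Tensor(m), 6, 6).data, m)
        c = np.full((1, 1, 3, 3), 0.4)
        np.testing.assert_allclose(resize_mask(Tensor(c), 7, 9).data, 0.4)

    def test_resize_hand_evaluated_bilinear(self):
        m = Tensor(np.array([[0.0, 1.0], [0.0, 1.0]])[None, None])
        np.testing.assert_allclose(resize_mask(m, 2, 4).data[0, 0],
                                   [[0, 0.25, 0.75, 1]] * 2)

    def test_constant_mask_normalises_to_zero(self):
        out = normalize_mask(Tensor(np.full((1, 1, 4, 4), 3.0)))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_unit_range_input_is_near_identity(self):
        m = np.linspace(0, 1, 16).reshape(1, 1, 4, 4)
        out = normalize_mask(Tensor(m), eps=1e-6)
        assert np.abs(out.data - m).max() <= 1e-6

    def test_direct_formula(self):
        out = normalize_mask(Tensor(np.array([2.0, 4.0, 6.0]).reshape(1, 3)), eps=1e-6)
        np.testing.assert_allclose(out.data[0], [0.0, 2 / (4 + 1e-6), 4 / (4 + 1e-6)])

    def test_range_invariant_on_extreme_inputs(self):
        rng = np.random.default_rng(1)
        for arr in (rng.normal(0, 1e8, (1, 1, 5, 5)),
                    np.full((1, 1, 5, 5), -7.0),
                    np.zeros((1, 1, 5, 5))):
            out = normalize_mask(Tensor(arr)).data
            assert np.isfinite(out).all() and out.min() >= 0 and out.max() < 1


class TestBranches:
    def test_spatial_identity_and_annihilator(self):
        F = Tensor(np.random.default_rng(2).random((2, 3, 4, 4)))
        np.testing.assert_allclose(
            spatial_attention(F, Tensor(np.ones((2, 1, 4, 4)))).data, F.data)
        np.testing.assert_array_equal(
            spatial_attention(F, Tensor(np.zeros((2, 1, 4, 4)))).data, 0.0)

    def test_spatial_elementwise_fixture(self):
        F = Tensor(np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(1, 1, 2, 2))
        m = Tensor(np.array([[0.0, 1.0], [0.5, 1.0]]).reshape(1, 1, 2, 2))
        np.testing.assert_allclose(spatial_attention(F, m).data[0, 0],
                                   [[0.0, 2.0], [1.5, 4.0]])

    def test_spatial_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            spatial_attention(Tensor(np.zeros((1, 2, 4, 4))),
                              Tensor(np.zeros((1, 1, 3, 3))))

    def test_channel_identity_with_unit_stub(self):
        F = Tensor(np.random.default_rng(3).random((2, 4, 3, 3)))
        m = Tensor(np.random.default_rng(4).random((2, 1, 3, 3)))
        out = channel_attention(F, m, const_mlp(1.0))
        np.testing.assert_allclose(out.data, F.data)

    def test_zero_weight_mlp_gives_half_scaling(self):
        # sigmoid(0) = 0.5: an all-zero MLP scales every channel by half
        rng = np.random.default_rng(5)
        F = Tensor(rng.random((1, 8, 4, 4)))
        mlp = ChannelMLP(8, reduction=2, rng=rng)
        for p in mlp.parameters():
            p.data[...] = 0.0
        out = channel_attention(F, Tensor(np.zeros((1, 1, 4, 4))), mlp)
        np.testing.assert_allclose(out.data, 0.5 * F.data)

    def test_masked_gap_matches_bruteforce(self):
        rng = np.random.default_rng(6)
        F = rng.random((2, 3, 5, 5))
        m = rng.random((2, 1, 5, 5))
        seen = {}

        def capture(pooled):
            seen["gap"] = pooled.data.copy()
            return Tensor(np.ones(pooled.shape)) + 0.0 * pooled

        channel_attention(Tensor(F), Tensor(m), capture)
        expect = np.zeros((2, 3))
        for b in range(2):
            for c in range(3):
                acc = 0.0
                for i in range(5):
                    for j in range(5):
                        acc += F[b, c, i, j] * m[b, 0, i, j]
                expect[b, c] = acc / 25.0
        np.testing.assert_allclose(seen["gap"], expect)


class TestFusion:
    def setup_method(self):
        rng = np.random.default_rng(7)
        self.F = Tensor(rng.random((2, 3, 4, 4)))
        self.mask = Tensor(rng.random((2, 1, 8, 8)))

    def test_zero_stubs_reduce_to_identity(self):
        const = Tensor(np.full((2, 1, 8, 8), 0.3))  # normalises to all zeros
        out = mga_forward(self.F, const, const_mlp(0.0))
        np.testing.assert_allclose(out.data, self.F.data)

    def test_unit_mask_unit_mlp_triples_features(self):
        # with mask_norm == 1 everywhere and a unit channel gate both
        # branches return F, so the parallel fusion is exactly 3F
        ones = Tensor(np.ones((2, 1, 4, 4)))
        F_s = spatial_attention(self.F, ones)
        F_c = channel_attention(self.F, ones, const_mlp(1.0))
        np.testing.assert_allclose((F_s + F_c + self.F).data, 3 * self.F.data)

    def test_variant_closed_forms_with_stubs(self):
        ones = Tensor(np.ones((2, 1, 4, 4)))
        # spatial_only with mask_norm == 1: F' = 2F
        F_s = spatial_attention(self.F, ones) + self.F
        np.testing.assert_allclose(F_s.data, 2 * self.F.data)
        # channel_only with unit stub: F' = 2F
        F_c = channel_attention(self.F, ones, const_mlp(1.0)) + self.F
        np.testing.assert_allclose(F_c.data, 2 * self.F.data)

    def test_none_variant_is_passthrough(self):
        out = mga_variant_forward(self.F, self.mask, const_mlp(1.0), "none")
        np.testing.assert_array_equal(out.data, self.F.data)

    def test_serial_differs_from_parallel_on_nonconstant_mask(self):
        rng = np.random.default_rng(8)
        mlp = ChannelMLP(3, reduction=1, rng=rng)
        par = mga_variant_forward(self.F, self.mask, mlp, "parallel")
        ser = mga_variant_forward(self.F, self.mask, mlp, "serial")
        assert np.abs(par.data - ser.data).max() > 1e-8

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            mga_variant_forward(self.F, self.mask, const_mlp(1.0), "cbam")

    @pytest.mark.parametrize("c,h,w", [(1, 2, 3), (4, 8, 8), (8, 5, 7)])
    def test_output_shape_contract(self, c, h, w):
        rng = np.random.default_rng(9)
        F = Tensor(rng.random((2, c, h, w)))
        mask = Tensor(rng.random((2, 1, 16, 16)))
        mlp = ChannelMLP(c, rng=rng)
        assert mga_forward(F, mask, mlp).shape == F.shape

    def test_spatial_branch_monotone_in_mask(self):
        F = Tensor(np.abs(np.random.default_rng(10).random((1, 2, 3, 3))))
        lo = np.full((1, 1, 3, 3), 0.2)
        hi = lo.copy()
        hi[0, 0, 1, 1] = 0.9
        out_lo = spatial_attention(F, Tensor(lo)).data
        out_hi = spatial_attention(F, Tensor(hi)).data
        assert (np.abs(out_hi[:, :, 1, 1]) >= np.abs(out_lo[:, :, 1, 1])).all()


class TestGradientFlow:
    def test_autodiff_matches_finite_differences_through_mask_path(self):
        """The mask input is never detached: d loss / d mask must agree with
        central finite differences to 1e-4 relative error."""
        rng = np.random.default_rng(11)
        F = Tensor(rng.random((1, 2, 4, 4)))
        mlp = ChannelMLP(2, reduction=1, rng=rng)
        mask0 = rng.random((1, 1, 6, 6))  # distinct values: unique min/max

        def loss_of(mask_arr, track=False):
            m = Tensor(mask_arr, requires_grad=track)
            loss = (mga_forward(F, m, mlp) ** 2).sum()
            return m, loss

        m, loss = loss_of(mask0.copy(), track=True)
        loss.backward()
        num = np.zeros_like(mask0)
        eps = 1e-6
        it = np.nditer(mask0, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            up, dn = mask0.copy(), mask0.copy()
            up[i] += eps
            dn[i] -= eps
            num[i] = (loss_of(up)[1].data - loss_of(dn)[1].data) / (2 * eps)
        rel = np.abs(m.grad - num).max() / np.abs(num).max()
        assert rel < 1e-4

    def test_module_forward_matches_functional(self):
        rng = np.random.default_rng(12)
        F = Tensor(rng.random((2, 4, 5, 5)))
        mask = Tensor(rng.random((2, 1, 10, 10)))
        mod = MaskGuidedAttention(4, reduction=2, variant="parallel",
                                  rng=np.random.default_rng(13))
        out = mod(F, mask)
        ref = mga_variant_forward(F, mask, mod.mlp, "parallel")
        np.testing.assert_allclose(out.data, ref.data)
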