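"""Gated fusion, role branches, and the pair decoder."""

import numpy as np
import pytest

import tdagene._autodiff as ad
from tdagene._autodiff import Tensor
from tdagene.fusion import (
    BranchMLP,
    FusionConfig,
    FusionHead,
    GatedFusion,
    PairDecoder,
    broadcast_tda,
)
from tdagene.tda import TDAFeatures


class TestBroadcast:
    def test_degenerate_features_zero_matrix(self):
        t = TDAFeatures(0.0, 0, 0.0, 0.0)
        out = broadcast_tda(t, 3)
        np.testing.assert_array_equal(out, np.zeros((3, 4)))

    def test_all_rows_identical(self):
        t = TDAFeatures(0.15, 7, 0.2, 0.75)
        out = broadcast_tda(t, 5)
        assert out.shape == (5, 4)
        assert (out == out[0]).all()

    def test_raw_mode_matches_triangle_example(self):
        t = TDAFeatures(0.15, 1, 0.2, 0.75)
        out = broadcast_tda(t, 2, standardize=False)
        np.testing.assert_allclose(out, [[0.15, 1, 0.2, 0.75]] * 2)

    def test_standardization_compresses_cycles(self):
        cfg = FusionConfig()
        t = TDAFeatures(0.5, 100, 1.0, 0.5)
        out = broadcast_tda(t, 1, cfg)
        assert out[0, 1] == pytest.approx(np.log1p(100) / cfg.tda_channel_scale[1])


class TestGatedFusion:
    def _setup(self, gate=True):
        rng = np.random.default_rng(0)
        fusion = GatedFusion(6, FusionConfig(), rng, gate=gate)
        h = Tensor(np.random.default_rng(1).standard_normal((4, 6)))
        t = np.random.default_rng(2).random((4, 4))
        return fusion, h, t

    def test_zero_gate_params_give_half_gate(self):
        fusion, h, t = self._setup()
        fusion.gate.W.data[:] = 0.0
        fusion.gate.b.data[:] = 0.0
        c = np.hstack([h.data, t])
        # before the projection, f must equal 0.5 * c
        g = ad.sigmoid(fusion.gate(ad.concat([h, Tensor(t)], axis=1)))
        np.testing.assert_allclose((g * ad.concat([h, Tensor(t)], axis=1)).data,
                                   0.5 * c, atol=1e-12)

    def test_large_bias_saturates_gate_open(self):
        fusion, h, t = self._setup()
        fusion.gate.W.data[:] = 0.0
        fusion.gate.b.data[:] = 20.0
        c = ad.concat([h, Tensor(t)], axis=1)
        g = ad.sigmoid(fusion.gate(c))
        np.testing.assert_allclose((g * c).data, c.data, atol=1e-8)

    def test_gate_strictly_in_unit_interval(self):
        fusion, h, t = self._setup()
        g = ad.sigmoid(fusion.gate(ad.concat([h, Tensor(t)], axis=1)))
        assert (g.data > 0).all() and (g.data < 1).all()

    def test_zero_tda_channels_nullified(self):
        """With an all-zero topology vector the gated product's last 4
        channels vanish, so the fusion depends on h alone."""
        fusion, h, _ = self._setup()
        t0 = np.zeros((4, 4))
        c = ad.concat([h, Tensor(t0)], axis=1)
        f = ad.sigmoid(fusion.gate(c)) * c
        np.testing.assert_array_equal(f.data[:, -4:], 0.0)

    def test_fused_output_finite_and_shape(self):
        fusion, h, t = self._setup()
        out = fusion.fuse(h, t)
        assert out.data.shape == (4, 6)
        assert np.isfinite(out.data).all()


class TestBranches:
    def test_output_width_default(self):
        rng = np.random.default_rng(3)
        branch = BranchMLP(12, FusionConfig(), rng)
        out = branch(Tensor(np.random.default_rng(4).standard_normal((5, 12))))
        assert out.data.shape == (5, 16)

    def test_independent_branches_differ(self):
        rng = np.random.default_rng(5)
        cfg = FusionConfig()
        tf_b = BranchMLP(8, cfg, rng)
        tg_b = BranchMLP(8, cfg, rng)
        f = Tensor(np.random.default_rng(6).standard_normal((4, 8)))
        assert not np.allclose(tf_b(f).data, tg_b(f).data)

    def test_branch_gradient_check(self):
        rng = np.random.default_rng(7)
        branch = BranchMLP(5, FusionConfig(branch_out_dim=3), rng)
        x = np.random.default_rng(8).standard_normal((4, 5))
        w = np.random.default_rng(9).standard_normal((4, 3))

        def loss():
            return (branch(Tensor(x)) * Tensor(w)).sum()

        L = loss()
        for p in branch.params():
            p.grad = None
        L.backward()
        eps = 1e-6
        rng_sel = np.random.default_rng(10)
        for p in branch.params():
            flat = list(np.ndindex(p.data.shape))
            sel = flat if len(flat) <= 4 else \
                [flat[i] for i in rng_sel.choice(len(flat), 4, replace=False)]
            for ix in sel:
                orig = p.data[ix]
                p.data[ix] = orig + eps
                lp = loss().item()
                p.data[ix] = orig - eps
                lm = loss().item()
                p.data[ix] = orig
                assert p.grad[ix] == pytest.approx((lp - lm) / (2 * eps),
                                                   rel=1e-4, abs=1e-7)


class TestDecoder:
    def test_zero_weights_give_half_scores(self):
        rng = np.random.default_rng(11)
        dec = PairDecoder(4, FusionConfig(), rng)
        for lin in (dec.l1, dec.l2, dec.l3):
            lin.W.data[:] = 0.0
            lin.b.data[:] = 0.0
        u = Tensor(np.random.default_rng(12).standard_normal((6, 4)))
        v = Tensor(np.random.default_rng(13).standard_normal((6, 4)))
        np.testing.assert_allclose(dec(u, v).data, 0.5, atol=1e-12)

    def test_scores_in_open_unit_interval(self):
        rng = np.random.default_rng(14)
        dec = PairDecoder(4, FusionConfig(), rng)
        u = Tensor(np.random.default_rng(15).standard_normal((10, 4)))
        v = Tensor(np.random.default_rng(16).standard_normal((10, 4)))
        s = dec(u, v).data
        assert ((s > 0) & (s < 1)).all() and np.isfinite(s).all()

    def test_asymmetry_of_pair_order(self):
        """score(i,j) != score(j,i) in general: the two halves play
        different roles."""
        rng = np.random.default_rng(17)
        head = FusionHead(6, FusionConfig(branch_out_dim=4), rng)
        h = Tensor(np.random.default_rng(18).standard_normal((5, 6)))
        t = np.random.default_rng(19).random((5, 4))
        e_tf, e_tg = head.embed(h, t)
        fwd = head.decode_pairs(e_tf, e_tg, np.array([[0, 1]])).data
        rev = head.decode_pairs(e_tf, e_tg, np.array([[1, 0]])).data
        assert fwd[0] != pytest.approx(rev[0], abs=1e-9)


class TestVariants:
    def _h_t(self):
        h = Tensor(np.random.default_rng(20).standard_normal((5, 6)))
        t = np.random.default_rng(21).random((5, 4))
        return h, t

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            FusionHead(6, FusionConfig(), np.random.default_rng(0),
                       variant="bogus")

    def test_no_tda_ignores_topology(self):
        head = FusionHead(6, FusionConfig(), np.random.default_rng(22),
                          variant="no_tda")
        h, t = self._h_t()
        a = head.embed(h, t)
        b = head.embed(h, np.ones_like(t) * 9.9)
        np.testing.assert_array_equal(a[0].data, b[0].data)

    def test_no_fusion_drops_gate(self):
        head = FusionHead(6, FusionConfig(), np.random.default_rng(23),
                          variant="no_fusion")
        assert head.fusion.gate is None
        h, t = self._h_t()
        e_tf, e_tg = head.embed(h, t)
        assert e_tf.data.shape == (5, 16)

    def test_no_branch_shares_parameters(self):
        head = FusionHead(6, FusionConfig(), np.random.default_rng(24),
                          variant="no_branch")
        assert head.target_branch is head.tf_branch
        h, t = self._h_t()
        e_tf, e_tg = head.embed(h, t)
        np.testing.assert_array_equal(e_tf.data, e_tg.data)

    def test_full_head_deterministic_in_eval(self):
        head = FusionHead(6, FusionConfig(), np.random.default_rng(25))
        h, t = self._h_t()
        pairs = np.array([[0, 1], [2, 3]])
        a = head.decode_pairs(*head.embed(h, t), pairs).data
        b = head.decode_pairs(*head.embed(h, t), pairs).data
        np.testing.assert_array_equal(a, b)
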