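"""Architecture tests: shapes, hand-computed SSM recurrences, gradient
checks, attention-pool properties, DAFM algebra and ablation routing."""

import numpy as np
import pytest

from tfrim_sad.network import (
    CBAM, AttentionPool, DualStreamNet, MultiBranchBlock, NetworkConfig,
    positional_grid,
)
from tfrim_sad.nn import Tensor, selective_scan, ssm_discretize
from tfrim_sad.nn.layers import Conv1d, Conv2d, LayerNorm
from tfrim_sad.train_eval import bce_loss

SMALL = NetworkConfig.small()


class TestPositionalGrid:
    def test_corners_and_monotonicity(self):
        g = positional_grid(24, 48)
        assert g.shape == (2, 24, 48)
        assert g[0, 0, 0] == 0.0 and g[1, 0, 0] == 0.0
        assert g[0, -1, -1] == 1.0 and g[1, -1, -1] == 1.0
        assert np.all(np.diff(g[0], axis=0) >= 0)
        assert np.all(np.diff(g[1], axis=1) >= 0)

    def test_single_row_is_zero(self):
        assert np.all(positional_grid(1, 5)[0] == 0.0)


class TestMultiBranchBlock:
    def test_output_channels_are_four_times_width(self, rng):
        block = MultiBranchBlock(6, 5, np.random.default_rng(0))
        out = block(Tensor(rng.normal(size=(2, 6, 8, 9))))
        assert out.shape == (2, 20, 8, 9)  # 4 paths x width, spatial preserved

    def test_zero_input_zero_biases_gives_zero(self):
        block = MultiBranchBlock(4, 3, np.random.default_rng(0))
        out = block(Tensor(np.zeros((1, 4, 6, 6))))
        assert np.allclose(out.data, 0.0)

    def test_undersized_input_rejected(self, rng):
        block = MultiBranchBlock(4, 3, np.random.default_rng(0))
        with pytest.raises(ValueError):
            block(Tensor(rng.normal(size=(1, 4, 2, 2))))

    def test_gradient_reaches_input_through_residual(self, rng):
        """Zero-scale the four branch paths; the residual still propagates."""
        block = MultiBranchBlock(4, 3, np.random.default_rng(0))
        for conv in (block.pool_proj, block.conv31, block.conv13, block.conv33,
                     block.conv11):
            conv.weight.data[:] = 0.0
            conv.bias.data[:] = 0.0
        x = Tensor(rng.normal(size=(1, 4, 6, 6)), requires_grad=True)
        block(x).sum().backward()
        assert x.grad is not None and np.any(x.grad != 0.0)


class TestSSM:
    def test_discretize_scalar_closed_form(self):
        abar, bbar = ssm_discretize(np.array(-1.0), np.array(1.0), np.array(0.1))
        assert abar == pytest.approx(0.904837, abs=1e-6)
        assert bbar == pytest.approx(0.095163, abs=1e-6)

    def test_discretize_zoh_limit_small_delta(self):
        abar, bbar = ssm_discretize(np.array(-2.0), np.array(3.0), np.array(1e-8))
        assert abar == pytest.approx(1.0, abs=1e-7)
        assert bbar == pytest.approx(3e-8, rel=1e-4)

    def test_discretize_removable_singularity(self):
        abar, bbar = ssm_discretize(np.array(0.0), np.array(2.0), np.array(0.5))
        assert abar == 1.0 and bbar == pytest.approx(1.0)

    def test_scan_hand_computed_three_steps(self):
        """a=-1, delta=0.1, b=c=1, Dskip=0, inputs (1,0,0): h decays by
        exp(-0.1) after the first injection of bbar=0.095163."""
        x = Tensor(np.array([[[1.0], [0.0], [0.0]]]))          # (1, 3, 1)
        delta = Tensor(np.full((1, 3, 1), 0.1))
        b = Tensor(np.ones((1, 3, 1)))
        c = Tensor(np.ones((1, 3, 1)))
        A = Tensor(np.array([[-1.0]]))
        d_skip = Tensor(np.zeros(1))
        y = selective_scan(x, delta, b, c, A, d_skip).data[0, :, 0]
        np.testing.assert_allclose(y, [0.0951626, 0.0861067, 0.0779125], atol=1e-6)

    def test_scan_zero_input_zero_output(self):
        x = Tensor(np.zeros((2, 5, 3)))
        y = selective_scan(x, Tensor(np.full((2, 5, 3), 0.2)),
                           Tensor(np.ones((2, 5, 4))), Tensor(np.ones((2, 5, 4))),
                           Tensor(-np.ones((3, 4))), Tensor(np.zeros(3)))
        assert np.allclose(y.data, 0.0)

    def test_scan_matches_naive_loop(self, rng):
        """Vectorised scan vs an independent step-by-step recurrence on
        random length-32 sequences (100 instances)."""
        for _ in range(100):
            B, L, D, N = 1, 32, 3, 2
            x = rng.normal(size=(B, L, D))
            delta = rng.uniform(0.01, 0.5, size=(B, L, D))
            b = rng.normal(size=(B, L, N))
            c = rng.normal(size=(B, L, N))
            A = -rng.uniform(0.1, 2.0, size=(D, N))
            dsk = rng.normal(size=D)
            y = selective_scan(Tensor(x), Tensor(delta), Tensor(b), Tensor(c),
                               Tensor(A), Tensor(dsk)).data
            # naive oracle
            y_ref = np.zeros((B, L, D))
            for bi in range(B):
                h = np.zeros((D, N))
                for t in range(L):
                    for d in range(D):
                        abar = np.exp(delta[bi, t, d] * A[d])
                        bbar = (abar - 1.0) / A[d] * b[bi, t]
                        h[d] = abar * h[d] + bbar * x[bi, t, d]
                        y_ref[bi, t, d] = c[bi, t] @ h[d] + dsk[d] * x[bi, t, d]
            assert np.max(np.abs(y - y_ref)) < 1e-5

    def test_scan_gradients_match_finite_differences(self, rng):
        """Analytic BPTT vs central differences on a tiny instance
        (D=4, N=2, L=8), 1e-3 relative tolerance."""
        B, L, D, N = 2, 8, 4, 2
        arrays = {
            "x": rng.normal(size=(B, L, D)),
            "delta": rng.uniform(0.05, 0.4, size=(B, L, D)),
            "b": rng.normal(size=(B, L, N)),
            "c": rng.normal(size=(B, L, N)),
            "A": -rng.uniform(0.2, 2.0, size=(D, N)),
            "d_skip": rng.normal(size=D),
        }
        w = rng.normal(size=(B, L, D))  # fixed projection for a scalar loss

        def run(vals):
            tensors = {k: Tensor(v, requires_grad=True) for k, v in vals.items()}
            y = selective_scan(tensors["x"], tensors["delta"], tensors["b"],
                               tensors["c"], tensors["A"], tensors["d_skip"])
            return (y * Tensor(w)).sum(), tensors

        loss, tensors = run(arrays)
        loss.backward()
        fd_rng = np.random.default_rng(5)
        for name, arr in arrays.items():
            grad = tensors[name].grad
            for _ in range(4):
                i = fd_rng.integers(arr.size)
                eps = 1e-6
                for sign in (+1, -1):
                    pert = {k: v.copy() for k, v in arrays.items()}
                    pert[name].ravel()[i] += sign * eps
                    if sign > 0:
                        up = float(run(pert)[0].data)
                    else:
                        down = float(run(pert)[0].data)
                fd = (up - down) / (2 * eps)
                assert fd == pytest.approx(grad.ravel()[i], rel=1e-3, abs=1e-7)


class TestAttentionPool:
    def test_constant_sequence_is_fixed_point(self, rng):
        pool = AttentionPool(6, np.random.default_rng(0))
        const = rng.normal(size=6)
        z = Tensor(np.tile(const, (2, 7, 1)))
        np.testing.assert_allclose(pool(z).data, np.tile(const, (2, 1)), atol=1e-12)

    def test_zero_scores_give_uniform_mean(self, rng):
        pool = AttentionPool(6, np.random.default_rng(0))
        pool.score.weight.data[:] = 0.0
        z = rng.normal(size=(3, 5, 6))
        np.testing.assert_allclose(pool(Tensor(z)).data, z.mean(axis=1), atol=1e-12)

    def test_weights_normalised(self, rng):
        pool = AttentionPool(6, np.random.default_rng(1))
        for _ in range(100):
            alpha = pool.weights(Tensor(rng.normal(size=(2, 9, 6)))).data
            assert np.all(alpha >= 0)
            np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-6)


class TestDAFM:
    def _net(self):
        return DualStreamNet(NetworkConfig.small(use_time=False), seed=0).eval()

    def test_identity_at_initialisation(self, rng):
        net = self._net()
        x = Tensor(rng.normal(size=(3, net.cfg.fused_dim)))
        d = Tensor(rng.normal(size=(3, 4)))
        np.testing.assert_allclose(net.dafm(x, d).data, x.data, atol=1e-12)

    def test_affine_in_fused_features_for_fixed_demographics(self, rng):
        net = self._net()
        net.demo_net.out.weight.data[:] = rng.normal(size=net.demo_net.out.weight.shape)
        d = Tensor(rng.normal(size=(2, 4)))
        x1 = Tensor(rng.normal(size=(2, net.cfg.fused_dim)))
        x2 = Tensor(rng.normal(size=(2, net.cfg.fused_dim)))
        zero = Tensor(np.zeros((2, net.cfg.fused_dim)))
        lhs = net.dafm(x1 + x2, d).data + net.dafm(zero, d).data
        rhs = net.dafm(x1, d).data + net.dafm(x2, d).data
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_modulation_dimensions(self):
        net = DualStreamNet(NetworkConfig(), seed=0)
        assert net.demo_net.out.bias.shape == (512,)  # split into 256 + 256
        assert net.cfg.fused_dim == 256


class TestForward:
    def test_probabilities_shape_and_range(self, rng):
        net = DualStreamNet(SMALL, seed=0).eval()
        out = net(tfrim=rng.normal(size=(2, 2, 24, 48)),
                  wave=rng.normal(size=(2, 2, 9120)),
                  demo=rng.normal(size=(2, 4)))
        assert out.shape == (2, 3)
        assert np.all(out.data > 0.0) and np.all(out.data < 1.0)

    def test_eval_mode_deterministic(self, rng):
        net = DualStreamNet(SMALL, seed=0).eval()
        args = dict(tfrim=rng.normal(size=(1, 2, 24, 48)),
                    wave=rng.normal(size=(1, 2, 9120)),
                    demo=rng.normal(size=(1, 4)))
        np.testing.assert_array_equal(net(**args).data, net(**args).data)

    def test_identical_seed_identical_initialisation(self):
        a = DualStreamNet(SMALL, seed=3)
        b = DualStreamNet(SMALL, seed=3)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_channel_swap_changes_tfrim_features(self, rng):
        net = DualStreamNet(SMALL, seed=0).eval()
        x = rng.normal(size=(1, 2, 24, 48))
        a = net.tfrim_enc(Tensor(x)).data
        b = net.tfrim_enc(Tensor(x[:, ::-1].copy())).data
        assert not np.allclose(a, b)

    def test_time_column_shuffle_changes_tfrim_features(self, rng):
        """Positional encoding breaks translation invariance."""
        net = DualStreamNet(SMALL, seed=0).eval()
        x = rng.normal(size=(1, 2, 24, 48))
        perm = np.random.default_rng(1).permutation(48)
        a = net.tfrim_enc(Tensor(x)).data
        b = net.tfrim_enc(Tensor(x[:, :, :, perm].copy())).data
        assert not np.allclose(a, b)

    def test_temporal_frontend_length(self):
        net = DualStreamNet(NetworkConfig(), seed=0).eval()
        x = Tensor(np.random.default_rng(0).normal(size=(1, 2, 9120)))
        f_local = net.time_enc.frontend(x)
        assert f_local.shape == (1, 64, 1140)  # 9120 / 2^3

    def test_wrong_waveform_length_rejected(self, rng):
        net = DualStreamNet(SMALL, seed=0).eval()
        with pytest.raises(ValueError):
            net(tfrim=rng.normal(size=(1, 2, 24, 48)),
                wave=rng.normal(size=(1, 2, 5000)), demo=rng.normal(size=(1, 4)))

    def test_demographics_only_ablation(self, rng):
        net = DualStreamNet(NetworkConfig.small(use_tfrim=False, use_time=False),
                            seed=0).eval()
        out = net(demo=rng.normal(size=(4, 4)))
        assert out.shape == (4, 3)

    def test_dual_branch_without_demographics_bypasses_modulation(self, rng):
        net = DualStreamNet(NetworkConfig.small(use_demo=False), seed=0).eval()
        out = net(tfrim=rng.normal(size=(1, 2, 24, 48)),
                  wave=rng.normal(size=(1, 2, 9120)))
        assert out.shape == (1, 3)
        assert net.demo_net is None

    def test_no_branches_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(use_tfrim=False, use_time=False, use_demo=False)

    @pytest.mark.parametrize("fusion", ["concat", "gating", "additive"])
    def test_alternative_fusion_heads(self, fusion, rng):
        net = DualStreamNet(NetworkConfig.small(fusion=fusion), seed=0).eval()
        out = net(tfrim=rng.normal(size=(1, 2, 24, 48)),
                  wave=rng.normal(size=(1, 2, 9120)), demo=rng.normal(size=(1, 4)))
        assert out.shape == (1, 3)


class TestLayerGradients:
    """Finite-difference checks for the custom conv/normalisation ops."""

    @pytest.mark.parametrize("make,shape", [
        (lambda: Conv1d(2, 3, 5, stride=2, rng=np.random.default_rng(0)), (2, 2, 17)),
        (lambda: Conv2d(2, 3, 3, rng=np.random.default_rng(0)), (2, 2, 6, 7)),
        (lambda: LayerNorm(5), (2, 4, 5)),
        (lambda: CBAM(4, 2, np.random.default_rng(0)), (2, 4, 7, 7)),
    ])
    def test_parameter_gradients(self, make, shape, rng):
        mod = make()
        x = rng.normal(size=shape)
        w = rng.normal(size=shape[:1])  # avoid symmetric loss

        def loss():
            out = mod(Tensor(x))
            return (out * out).sum() * 0.5

        val = loss()
        val.backward()
        fd_rng = np.random.default_rng(2)
        for p in mod.parameters():
            for _ in range(3):
                i = fd_rng.integers(p.data.size)
                eps = 1e-6
                orig = p.data.ravel()[i]
                p.data.ravel()[i] = orig + eps
                up = float(loss().data)
                p.data.ravel()[i] = orig - eps
                down = float(loss().data)
                p.data.ravel()[i] = orig
                fd = (up - down) / (2 * eps)
                assert fd == pytest.approx(p.grad.ravel()[i], rel=1e-3, abs=1e-6)
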