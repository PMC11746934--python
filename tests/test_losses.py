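"""Loss identities, brute-force oracles, and gradient-direction checks."""

import numpy as np
import pytest

from scstain import losses as L
from scstain.autodiff import Tensor
from scstain.losses import LossWeights


def _const(v, shape=(4, 4)):
    return np.full(shape, float(v))


class TestLsgan:
    @pytest.mark.parametrize("real,fake,expected", [
        (1.0, 0.0, 0.0), (0.0, 1.0, 2.0), (0.5, 0.5, 0.5)])
    def test_d_identities(self, real, fake, expected):
        assert L.lsgan_d(_const(real), _const(fake)).item() == expected

    @pytest.mark.parametrize("fake,expected", [(1.0, 0.0), (0.0, 1.0), (0.5, 0.25)])
    def test_g_identities(self, fake, expected):
        assert L.lsgan_g(_const(fake)).item() == expected


class TestPatchNCE:
    def test_single_site_is_zero(self):
        z = [Tensor(np.array([[1.0, 0.0]]))]
        assert L.patch_nce(z, z, tau=1.0).item() == pytest.approx(0.0, abs=1e-12)

    def test_uniform_similarities_give_log_s(self):
        # all pairwise dot products equal -> uniform softmax -> log S
        z = [Tensor(np.array([[1.0, 0.0], [1.0, 0.0]]))]
        assert L.patch_nce(z, z, tau=0.5).item() == pytest.approx(np.log(2.0))

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_dense_softmax_oracle(self, trial):
        rng = np.random.default_rng(trial)
        s, d, tau = 8, 5, 0.07
        z = rng.standard_normal((s, d))
        zh = rng.standard_normal((s, d))
        z /= np.linalg.norm(z, axis=1, keepdims=True)
        zh /= np.linalg.norm(zh, axis=1, keepdims=True)
        # independent oracle: explicit per-site softmax cross-entropy
        expected = 0.0
        for i in range(s):
            logits = np.array([z[i] @ zh[t] / tau for t in range(s)])
            p = np.exp(logits - logits.max())
            p /= p.sum()
            expected += -np.log(p[i])
        expected /= s
        got = L.patch_nce([Tensor(z)], [Tensor(zh)], tau=tau).item()
        assert got == pytest.approx(expected, rel=1e-10)

    def test_loss_decreases_when_positive_logit_increases(self):
        # orthonormal anchors: perturbing zh[i] along e_i moves only the
        # positive logit (i, i), all other logits stay fixed
        rng = np.random.default_rng(7)
        s = 6
        z = np.eye(s)
        zh = rng.standard_normal((s, s))
        zh /= np.linalg.norm(zh, axis=1, keepdims=True)
        base = L.patch_nce([Tensor(z)], [Tensor(zh)]).item()
        zh2 = zh.copy()
        zh2[2, 2] += 0.05
        assert L.patch_nce([Tensor(z)], [Tensor(zh2)]).item() < base

    def test_empty_stack_raises(self):
        with pytest.raises(ValueError):
            L.patch_nce([], [])


class TestPseudoLoss:
    def test_oracle_generator_scores_zero(self, rng):
        y = rng.random((16, 16, 3))

        class Oracle:
            def __call__(self, _):
                return Tensor(y.transpose(2, 0, 1)[None])

        assert L.pseudo_loss(Oracle(), y).item() == pytest.approx(0.0)

    def test_max_l1_on_unit_range(self):
        y = np.ones((8, 8, 3))

        class Zero:
            def __call__(self, _):
                return Tensor(np.zeros((1, 3, 8, 8)))

        assert L.pseudo_loss(Zero(), y).item() == pytest.approx(1.0)

    def test_expected_l1_of_uniform_to_half(self, rng):
        y = rng.random((64, 64, 3))

        class Half:
            def __call__(self, _):
                return Tensor(np.full((1, 3, 64, 64), 0.5))

        # E|U - 1/2| = 1/4 for U ~ Uniform(0,1)
        assert L.pseudo_loss(Half(), y).item() == pytest.approx(0.25, abs=0.01)


class TestTVNorm:
    def test_constant_field_is_zero(self):
        assert L.tv_norm(np.full((2, 6, 6), 3.0)).item() == 0.0

    def test_single_unit_step(self):
        phi = np.zeros((2, 1, 2))
        phi[0, 0, 1] = 1.0
        assert L.tv_norm(phi).item() == pytest.approx(1.0)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_double_loop_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        phi = rng.standard_normal((2, 8, 8))
        expected = 0.0
        for i in range(8):
            for j in range(8):
                row2 = col2 = 0.0
                if i + 1 < 8:
                    row2 = ((phi[:, i + 1, j] - phi[:, i, j]) ** 2).sum()
                if j + 1 < 8:
                    col2 = ((phi[:, i, j + 1] - phi[:, i, j]) ** 2).sum()
                expected += np.sqrt(row2 + col2)
        assert L.tv_norm(phi).item() == pytest.approx(expected, rel=1e-10)


class TestRegLosses:
    def test_stage1_zero_at_alignment(self, rng):
        x = rng.random((32, 32))
        phi = np.zeros((2, 32, 32))
        assert L.reg_stage1(x, x, phi).item() == pytest.approx(0.0)

    def test_stage1_shift_decomposition(self):
        rng = np.random.default_rng(3)
        base = rng.random((40, 40))
        shift = 3
        od = np.roll(base, -shift, axis=1)       # moving shifted left
        phi = np.zeros((2, 40, 40))
        phi[1] = -shift                          # sample 3 columns left
        loss = L.reg_stage1(base, od, phi, lambda_tv=0.5)
        # interior data term vanishes; the first columns clamp to od[:, 0]
        tv_only = 0.5 * L.tv_norm(phi).item() / (40 * 40)
        data = loss.item() - tv_only
        border = np.abs(base[:, :shift] - od[:, :1]).sum() / (40 * 40)
        assert data == pytest.approx(border, abs=1e-9)

    def test_stage1_reduces_to_l1_at_zero_field(self, rng):
        x, od = rng.random((16, 16)), rng.random((16, 16))
        phi = np.zeros((2, 16, 16))
        assert (L.reg_stage1(x, od, phi, lambda_tv=0.1).item()
                == pytest.approx(np.abs(x - od).mean()))

    def test_stage2_R_zero_at_alignment(self, rng):
        ds = rng.random((16, 16, 3))
        phi = np.zeros((2, 16, 16))
        assert L.reg_stage2_R(ds, ds, phi).item() == pytest.approx(0.0)

    def test_stage2_R_monotone_under_field_noise(self, noise_free_slice):
        from scstain import phantom as ph
        from scstain.nets import warp_image

        wp = ph.make_weak_pair(noise_free_slice, amplitude=6.0, seed=9)
        ds = noise_free_slice.ps   # ideal translator output: x-geometry stain
        vals = []
        for amp in (0.0, 2.0, 4.0):
            noise = ph.random_smooth_field((128, 128), amp, seed=77)
            phi = wp.phi_true + noise
            vals.append(L.reg_stage2_R(ds, wp.y, phi, lambda_tv=0.0).item())
        assert vals[0] <= vals[1] <= vals[2]

    def test_stage2_G_is_plain_l1(self, rng):
        a, b = rng.random((8, 8, 3)), rng.random((8, 8, 3))
        assert L.reg_stage2_G(a, b).item() == pytest.approx(np.abs(a - b).mean())

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            L.reg_stage1(rng.random((8, 8)), rng.random((9, 9)),
                         np.zeros((2, 9, 9)))


class TestTotalLoss:
    def test_reduces_to_gan_when_other_weights_zero(self):
        comp = {"gan_g": 0.7, "nce": 1.0, "pseudo": 2.0, "reg": 3.0}
        w = LossWeights(w_gan=1.0, w_nce=0.0, w_pseudo=0.0, w_reg=0.0)
        assert L.total_loss(comp, w).item() == pytest.approx(0.7)

    def test_unit_weights_sum(self):
        comp = {"gan_g": 1.0, "nce": 2.0, "pseudo": 3.0, "reg": 4.0}
        w = LossWeights(1.0, 1.0, 1.0, 1.0)
        assert L.total_loss(comp, w).item() == pytest.approx(10.0)

    def test_linearity_in_weights(self):
        comp = {"gan_g": 1.0, "nce": 2.0, "pseudo": 3.0, "reg": 4.0}
        one = L.total_loss(comp, LossWeights(1, 1, 1, 1)).item()
        two = L.total_loss(comp, LossWeights(2, 2, 2, 2)).item()
        assert two == pytest.approx(2 * one)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            L.total_loss({"gan_g": 1.0}, LossWeights(w_gan=-1.0))


def test_all_losses_nonnegative_at_random_inputs(rng):
    assert L.lsgan_d(rng.random((4, 4)), rng.random((4, 4))).item() >= 0
    assert L.lsgan_g(rng.random((4, 4))).item() >= 0
    assert L.tv_norm(rng.standard_normal((2, 6, 6))).item() >= 0
    a, b = rng.random((6, 6, 3)), rng.random((6, 6, 3))
    assert L.reg_stage2_G(a, b).item() >= 0
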