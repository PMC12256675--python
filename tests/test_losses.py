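"""LNCC similarity, diffusion regularizer and the combined training loss."""

import numpy as np
import pytest

from conftest import finite_diff_check
from dosewarp.grids import DisplacementField, Volume3D
from dosewarp.registration.losses import (
    LossWeights,
    diffusion_grad,
    diffusion_regularizer,
    lncc,
    lncc_loss,
    lncc_loss_with_grad,
    total_loss,
    total_loss_with_grad,
)


class TestLNCC:
    def test_self_similarity_is_one(self, rng):
        img = rng.standard_normal((16, 16, 12))
        assert lncc(img, img, n=9) == pytest.approx(1.0, abs=1e-3)

    def test_sign_flip_invariance(self, rng):
        """The squared correlation treats an image and its negation alike."""
        img = rng.standard_normal((16, 16, 12))
        assert lncc(img, -img, n=9) == pytest.approx(lncc(img, img, n=9), abs=1e-12)

    def test_independent_noise_scores_low(self):
        vals = [
            lncc(
                np.random.default_rng(2 * s).standard_normal((32, 32, 32)),
                np.random.default_rng(2 * s + 1).standard_normal((32, 32, 32)),
                n=9,
            )
            for s in range(10)
        ]
        assert max(vals) < 0.2

    def test_value_in_unit_interval(self, rng):
        a = rng.standard_normal((12, 12, 12))
        b = rng.standard_normal((12, 12, 12))
        assert 0.0 <= lncc(a, b) <= 1.0

    def test_constant_window_defined_as_zero(self):
        a = np.zeros((11, 11, 11))
        assert lncc(a, a, n=9) == 0.0

    def test_window_larger_than_volume_rejected(self, rng):
        with pytest.raises(ValueError, match="window"):
            lncc(rng.standard_normal((5, 5, 5)), rng.standard_normal((5, 5, 5)), n=9)

    def test_gradient_matches_finite_differences(self, rng):
        f = rng.standard_normal((12, 12, 10))
        g = rng.standard_normal((12, 12, 10))
        _, grad = lncc_loss_with_grad(f, g, n=5)

        def loss():
            return lncc_loss(f, g, n=5)

        finite_diff_check(loss, g, grad, rng, eps=1e-5, tol=1e-4)


class TestDiffusionRegularizer:
    def test_constant_field_is_zero(self):
        u = np.full((6, 6, 6, 3), 3.7)
        assert diffusion_regularizer(u, reduce="sum") == 0.0

    def test_linear_ramp_closed_form(self):
        """u_x = c*x gives gradient c at every voxel (one-sided at the
        boundary), so the sum is n_voxels * c^2."""
        c = 0.8
        shape = (7, 6, 5)
        u = np.zeros((*shape, 3))
        u[..., 0] = c * np.arange(shape[0])[:, None, None]
        expected = np.prod(shape) * c**2
        assert diffusion_regularizer(u, reduce="sum") == pytest.approx(expected, rel=1e-12)

    def test_noise_strictly_increases_value(self):
        base = np.zeros((8, 8, 8, 3))
        base[..., 1] = np.linspace(0, 1, 8)[None, :, None]
        v0 = diffusion_regularizer(base, reduce="sum")
        for seed in range(10):
            noisy = base + np.random.default_rng(seed).normal(0, 0.1, base.shape)
            assert diffusion_regularizer(noisy, reduce="sum") > v0

    def test_nonzero_for_any_nonconstant_field(self, rng):
        u = np.zeros((6, 6, 6, 3))
        u[3, 3, 3, 0] = 1e-9
        assert diffusion_regularizer(u, reduce="sum") > 0

    def test_gradient_matches_finite_differences(self, rng):
        u = rng.standard_normal((7, 6, 5, 3))
        grad = diffusion_grad(u, reduce="mean")

        def loss():
            return diffusion_regularizer(u, reduce="mean")

        finite_diff_check(loss, u, grad, rng)


class TestTotalLoss:
    def test_lambda_zero_equals_similarity_alone(self, rng):
        f = rng.standard_normal((12, 12, 12))
        m = rng.standard_normal((12, 12, 12))
        u = rng.normal(0, 1, (12, 12, 12, 3))
        spacing = (1.0, 1.0, 1.0)
        got = total_loss(Volume3D(f, spacing), Volume3D(m, spacing),
                         DisplacementField(u, spacing), LossWeights(0.0))
        from dosewarp.registration.warp import warp_array

        expected = lncc_loss(f, warp_array(m, u, spacing))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_identical_images_zero_field_near_minus_one(self, rng):
        img = rng.standard_normal((12, 12, 12))
        spacing = (1.0, 1.0, 1.0)
        u = np.zeros((12, 12, 12, 3))
        got = total_loss(Volume3D(img, spacing), Volume3D(img, spacing),
                         DisplacementField(u, spacing), LossWeights(1.0))
        assert got == pytest.approx(-1.0, abs=1e-3)

    def test_affine_in_lambda(self, rng):
        """total(λ) = Lsim + λ·Lsmooth: exact additivity of the two terms."""
        f = rng.standard_normal((12, 12, 12))
        m = rng.standard_normal((12, 12, 12))
        u = rng.normal(0, 1, (12, 12, 12, 3))
        spacing = (2.0, 2.0, 2.0)
        fv, mv = Volume3D(f, spacing), Volume3D(m, spacing)
        field = DisplacementField(u, spacing)
        sim = total_loss(fv, mv, field, LossWeights(0.0))
        smooth = diffusion_regularizer(u, reduce="mean")
        for lam in (0.5, 1.0, 3.0):
            assert total_loss(fv, mv, field, LossWeights(lam)) == pytest.approx(
                sim + lam * smooth, abs=1e-9
            )

    def test_combined_gradient_matches_finite_differences(self, rng):
        f = rng.standard_normal((10, 10, 8))
        m = rng.standard_normal((10, 10, 8))
        u = rng.normal(0, 0.5, (10, 10, 8, 3))
        spacing = (2.0, 2.0, 4.0)
        _, gu = total_loss_with_grad(f, m, u, spacing, lam=1.0, n=5)

        def loss():
            l, _ = total_loss_with_grad(f, m, u, spacing, lam=1.0, n=5)
            return l

        finite_diff_check(loss, u, gu, rng, eps=1e-5, tol=2e-4, n_probe=8)
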