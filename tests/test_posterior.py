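"""Log-posterior, analytic gradients and the tanh reparameterisation."""

import numpy as np
import pytest

import wmhatlas as wa
from wmhatlas.splines import delta_kernel


def random_instance(seed, shape=(5, 5, 5, 3), h=2, full_mask=True):
    rng = np.random.default_rng(seed)
    N = rng.integers(3, 12, shape[-1])
    R = rng.integers(0, N[None, None, None, :] + 1, shape)
    C = rng.uniform(0.15, 0.85, shape)
    mask = np.ones(shape, bool) if full_mask else rng.random(shape[:3]) > 0.3
    state = wa.ModelState(
        latent=wa.latent_from_coefficients(C),
        kernels=wa.make_kernels(h),
        mask=mask,
    )
    return state, R, N, C


class TestReparameterisation:
    def test_tanh_map_values(self):
        assert wa.coefficients_from_latent(np.array(0.0)) == 0.5
        assert wa.coefficients_from_latent(np.array(1.0)) == pytest.approx(0.880797, abs=1e-6)
        assert wa.coefficients_from_latent(np.array(50.0)) == pytest.approx(1.0)
        assert wa.coefficients_from_latent(np.array(-50.0)) == pytest.approx(0.0)

    def test_inverse_is_finite_at_bounds(self):
        lam = wa.latent_from_coefficients(np.array([0.0, 1.0]), epsilon=1e-4)
        assert np.all(np.isfinite(lam))
        assert lam[0] == pytest.approx(np.arctanh(-0.9998))

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        C = rng.uniform(1e-3, 1 - 1e-3, (4, 4, 4, 2))
        back = wa.coefficients_from_latent(wa.latent_from_coefficients(C))
        np.testing.assert_allclose(back, C, atol=1e-12)


class TestLogPosterior:
    def test_scalar_binomial_value(self):
        # identity basis: theta equals the coefficient at the single voxel
        R = np.array([[[[3]]]])
        N = np.array([10])
        state = wa.ModelState(
            latent=wa.latent_from_coefficients(np.full((1, 1, 1, 1), 0.3)),
            kernels=(delta_kernel(),) * 4,
            mask=np.ones((1, 1, 1, 1), bool),
        )
        expected = 3 * np.log(0.3) + 7 * np.log(0.7)  # = -6.10864
        assert wa.log_posterior(state, R, N) == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(-6.10864, abs=1e-5)

    def test_empty_data_gives_zero(self):
        state, R, N, _ = random_instance(1)
        assert wa.log_posterior(state, np.zeros_like(R), np.zeros_like(N)) == 0.0

    def test_mle_maximises_identity_basis(self):
        rng = np.random.default_rng(2)
        shape = (4, 4, 4, 2)
        N = np.array([9, 14])
        R = rng.integers(0, N[None, None, None, :] + 1, shape)
        kernels = (delta_kernel(),) * 4
        mask = np.ones(shape, bool)
        mle = wa.empirical_average(R, N)
        s_mle = wa.ModelState(latent=wa.latent_from_coefficients(mle), kernels=kernels, mask=mask)
        best = wa.log_posterior(s_mle, R, N)
        for _ in range(10):
            C = rng.uniform(0.05, 0.95, shape)
            s = wa.ModelState(latent=wa.latent_from_coefficients(C), kernels=kernels, mask=mask)
            assert wa.log_posterior(s, R, N) <= best + 1e-9

    def test_r_exceeding_n_rejected(self):
        state, R, N, _ = random_instance(3)
        with pytest.raises(ValueError):
            wa.log_posterior(state, R + N.max(), N)


class TestGradients:
    @pytest.mark.parametrize("seed,full_mask", [(0, True), (1, True), (2, False)])
    def test_coefficient_gradient_matches_finite_differences(self, seed, full_mask):
        state, R, N, C = random_instance(seed, full_mask=full_mask)
        G = wa.grad_wrt_coefficients(state, R, N)
        rng = np.random.default_rng(seed + 100)
        d = 1e-6
        for _ in range(12):
            i = tuple(rng.integers(0, s) for s in C.shape)
            Cp, Cm = C.copy(), C.copy()
            Cp[i] += d
            Cm[i] -= d
            fd = (
                wa.log_posterior(state, R, N, latent=wa.latent_from_coefficients(Cp))
                - wa.log_posterior(state, R, N, latent=wa.latent_from_coefficients(Cm))
            ) / (2 * d)
            assert G[i] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_latent_gradient_matches_finite_differences(self):
        state, R, N, _ = random_instance(5)
        G = wa.grad_wrt_latent(state, R, N)
        rng = np.random.default_rng(6)
        lam = state.latent
        d = 1e-6
        for _ in range(12):
            i = tuple(rng.integers(0, s) for s in lam.shape)
            lp, lm = lam.copy(), lam.copy()
            lp[i] += d
            lm[i] -= d
            fd = (
                wa.log_posterior(state, R, N, latent=lp)
                - wa.log_posterior(state, R, N, latent=lm)
            ) / (2 * d)
            assert G[i] == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_directional_derivative_consistency(self):
        state, R, N, _ = random_instance(7)
        G = wa.grad_wrt_latent(state, R, N)
        rng = np.random.default_rng(8)
        lam = state.latent
        for _ in range(3):
            q = rng.standard_normal(lam.shape)
            d = 1e-6
            fd = (
                wa.log_posterior(state, R, N, latent=lam + d * q)
                - wa.log_posterior(state, R, N, latent=lam - d * q)
            ) / (2 * d)
            assert np.vdot(G, q) == pytest.approx(fd, rel=1e-5)

    def test_chain_rule_factor(self):
        state, R, N, _ = random_instance(9)
        state.latent = np.zeros_like(state.latent)  # sech^2(0)/2 = 1/2
        gc = wa.grad_wrt_coefficients(state, R, N)
        gl = wa.grad_wrt_latent(state, R, N)
        np.testing.assert_allclose(gl, 0.5 * gc, atol=1e-12)

    def test_gradient_zero_at_identity_basis_mle(self):
        rng = np.random.default_rng(10)
        shape = (4, 4, 4, 2)
        N = np.array([8, 12])
        R = rng.integers(1, N[None, None, None, :], shape)  # interior MLE
        state = wa.ModelState(
            latent=wa.latent_from_coefficients(wa.empirical_average(R, N)),
            kernels=(delta_kernel(),) * 4,
            mask=np.ones(shape, bool),
        )
        G = wa.grad_wrt_coefficients(state, R, N)
        np.testing.assert_allclose(G, 0.0, atol=1e-8)

    def test_no_lesions_pushes_probability_down(self):
        shape = (5, 5, 5, 2)
        state = wa.ModelState(
            latent=np.zeros(shape),  # theta = 0.5 everywhere
            kernels=wa.make_kernels(2),
            mask=np.ones(shape, bool),
        )
        N = np.array([6, 6])
        G = wa.grad_wrt_coefficients(state, np.zeros(shape, int), N)
        assert np.all(G < 0)

    def test_mask_respected(self):
        state, R, N, _ = random_instance(11, full_mask=False)
        out = ~state.mask
        assert np.all(wa.grad_wrt_coefficients(state, R, N)[out] == 0)
        # data outside the mask must not change the objective
        R2 = R.copy()
        R2[out] = 0
        assert wa.log_posterior(state, R, N) == pytest.approx(
            wa.log_posterior(state, R2, N)
        )
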