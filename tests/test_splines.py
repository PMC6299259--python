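"""Spline kernels and normalised separable convolution."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import wmhatlas as wa
from wmhatlas.splines import cubic_bspline


def dense_convolve(field, taps, center, axes):
    """Brute-force zero-padded convolution oracle.

    Forms the explicit outer-product kernel over the named axes and sums
    shifted copies of the zero-padded field, one kernel offset at a time —
    a direct evaluation of the defining sum, independent of scipy.
    Valid for symmetric kernels (correlation == convolution).
    """
    field = np.asarray(field, dtype=float)
    taps = np.asarray(taps, dtype=float)
    W = np.ones((1,) * field.ndim)
    pad = [(0, 0)] * field.ndim
    for ax in axes:
        s = [1] * field.ndim
        s[ax] = taps.size
        W = W * taps.reshape(s)
        pad[ax] = (center, taps.size - 1 - center)
    fp = np.pad(field, pad)
    out = np.zeros_like(field)
    for kidx in np.ndindex(*W.shape):
        w = W[kidx]
        if w == 0.0:
            continue
        sl = tuple(
            slice(kidx[ax] if W.shape[ax] > 1 else 0,
                  (kidx[ax] if W.shape[ax] > 1 else 0) + field.shape[ax])
            for ax in range(field.ndim)
        )
        out += w * fp[sl]
    return out


class TestCubicKernel:
    def test_unit_spacing_taps(self):
        k = wa.cubic_bspline_kernel(1)
        assert np.allclose(k.taps, [1 / 6, 2 / 3, 1 / 6])

    def test_spacing_two_taps(self):
        k = wa.cubic_bspline_kernel(2)
        assert k.taps[k.center + 1] == pytest.approx(23 / 48)
        assert k.taps[k.center + 3] == pytest.approx(1 / 48)
        assert len(k.taps) == 7  # support |offset| <= 2h-1

    @pytest.mark.parametrize("bad", [0, -1, 1.5])
    def test_invalid_spacing_rejected(self, bad):
        with pytest.raises(ValueError):
            wa.cubic_bspline_kernel(bad)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(h=st.integers(min_value=1, max_value=6))
    def test_symmetry_and_support(self, h):
        k = wa.cubic_bspline_kernel(h)
        for off in range(1, k.center + 1):
            assert k.taps[k.center + off] == pytest.approx(k.taps[k.center - off])
        assert np.all(k.taps >= 0) and k.taps.sum() > 0
        # B3 vanishes at |x| >= 2: one sample beyond the stored support
        assert cubic_bspline(np.array([2 * h / h])) == 0


class TestConvolveSeparable:
    def test_delta_response_is_outer_product(self):
        field = np.zeros((7, 7, 7, 5))
        field[3, 3, 3, 2] = 1.0
        k = wa.cubic_bspline_kernel(1)
        out = wa.convolve_separable(field, k, axes=(0, 1, 2, 3))
        t = k.taps
        expected = np.einsum("i,j,k,l->ijkl", t, t, t, t)
        np.testing.assert_allclose(out[2:5, 2:5, 2:5, 1:4], expected)

    def test_axis_order_independent(self):
        rng = np.random.default_rng(0)
        f = rng.random((6, 5, 4, 3))
        k = wa.cubic_bspline_kernel(2)
        a = wa.convolve_separable(wa.convolve_separable(f, k, axes=(0,)), k, axes=(1,))
        b = wa.convolve_separable(wa.convolve_separable(f, k, axes=(1,)), k, axes=(0,))
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(1)
        f = rng.random((5, 5, 5, 3))
        k = wa.cubic_bspline_kernel(1)
        out = wa.convolve_separable(f, k, axes=(0, 1, 2, 3))
        expected = dense_convolve(f, k.taps, k.center, axes=(0, 1, 2, 3))
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_bad_axes_rejected(self):
        f = np.zeros((3, 3, 3, 2))
        with pytest.raises(ValueError):
            wa.convolve_separable(f, wa.cubic_bspline_kernel(1), axes=(7,))
        with pytest.raises(ValueError):
            wa.convolve_separable(f, wa.cubic_bspline_kernel(1), axes=())


class TestNormalizedConvolve:
    def test_constant_preserved_at_edges(self):
        rng = np.random.default_rng(2)
        mask = rng.random((7, 6, 7, 4)) > 0.4
        mask[0, 0, 0, 0] = True
        f = np.full(mask.shape, 0.37)
        for h in (1, 2, 3):
            out = wa.normalized_convolve(f, mask, wa.cubic_bspline_kernel(h))
            np.testing.assert_allclose(out[mask], 0.37, atol=1e-12)

    def test_partition_of_unity(self):
        mask = np.zeros((6, 6, 6, 3), dtype=bool)
        mask[1:5, 1:5, 1:5, :] = True
        out = wa.normalized_convolve(np.ones(mask.shape), mask, wa.make_kernels(2))
        np.testing.assert_allclose(out[mask], 1.0, atol=1e-12)

    def test_zero_field_maps_to_zero(self):
        mask = np.ones((5, 5, 5, 2), dtype=bool)
        out = wa.normalized_convolve(np.zeros(mask.shape), mask, wa.cubic_bspline_kernel(2))
        np.testing.assert_allclose(out[mask], 0.0)

    def test_edge_delta_matches_hand_ratio(self):
        # single lesioned voxel adjacent to the mask edge of a 7^3 volume
        mask = np.ones((7, 7, 7), dtype=bool)
        f = np.zeros((7, 7, 7))
        f[0, 3, 3] = 1.0
        k = wa.cubic_bspline_kernel(1)
        out = wa.normalized_convolve(f, mask, k, axes=(0, 1, 2))
        # at the corner-adjacent voxel (0,3,3): numerator = central tap^3,
        # denominator = (sum of taps within the volume along x) * full sums
        t = k.taps
        num = t[1] ** 3
        den = (t[1] + t[2]) * t.sum() * t.sum()
        assert out[0, 3, 3] == pytest.approx(num / den)

    def test_no_support_yields_nan(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[0, 0, 0] = True
        out = wa.normalized_convolve(np.ones(mask.shape), mask,
                                     wa.cubic_bspline_kernel(1), axes=(0, 1, 2))
        assert np.isnan(out[4, 4, 4])
        assert out[0, 0, 0] == pytest.approx(1.0)


class TestEvaluateProbabilityField:
    def test_constants_and_bounds(self):
        mask = np.ones((6, 6, 6, 3), dtype=bool)
        for c in (0.0, 0.2, 1.0):
            theta = wa.evaluate_probability_field(
                np.full(mask.shape, c), wa.make_kernels(2), mask
            )
            np.testing.assert_allclose(theta[mask], c, atol=1e-12)

    def test_monotone_and_linear(self):
        rng = np.random.default_rng(3)
        mask = rng.random((6, 6, 6, 4)) > 0.3
        mask[2, 2, 2, :] = True
        k = wa.make_kernels(2)
        C1 = rng.uniform(0, 0.5, mask.shape)
        C2 = C1 + rng.uniform(0, 0.5, mask.shape)
        t1 = wa.evaluate_probability_field(C1, k, mask)
        t2 = wa.evaluate_probability_field(C2, k, mask)
        assert np.all(t1[mask] <= t2[mask] + 1e-12)
        mix = wa.evaluate_probability_field(0.3 * C1 + 0.7 * C2, k, mask)
        np.testing.assert_allclose(mix[mask], (0.3 * t1 + 0.7 * t2)[mask], atol=1e-12)

    def test_matches_dense_weighted_sum(self):
        rng = np.random.default_rng(4)
        mask = rng.random((6, 6, 6, 4)) > 0.3
        mask[3, 3, 3, :] = True
        C = rng.uniform(0, 1, mask.shape)
        k = wa.cubic_bspline_kernel(2)
        theta = wa.evaluate_probability_field(C, k, mask)
        num = dense_convolve(C * mask, k.taps, k.center, axes=(0, 1, 2, 3))
        den = dense_convolve(mask.astype(float), k.taps, k.center, axes=(0, 1, 2, 3))
        exp = num[mask] / den[mask]
        np.testing.assert_allclose(theta[mask], exp, atol=1e-10)

    def test_out_of_range_coefficients_rejected(self):
        mask = np.ones((4, 4, 4, 2), dtype=bool)
        with pytest.raises(ValueError):
            wa.evaluate_probability_field(np.full(mask.shape, 1.4),
                                          wa.cubic_bspline_kernel(1), mask)
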