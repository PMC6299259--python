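"""Binomial log-posterior over spline coefficients and its analytic gradient.

With a uniform prior on the lesion probability the posterior reduces to the
binomial likelihood: per voxel/bin j with R_j lesioned subjects out of N_j,

    L = sum_j R_j log(theta_j) + sum_j (N_j - R_j) log(1 - theta_j),

where theta = normalised spline convolution of the coefficient field C
(constants in L — the prior normaliser and the binomial coefficients — are
dropped).  The gradient with respect to a coefficient C_k is the
correlation of the per-voxel residual

    (R_j / theta_j  -  (N_j - R_j) / (1 - theta_j)) / D_j

with the spline kernel, where D is the normalising image; by kernel
symmetry correlation equals convolution, so the gradient costs the same
four 1-D passes as the forward model.  The box constraint C in [0, 1] is
removed by the reparameterisation C = (1 + tanh(lambda)) / 2, whose chain
rule contributes an elementwise factor sech^2(lambda) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .splines import Kernel1D, convolve_separable, ALL_AXES

__all__ = [
    "ModelState",
    "coefficients_from_latent",
    "latent_from_coefficients",
    "log_posterior",
    "grad_wrt_coefficients",
    "grad_wrt_latent",
]

#: probability clamp inside logs and denominators; the likelihood is
#: undefined at theta in {0, 1}, which real all-zero / all-lesion voxels hit
DEFAULT_EPSILON = 1e-6


def coefficients_from_latent(lam: np.ndarray) -> np.ndarray:
    """C = (1 + tanh(lambda)) / 2, mapping R onto (0, 1) elementwise."""
    return 0.5 * (1.0 + np.tanh(lam))


def latent_from_coefficients(C: np.ndarray, epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Inverse map lambda = atanh(2 C - 1), clipping C to [eps, 1 - eps].

    The clip keeps the latent finite when the initialisation touches the
    box boundary (e.g. lesion-free background voxels with average 0).
    """
    C = np.clip(np.asarray(C, dtype=float), epsilon, 1.0 - epsilon)
    return np.arctanh(2.0 * C - 1.0)


def _broadcast_bins(N: np.ndarray, shape) -> np.ndarray:
    """Per-bin counts broadcast over space: accepts (t,) or full 4D."""
    N = np.asarray(N)
    if N.ndim == 1:
        return N[None, None, None, :]
    return N


@dataclass
class ModelState:
    """Mutable fitting state: latent field, kernels, mask and clamp.

    The normalising image (convolution of the mask indicator) depends only
    on the kernels and mask, so it is computed once and cached.
    """

    latent: np.ndarray
    kernels: Sequence[Kernel1D]
    mask: np.ndarray
    epsilon: float = DEFAULT_EPSILON
    _den: np.ndarray = field(default=None, repr=False)
    _u: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if not (0.0 < self.epsilon < 0.5):
            raise ValueError("epsilon must lie in (0, 0.5)")
        self.latent = np.asarray(self.latent, dtype=float)
        mask = np.asarray(self.mask)
        if mask.ndim == 3:
            mask = mask[..., None]
        mask = np.broadcast_to(mask > 0, self.latent.shape)
        self.mask = mask
        self._u = np.ascontiguousarray(mask, dtype=float)
        if not self._u.any():
            raise ValueError("mask must contain at least one inside voxel")
        self._den = convolve_separable(self._u, self.kernels, ALL_AXES)

    @property
    def denominator(self) -> np.ndarray:
        return self._den

    def coefficients(self) -> np.ndarray:
        return coefficients_from_latent(self.latent)

    def probability(self, latent: np.ndarray | None = None) -> np.ndarray:
        """theta for the current (or a trial) latent field; NaN off-support."""
        lam = self.latent if latent is None else latent
        C = coefficients_from_latent(lam)
        num = convolve_separable(C * self._u, self.kernels, ALL_AXES)
        theta = np.full(num.shape, np.nan)
        good = self._den > 0
        np.divide(num, self._den, out=theta, where=good)
        np.clip(theta, 0.0, 1.0, out=theta)
        return theta


def _check_counts(R, N, shape):
    R = np.asarray(R)
    Nb = _broadcast_bins(N, shape)
    if np.any(R > Nb):
        raise ValueError("count field R exceeds cohort size N at some voxel")
    return R, Nb


def log_posterior(state: ModelState, R: np.ndarray, N: np.ndarray,
                  latent: np.ndarray | None = None) -> float:
    """Binomial log-likelihood of (R, N) under theta(lambda), in-mask only.

    theta is clamped to [eps, 1 - eps] inside the logarithms; empty bins
    (R = N = 0) contribute exactly zero.
    """
    R, Nb = _check_counts(R, N, state.latent.shape)
    theta = state.probability(latent)
    eps = state.epsilon
    tc = np.clip(theta, eps, 1.0 - eps)
    with np.errstate(invalid="ignore"):
        terms = R * np.log(tc) + (Nb - R) * np.log1p(-tc)
    return float(np.sum(terms, where=state.mask & np.isfinite(terms)))


def grad_wrt_coefficients(state: ModelState, R: np.ndarray, N: np.ndarray,
                          latent: np.ndarray | None = None) -> np.ndarray:
    """Analytic gradient dL/dC: kernel correlation of the scaled residual.

    Zero outside the mask (out-of-mask coefficients never enter theta) and
    zero wherever the probability clamp is active (the clamp is flat there).
    """
    R, Nb = _check_counts(R, N, state.latent.shape)
    theta = state.probability(latent)
    eps = state.epsilon
    active = state.mask & (theta > eps) & (theta < 1.0 - eps)
    resid = np.zeros_like(state.latent)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = R / theta - (Nb - R) / (1.0 - theta)
        np.divide(raw, state._den, out=resid, where=active)
    grad = convolve_separable(resid, state.kernels, ALL_AXES)
    grad *= state._u
    return grad


def grad_wrt_latent(state: ModelState, R: np.ndarray, N: np.ndarray,
                    latent: np.ndarray | None = None) -> np.ndarray:
    """Chain rule through C = (1 + tanh(lambda)) / 2: dC/dlambda = sech^2 / 2."""
    lam = state.latent if latent is None else latent
    gC = grad_wrt_coefficients(state, R, N, latent)
    sech2 = 1.0 - np.tanh(lam) ** 2
    return gC * (0.5 * sech2)
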