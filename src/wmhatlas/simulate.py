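"""Synthetic age-stratified lesion cohorts with closed-form ground truth.

Each simulated subject is a thresholded smoothed Gaussian random field: at
every in-mask voxel a standard normal deviate is added to a latent mean
``mu(x)``, the field is smoothed with a small Gaussian kernel ``K``
(sigma = 0.8 voxels by default, which clusters lesion voxels into plausible
blobs), and voxels where the smoothed field exceeds zero become lesions.
Because the smoothed field is Gaussian with mean ``K * mu`` and variance
``K^2 * M`` (M the brain mask, K^2 the elementwise-squared kernel), the
exact per-voxel lesion probability is

    theta_true = Phi( (K * mu) / sqrt(K^2 * M) ),

which serves as the ground truth for scoring estimators.

The latent mean is the probit of a target probability map, mu = Phi^-1(p):
without smoothing this makes P(lesion) = p exactly, and it keeps the
near-zero background of a sparse lesion frequency map at near-zero
probability rather than drifting towards one half.  The built-in target
map emulates a white matter hyperintensity frequency atlas: a handful of
anisotropic periventricular-style blobs flanking the midline, sparse
(the overwhelming majority of in-mask voxels below 0.01), peaking around
0.45, and scaled by a logistic function of the covariate bin so that
lesion probability rises with "age".  A real frequency map can be
substituted via ``SimulationConfig.base_probability``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import norm

from .splines import Kernel1D, gaussian_kernel, convolve_separable

__all__ = [
    "SimulationConfig",
    "GroundTruthField",
    "default_brain_mask",
    "synthesize_target_probability",
    "latent_mean_from_probability",
    "true_probability_field",
    "simulate_subject_map",
    "simulate_cohort",
    "scaled_down_config",
]

#: probability clip for the probit link; keeps mu finite at p in {0, 1}
PROBIT_EPS = 1e-4


@dataclass
class SimulationConfig:
    """Stated conditions of the simulation study.

    Defaults are the full-scale protocol: 91 x 109 x 91 volumes, 60
    covariate bins, between 1 and 50 subjects per bin, lesion smoothing
    sigma 0.8 voxels.
    """

    shape: tuple = (91, 109, 91)
    n_bins: int = 60
    subjects_per_bin_range: tuple = (1, 50)
    smoothing_sigma: float = 0.8
    seed: int = 0
    mask: Optional[np.ndarray] = None
    base_probability: Optional[np.ndarray] = None
    peak_probability: float = 0.45
    dtype: np.dtype = np.float32

    def __post_init__(self):
        lo, hi = self.subjects_per_bin_range
        if lo < 1 or hi < lo:
            raise ValueError("subjects_per_bin_range must satisfy 1 <= lo <= hi")
        if self.smoothing_sigma <= 0:
            raise ValueError("smoothing_sigma must be positive")

    def resolved_mask(self) -> np.ndarray:
        if self.mask is not None:
            return np.asarray(self.mask) > 0
        return default_brain_mask(self.shape)

    def kernel(self) -> Kernel1D:
        return gaussian_kernel(self.smoothing_sigma)


def scaled_down_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Reduced-scale protocol: 45 x 54 x 45, 20 bins, ~250 subjects."""
    defaults = dict(
        shape=(45, 54, 45),
        n_bins=20,
        subjects_per_bin_range=(1, 24),
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@dataclass
class GroundTruthField:
    """Closed-form simulation truth theta_true and its latent mean mu."""

    theta_true: np.ndarray
    mu: np.ndarray


def default_brain_mask(shape) -> np.ndarray:
    """Centred ellipsoid occupying ~38% of the bounding box, a brain stand-in."""
    nx, ny, nz = shape
    x, y, z = np.ogrid[:nx, :ny, :nz]
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    r = ((x - cx) / (0.45 * nx)) ** 2 + ((y - cy) / (0.45 * ny)) ** 2 + (
        (z - cz) / (0.45 * nz)
    ) ** 2
    return r <= 1.0


def synthesize_target_probability(config: SimulationConfig) -> np.ndarray:
    """Deterministic 4D target probability map (x, y, z, t).

    Four anisotropic Gaussian blobs, elongated anterior-posterior and
    placed symmetrically about the midline near the volume centre (the
    periventricular pattern typical of WMH frequency maps), are summed,
    normalised to the configured peak, and modulated by a logistic ramp of
    the bin index so every voxel's probability is non-decreasing in t.  A
    user-supplied ``base_probability`` (3D, modulated the same way, or
    full 4D) overrides the synthetic blobs.
    """
    mask = config.resolved_mask()
    nx, ny, nz = config.shape
    T = config.n_bins

    if config.base_probability is not None:
        base = np.asarray(config.base_probability, dtype=float)
        if base.ndim == 4:
            out = base * mask[..., None]
            return out.astype(config.dtype)
        scale = 1.0  # a supplied 3D map is taken as the last-bin probability
    else:
        scale = config.peak_probability
        rng = np.random.default_rng(config.seed)
        x, y, z = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        base = np.zeros(config.shape)
        # Two blob pairs flanking the midline: anterior and posterior
        # periventricular caps.  The super-Gaussian plateau profile
        # exp(-r^16 / 2) is nearly constant over the core (so the latent
        # mean varies slowly at the lesion-smoothing scale, as a real
        # smoothed frequency map does) and drops sharply at the rim,
        # reproducing the plateau-and-edge character of WMH frequency
        # atlases; the blob extents are sized so the map stays sparse
        # (>= 95% of in-mask voxels below 0.01) with the plateau fraction
        # maximised within that bound.
        sig = (0.070 * nx, 0.135 * ny, 0.088 * nz)
        for side in (-1.0, 1.0):
            for frac_y, amp0 in ((0.40, 0.95), (0.62, 1.0)):
                cx = (nx - 1) / 2 + side * 0.12 * nx + rng.normal(0, 0.01 * nx)
                cy = frac_y * ny + rng.normal(0, 0.02 * ny)
                cz = (nz - 1) / 2 + rng.normal(0, 0.02 * nz)
                amp = amp0 * rng.uniform(0.95, 1.0)
                r2 = (
                    ((x - cx) / sig[0]) ** 2
                    + ((y - cy) / sig[1]) ** 2
                    + ((z - cz) / sig[2]) ** 2
                )
                np.maximum(base, amp * np.exp(-0.5 * r2**8), out=base)
        base *= mask
        peak = base.max()
        if peak > 0:
            base = base / peak

    # logistic rise with bin index, normalised to 1 at the last bin
    tau = np.arange(T) / max(T - 1, 1)
    ramp = 1.0 / (1.0 + np.exp(-(tau - 0.55) / 0.18))
    ramp = ramp / ramp[-1]
    out = scale * base[..., None] * ramp[None, None, None, :]
    out *= mask[..., None]
    return np.clip(out, 0.0, 1.0).astype(config.dtype)


def latent_mean_from_probability(p_target: np.ndarray, eps: float = PROBIT_EPS) -> np.ndarray:
    """Probit link mu = Phi^-1(clip(p, eps, 1 - eps)), elementwise."""
    p = np.clip(np.asarray(p_target, dtype=float), eps, 1.0 - eps)
    return norm.ppf(p)


def true_probability_field(
    mu: np.ndarray,
    kernel: Kernel1D,
    mask: np.ndarray,
) -> GroundTruthField:
    """theta_true = Phi( (K * mu) / sqrt(K^2 * M) ), per covariate bin.

    ``mu`` may be 3D (a single bin) or 4D; smoothing is purely spatial and
    masked, with the elementwise-squared kernel in the variance term.
    theta_true is zero outside the mask and NaN where the kernel has no
    in-mask support (which cannot happen inside the mask itself).
    """
    mu = np.asarray(mu, dtype=float)
    squeeze = mu.ndim == 3
    if squeeze:
        mu = mu[..., None]
    mask3 = np.asarray(mask) > 0
    m = mask3.astype(float)
    # K^2 * M: convolution of the mask with the elementwise-squared taps
    var = convolve_separable(
        m, Kernel1D(taps=kernel.taps**2, center=kernel.center), axes=(0, 1, 2)
    )
    sd = np.sqrt(np.maximum(var, 0.0))
    theta = np.zeros_like(mu)
    for t in range(mu.shape[-1]):
        num = convolve_separable(mu[..., t] * m, kernel, axes=(0, 1, 2))
        z = np.full(num.shape, np.nan)
        np.divide(num, sd, out=z, where=sd > 0)
        th = norm.cdf(z)  # NaN propagates where the kernel has no support
        th[~mask3 & (sd > 0)] = 0.0
        theta[..., t] = th
    theta = theta[..., 0] if squeeze else theta
    mu_out = mu[..., 0] if squeeze else mu
    return GroundTruthField(theta_true=theta, mu=mu_out)


def simulate_subject_map(
    mu_bin: np.ndarray,
    kernel: Kernel1D,
    mask: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One subject: threshold the masked-smoothed noisy latent field at zero."""
    mask3 = np.asarray(mask) > 0
    noise = rng.standard_normal(mu_bin.shape)
    f = np.asarray(mu_bin, dtype=noise.dtype) + noise
    f *= mask3
    smoothed = convolve_separable(f, kernel, axes=(0, 1, 2))
    return ((smoothed > 0) & mask3).astype(np.uint8)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray, GroundTruthField]:
    """Simulate the full cohort: returns (R_sim, N_sim, ground truth).

    Per bin, the number of subjects is drawn uniformly from
    ``subjects_per_bin_range`` and that many thresholded smoothed Gaussian
    fields are summed into the count field.  The (config, seed) pair fully
    determines every output.
    """
    rng = np.random.default_rng(config.seed)
    mask = config.resolved_mask()
    kernel = config.kernel()
    p = synthesize_target_probability(config)
    mu = latent_mean_from_probability(p)
    truth = true_probability_field(mu, kernel, mask)
    truth.theta_true = truth.theta_true.astype(config.dtype)

    lo, hi = config.subjects_per_bin_range
    N = rng.integers(lo, hi + 1, size=config.n_bins).astype(np.int64)
    R = np.zeros(config.shape + (config.n_bins,), dtype=np.int32)
    mu32 = mu.astype(np.float32)
    for t in range(config.n_bins):
        acc = np.zeros(config.shape, dtype=np.int32)
        for _ in range(int(N[t])):
            acc += simulate_subject_map(mu32[..., t], kernel, mask, rng)
        R[..., t] = acc
    return R, N, truth
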