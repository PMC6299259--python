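"""Reference estimators: per-bin average and its Gaussian-smoothed variant.

``Average`` is the per-bin lesion frequency R/N; ``Smoothed_Average(sigma)``
smooths it with a Gaussian kernel along all four axes (space and the
covariate axis) using the same mask-normalised scheme as the spline model,
so constants survive at mask edges.  Both serve as comparison points for
the Bayesian spline fit.
"""

from __future__ import annotations

import numpy as np

from .cohort import empirical_average
from .splines import gaussian_kernel, normalized_convolve, ALL_AXES

__all__ = ["average_baseline", "smoothed_average_baseline"]


def average_baseline(R: np.ndarray, N: np.ndarray) -> np.ndarray:
    """Per-bin empirical frequency R/N; empty bins are NaN."""
    return empirical_average(R, N)


def smoothed_average_baseline(
    R: np.ndarray,
    N: np.ndarray,
    sigma: float,
    mask: np.ndarray = None,
) -> np.ndarray:
    """Mask-normalised 4D Gaussian smoothing of the per-bin average.

    ``sigma`` is in voxel/bin units and identical across the four axes; the
    kernel is truncated at 4 sigma.  Voxels outside the mask and empty-bin
    (sentinel) voxels are excluded from the smoothing support, and the
    sentinel propagates to the output at those voxels.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    avg = empirical_average(R, N)
    defined = np.isfinite(avg)
    if mask is None:
        support = defined
    else:
        mask = np.asarray(mask)
        if mask.ndim == 3:
            mask = mask[..., None]
        support = defined & np.broadcast_to(mask > 0, avg.shape)
    kernel = gaussian_kernel(sigma)
    work = np.where(support, avg, 0.0)
    out = normalized_convolve(work, support, kernel, ALL_AXES)
    out[~support] = np.nan
    np.clip(out, 0.0, 1.0, out=out)
    return out
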