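"""Separable cubic B-spline kernels and mask-normalised convolution.

The probability representation used throughout this package is a linear
combination of shifted cubic B-splines,

    theta(j) = sum_i C_i B(j - i),

realised as image-space convolution of a coefficient volume ``C`` with a
sampled 1-D cubic B-spline, applied independently along each axis (the
basis is a separable outer product of 1-D splines).  Near the edge of the
field of view the spline tails fall outside the valid region; dividing the
raw convolution by the convolution of the support indicator ("normalised
convolution") removes the resulting roll-off so that constants are
reproduced exactly everywhere inside the mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "Kernel1D",
    "cubic_bspline_kernel",
    "gaussian_kernel",
    "delta_kernel",
    "make_kernels",
    "convolve_separable",
    "normalized_convolve",
    "evaluate_probability_field",
    "cubic_bspline",
]

#: all four axes of an (x, y, z, t) volume
ALL_AXES = (0, 1, 2, 3)


def cubic_bspline(x):
    """Standard cubic B-spline B3 evaluated at ``x`` (support ``|x| < 2``)."""
    x = np.abs(np.asarray(x, dtype=float))
    out = np.zeros_like(x)
    inner = x <= 1.0
    outer = (x > 1.0) & (x < 2.0)
    out[inner] = 2.0 / 3.0 - x[inner] ** 2 + 0.5 * x[inner] ** 3
    out[outer] = (2.0 - x[outer]) ** 3 / 6.0
    return out


@dataclass(frozen=True)
class Kernel1D:
    """A symmetric 1-D kernel sampled on the integer voxel grid.

    ``taps`` has odd length with ``center`` the middle index; symmetry about
    the centre makes correlation and convolution coincide, which the
    analytic gradient of the model relies on.
    """

    taps: np.ndarray
    center: int
    spacing: int = 1

    def __post_init__(self):
        taps = np.asarray(self.taps, dtype=float)
        object.__setattr__(self, "taps", taps)
        if taps.ndim != 1 or taps.size % 2 == 0:
            raise ValueError("kernel taps must be a 1-D odd-length array")
        if self.center != taps.size // 2:
            raise ValueError("kernel centre must be the middle tap")
        if np.any(taps < 0):
            raise ValueError("kernel taps must be non-negative")
        if not np.allclose(taps, taps[::-1]):
            raise ValueError("kernel taps must be symmetric about the centre")
        if taps.sum() <= 0:
            raise ValueError("kernel taps must have positive sum")

    @property
    def radius(self) -> int:
        return self.center


def cubic_bspline_kernel(knot_spacing: int) -> Kernel1D:
    """Cubic B-spline kernel dilated by an integer knot spacing ``h``.

    Taps are ``B3(k / h)`` for integer offsets ``k``; the support covers
    ``|k| <= 2h - 1``.  For ``h = 1`` this is the familiar (1/6, 2/3, 1/6).
    The taps are deliberately left un-normalised: the normalising image of
    :func:`normalized_convolve` cancels any overall scale.
    """
    if not float(knot_spacing).is_integer() or knot_spacing < 1:
        raise ValueError(f"knot_spacing must be a positive integer, got {knot_spacing!r}")
    h = int(knot_spacing)
    offsets = np.arange(-(2 * h - 1), 2 * h)
    taps = cubic_bspline(offsets / h)
    return Kernel1D(taps=taps, center=2 * h - 1, spacing=h)


def gaussian_kernel(sigma: float, truncate: float = 4.0) -> Kernel1D:
    """Sampled Gaussian kernel truncated at ``truncate * sigma`` (min radius 1)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    radius = max(1, int(np.ceil(truncate * sigma)))
    offsets = np.arange(-radius, radius + 1)
    taps = np.exp(-0.5 * (offsets / sigma) ** 2)
    taps /= taps.sum()
    return Kernel1D(taps=taps, center=radius)


def delta_kernel() -> Kernel1D:
    """Identity kernel (single unit tap); useful to disable smoothing."""
    return Kernel1D(taps=np.array([1.0]), center=0)


def make_kernels(knot_spacing: int | Sequence[int] = 2) -> tuple[Kernel1D, ...]:
    """Build per-axis cubic B-spline kernels for a 4D (x, y, z, t) field.

    A scalar applies the same knot spacing to all four axes (the default of
    2 voxels spatially and 2 bins along the covariate axis performed best
    in the knot-spacing sweep); a length-4 sequence sets them per axis.
    """
    if np.isscalar(knot_spacing):
        return tuple(cubic_bspline_kernel(int(knot_spacing)) for _ in range(4))
    spacings = tuple(knot_spacing)
    if len(spacings) != 4:
        raise ValueError("per-axis knot spacing must have length 4")
    return tuple(cubic_bspline_kernel(int(h)) for h in spacings)


def _kernel_list(kernel, axes) -> list[Kernel1D]:
    if isinstance(kernel, Kernel1D):
        return [kernel] * len(axes)
    kernels = list(kernel)
    if len(kernels) == len(axes):
        return kernels
    # a full per-axis tuple indexed by axis number
    if len(kernels) > max(axes):
        return [kernels[ax] for ax in axes]
    raise ValueError("kernel sequence does not cover the requested axes")


def convolve_separable(field: np.ndarray, kernel, axes: Iterable[int] = ALL_AXES) -> np.ndarray:
    """Sequential 1-D convolution along ``axes`` with zero padding.

    ``kernel`` may be a single :class:`Kernel1D` (used on every axis) or a
    sequence of kernels, either one per requested axis or one per array
    axis.  The result is independent of axis order.
    """
    axes = tuple(axes)
    if not axes:
        raise ValueError("axes must be non-empty")
    field = np.asarray(field)
    for ax in axes:
        if ax < -field.ndim or ax >= field.ndim:
            raise ValueError(f"axis {ax} out of range for a {field.ndim}-D field")
    out = np.asarray(field, dtype=field.dtype if field.dtype.kind == "f" else float)
    for ax, k in zip(axes, _kernel_list(kernel, axes)):
        out = ndimage.convolve1d(out, k.taps, axis=ax, mode="constant", cval=0.0)
    return out


def normalized_convolve(
    field: np.ndarray,
    mask: np.ndarray,
    kernel,
    axes: Iterable[int] = ALL_AXES,
) -> np.ndarray:
    """Mask-normalised separable convolution.

    Computes ``conv(field * mask) / conv(mask)``; voxels outside the mask
    contribute nothing to the numerator, and the denominator (the
    convolution of the support indicator) corrects the edge roll-off so a
    constant field is reproduced exactly at every in-mask voxel.  Where the
    denominator vanishes (no in-mask voxel within kernel reach) the result
    is NaN, the package-wide undefined sentinel.
    """
    mask = np.asarray(mask)
    if mask.shape != np.shape(field):
        mask = np.broadcast_to(mask, np.shape(field))
    m = mask.astype(float, copy=False)
    if not np.any(m > 0):
        raise ValueError("mask must contain at least one inside voxel")
    num = convolve_separable(np.asarray(field) * m, kernel, axes)
    den = convolve_separable(np.ascontiguousarray(m), kernel, axes)
    out = np.full(num.shape, np.nan, dtype=num.dtype)
    good = den > 0
    np.divide(num, den, out=out, where=good)
    return out


def evaluate_probability_field(C: np.ndarray, kernel, mask: np.ndarray) -> np.ndarray:
    """Probability field theta from a coefficient field ``C`` in [0, 1].

    theta is the normalised spline convolution of ``C`` over all four axes;
    because it is a convex combination of in-mask coefficient values it
    stays within [0, 1] (clipped against floating-point dust).  NaN marks
    voxels with no in-mask support.
    """
    C = np.asarray(C, dtype=float)
    if np.nanmin(C) < -1e-12 or np.nanmax(C) > 1 + 1e-12:
        raise ValueError("coefficients must lie in [0, 1]")
    theta = normalized_convolve(C, mask, kernel, ALL_AXES)
    return np.clip(theta, 0.0, 1.0, out=theta)
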