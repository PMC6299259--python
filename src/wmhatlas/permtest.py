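"""Permutation inference with max-statistic family-wise error correction.

Two flavours: an unpaired two-sample t-test comparing lesion probability
between groups (per-subject binary maps are smoothed with the model's
spline kernel first, which stabilises the variance of binary data), and an
age-effect test whose statistic is the per-voxel least-squares slope of the
fitted probability field across covariate bins, with the null built by
permuting subjects' bin assignments and refitting.

Family-wise correction uses the null distribution of the image-wide
maximum absolute statistic; corrected p-values follow the add-one rule
p = (1 + #{null maxima >= |stat|}) / (n_permutations + 1), so the smallest
attainable p is 1/(n_permutations + 1) and p = 0 never occurs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .cohort import CovariateBinning, SubjectLesionMap, accumulate
from .optimize import OptimizerConfig, fit_map
from .splines import Kernel1D, cubic_bspline_kernel, normalized_convolve

__all__ = ["PermutationResult", "two_group_max_t_test", "age_effect_permutation_test"]


@dataclass
class PermutationResult:
    stat_map: np.ndarray
    p_corr_map: np.ndarray
    z_map: np.ndarray
    n_permutations: int
    seed: int
    null_max_stats: np.ndarray
    n_zero_variance: int = 0
    messages: list = field(default_factory=list)


def _smooth_subject(volume, kernel, mask3):
    sm = normalized_convolve(volume.astype(float), mask3, kernel, axes=(0, 1, 2))
    return np.nan_to_num(sm, nan=0.0)[mask3]


def _t_stat(data: np.ndarray, is_a: np.ndarray):
    """Pooled-variance two-sample t per voxel column; zero where variance is zero."""
    a, b = data[is_a], data[~is_a]
    na, nb = len(a), len(b)
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1) if na > 1 else np.zeros_like(ma)
    vb = b.var(axis=0, ddof=1) if nb > 1 else np.zeros_like(mb)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / max(na + nb - 2, 1)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    t = np.zeros_like(ma)
    good = denom > 0
    np.divide(ma - mb, denom, out=t, where=good)
    n_zero = int((~good).sum())
    return t, n_zero


def _p_corr(stat_flat: np.ndarray, null_max: np.ndarray) -> np.ndarray:
    n = null_max.size
    if n == 0:
        return np.ones_like(stat_flat)
    exceed = (null_max[None, :] >= np.abs(stat_flat)[:, None]).sum(axis=1)
    return (1.0 + exceed) / (n + 1.0)


def _signed_z(stat_flat: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Inverse-normal transform of corrected p, signed like the statistic."""
    z = norm.isf(np.clip(p, 1e-300, 1.0 - 1e-12))
    return np.where(stat_flat == 0, 0.0, np.sign(stat_flat) * z)


def _embed(values: np.ndarray, mask3: np.ndarray, fill=np.nan) -> np.ndarray:
    out = np.full(mask3.shape, fill, dtype=float)
    out[mask3] = values
    return out


def two_group_max_t_test(
    group_a: Sequence[SubjectLesionMap],
    group_b: Sequence[SubjectLesionMap],
    mask: np.ndarray,
    n_permutations: int = 500,
    seed: int = 0,
    kernel: Optional[Kernel1D] = None,
    smooth: bool = True,
) -> PermutationResult:
    """Voxelwise unpaired t-test between two subject groups, FWE-corrected.

    The observed statistic uses the given group labels (the identity
    assignment); the null relabels subjects at random, recording the
    image-wide max |t| per permutation.  z-scores are the inverse-normal
    transform of the corrected p-values, signed like the t statistic.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    mask3 = np.asarray(mask) > 0
    kernel = kernel or cubic_bspline_kernel(2)
    subjects = list(group_a) + list(group_b)
    if smooth:
        data = np.stack([_smooth_subject(s.volume, kernel, mask3) for s in subjects])
    else:
        data = np.stack([s.volume[mask3].astype(float) for s in subjects])
    is_a = np.zeros(len(subjects), dtype=bool)
    is_a[: len(group_a)] = True

    t_obs, n_zero = _t_stat(data, is_a)
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(len(subjects))
        t_perm, _ = _t_stat(data, is_a[perm])
        null_max[i] = np.abs(t_perm).max()
    p = _p_corr(t_obs, null_max)
    z = _signed_z(t_obs, p)
    return PermutationResult(
        stat_map=_embed(t_obs, mask3),
        p_corr_map=_embed(p, mask3, fill=1.0),
        z_map=_embed(z, mask3, fill=0.0),
        n_permutations=n_permutations,
        seed=seed,
        null_max_stats=null_max,
        n_zero_variance=n_zero,
    )


def _slope_stat(theta: np.ndarray, mask3: np.ndarray) -> np.ndarray:
    """Least-squares slope of theta versus bin index, per in-mask voxel."""
    T = theta.shape[-1]
    t = np.arange(T, dtype=float)
    tc = t - t.mean()
    denom = (tc**2).sum()
    vals = np.nan_to_num(theta[mask3], nan=0.0)
    return (vals * tc[None, :]).sum(axis=1) / denom


def age_effect_permutation_test(
    subjects: Sequence[SubjectLesionMap],
    binning: CovariateBinning,
    mask: np.ndarray,
    kernel=2,
    fit_config: Optional[OptimizerConfig] = None,
    n_permutations: int = 100,
    seed: int = 0,
    max_redraws: int = 3,
) -> PermutationResult:
    """Permutation test for a covariate (age) effect on lesion probability.

    Statistic: per-voxel linear-trend slope of the fitted probability field
    across bins.  Null: permute the subjects' covariate values (bin
    assignments), refit, record the image-wide max |slope|.  A fit failure
    in a permutation is redrawn and logged.  With ``n_permutations=0`` the
    observed statistic is returned with all corrected p-values equal to 1.
    """
    if binning.n_bins < 2:
        raise ValueError("at least two covariate bins required")
    mask3 = np.asarray(mask) > 0
    subjects = list(subjects)

    def fit_slopes(subs):
        R, N = accumulate(subs, binning)
        theta, _, _ = fit_map(R, N, kernel=kernel, mask=mask3, config=fit_config)
        return _slope_stat(theta, mask3)

    obs = fit_slopes(subjects)
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_permutations)
    messages = []
    covs = np.array([s.covariate for s in subjects])
    for i in range(n_permutations):
        for attempt in range(max_redraws + 1):
            perm = rng.permutation(len(subjects))
            permuted = [
                SubjectLesionMap(s.subject_id, covs[j], s.volume, s.group)
                for s, j in zip(subjects, perm)
            ]
            try:
                null_max[i] = np.abs(fit_slopes(permuted)).max()
                break
            except Exception as exc:  # noqa: BLE001 - redrawn and logged
                messages.append(f"permutation {i} attempt {attempt}: {exc}")
        else:
            raise RuntimeError(f"permutation {i} failed after {max_redraws} redraws")
    p = _p_corr(obs, null_max)
    z = _signed_z(obs, p)
    return PermutationResult(
        stat_map=_embed(obs, mask3),
        p_corr_map=_embed(p, mask3, fill=1.0),
        z_map=_embed(z, mask3, fill=0.0),
        n_permutations=n_permutations,
        seed=seed,
        null_max_stats=null_max,
        messages=messages,
    )
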