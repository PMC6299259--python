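"""Aggregation of per-subject binary lesion maps into binned count fields.

Subjects are grouped into bins of a scalar covariate (age, in the typical
use).  The 4D count field ``R(x, y, z, t)`` holds, per voxel and bin, the
number of subjects in that bin with a lesion at that voxel; ``N(t)`` is the
number of subjects per bin.  ``R / N`` is the empirical per-bin lesion
frequency, the simplest population map and the raw data for the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SubjectLesionMap",
    "CovariateBinning",
    "assign_bins",
    "accumulate",
    "empirical_average",
    "fill_empty_bins",
]

#: sentinel for quantities undefined at a voxel/bin (e.g. an empty bin)
UNDEFINED = np.nan


@dataclass
class SubjectLesionMap:
    """One subject's binary lesion mask on the common reference grid."""

    subject_id: str
    covariate: float
    volume: np.ndarray
    group: Optional[str] = None

    def __post_init__(self):
        vol = np.asarray(self.volume)
        uniq = np.unique(vol)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"subject {self.subject_id}: lesion map is not binary")
        self.volume = vol.astype(np.uint8, copy=False)


@dataclass
class CovariateBinning:
    """Strictly increasing bin edges over the covariate.

    Bins are half-open ``[e_k, e_{k+1})`` with the last bin closed at the
    top, so every covariate in ``[edges[0], edges[-1]]`` lands in exactly
    one bin.
    """

    edges: np.ndarray
    labels: Sequence[str] = field(default=None)

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("need at least two bin edges")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        self.edges = edges
        if self.labels is None:
            self.labels = [
                f"[{lo:g}, {hi:g})" for lo, hi in zip(edges[:-1], edges[1:])
            ]
            self.labels[-1] = self.labels[-1][:-1] + "]"
        elif len(self.labels) != self.n_bins:
            raise ValueError("one label per bin required")

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1

    @classmethod
    def regular(cls, start: float, stop: float, width: float) -> "CovariateBinning":
        """Evenly spaced bins of a given width covering [start, stop]."""
        n = int(np.ceil((stop - start) / width - 1e-9))
        return cls(edges=start + width * np.arange(n + 1))


def assign_bins(
    subjects: Sequence[SubjectLesionMap],
    binning: CovariateBinning,
    policy: str = "error",
) -> np.ndarray:
    """Deterministic bin index per subject (half-open intervals, last closed).

    Out-of-range covariates raise by default, naming the subject; with
    ``policy="skip"`` they are flagged as index -1 and excluded downstream.
    """
    if policy not in ("error", "skip"):
        raise ValueError("policy must be 'error' or 'skip'")
    covs = np.array([s.covariate for s in subjects], dtype=float)
    edges = binning.edges
    idx = np.searchsorted(edges, covs, side="right") - 1
    idx[covs == edges[-1]] = binning.n_bins - 1  # close the last bin
    bad = (covs < edges[0]) | (covs > edges[-1])
    if np.any(bad):
        names = [subjects[i].subject_id for i in np.flatnonzero(bad)]
        if policy == "error":
            raise ValueError(f"covariate outside bin range for subjects: {names}")
        idx[bad] = -1
    return idx.astype(int)


def accumulate(
    subjects: Sequence[SubjectLesionMap],
    binning: CovariateBinning,
    mask: Optional[np.ndarray] = None,
    policy: str = "error",
) -> tuple[np.ndarray, np.ndarray]:
    """Sum subject maps into the count field ``R`` and bin sizes ``N``.

    ``R`` has shape ``grid + (n_bins,)``; ``N`` has shape ``(n_bins,)`` and
    broadcasts over space as ``N[None, None, None, :]``.  An optional 3D
    mask zeroes out-of-mask lesion voxels.
    """
    if len(subjects) == 0:
        raise ValueError("no subjects to accumulate")
    grid = subjects[0].volume.shape
    for s in subjects:
        if s.volume.shape != grid:
            raise ValueError(
                f"subject {s.subject_id}: grid {s.volume.shape} does not match "
                f"reference grid {grid}"
            )
    idx = assign_bins(subjects, binning, policy=policy)
    R = np.zeros(grid + (binning.n_bins,), dtype=np.int32)
    N = np.zeros(binning.n_bins, dtype=np.int64)
    for s, t in zip(subjects, idx):
        if t < 0:
            continue
        vol = s.volume if mask is None else (s.volume & (np.asarray(mask) > 0))
        R[..., t] += vol
        N[t] += 1
    return R, N


def empirical_average(R: np.ndarray, N: np.ndarray) -> np.ndarray:
    """Per-bin lesion frequency ``R / N``; empty bins are NaN (undefined)."""
    N = np.asarray(N, dtype=float)
    out = np.full(R.shape, UNDEFINED, dtype=float)
    nonempty = N > 0
    np.divide(R, N[None, None, None, :], out=out, where=nonempty[None, None, None, :])
    return out


def fill_empty_bins(average: np.ndarray, N: np.ndarray) -> np.ndarray:
    """Fill undefined (empty-bin) slices by linear interpolation along t.

    Bins outside the span of populated bins take the nearest populated
    bin's values.  Used to build a fully defined initialisation for the
    optimiser; the model itself needs no such fill because empty bins
    contribute zero likelihood.
    """
    N = np.asarray(N)
    defined = np.flatnonzero(N > 0)
    if defined.size == 0:
        raise ValueError("all bins are empty")
    out = np.array(average, dtype=float, copy=True)
    n_bins = average.shape[-1]
    for t in range(n_bins):
        if N[t] > 0:
            continue
        right = defined[np.searchsorted(defined, t)] if t < defined[-1] else None
        left = defined[np.searchsorted(defined, t) - 1] if t > defined[0] else None
        if left is None:
            out[..., t] = average[..., right]
        elif right is None:
            out[..., t] = average[..., left]
        else:
            w = (t - left) / (right - left)
            out[..., t] = (1 - w) * average[..., left] + w * average[..., right]
    return out
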