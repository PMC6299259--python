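"""NIfTI / CSV / YAML plumbing and the pipeline driver.

Conventions: voxel indices are 0-based everywhere; the NIfTI affine of the
reference grid is carried through to outputs but never used for resampling
(inputs are assumed already registered to a common space).  Undefined
voxels are encoded as NaN on disk and restored as the NaN sentinel.  Every
pipeline run writes a provenance block (config hash, seed, package
version) next to its outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .baselines import average_baseline, smoothed_average_baseline
from .cohort import CovariateBinning, SubjectLesionMap, accumulate
from .evaluate import knot_spacing_sweep, mse
from .optimize import OptimizerConfig, fit_map
from .permtest import two_group_max_t_test
from .simulate import SimulationConfig, simulate_cohort

__all__ = [
    "read_lesion_mask",
    "write_probability_field",
    "read_probability_field",
    "load_manifest",
    "run_pipeline",
]


def read_lesion_mask(
    path,
    binarize_threshold: Optional[float] = None,
    reference_shape: Optional[tuple] = None,
    reference_affine: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Load a 3D lesion mask, optionally binarising a probabilistic map.

    Values at or above ``binarize_threshold`` become 1 (the >= convention);
    an already-binary volume passes through unchanged.  The grid and affine
    are checked against the reference when given.  Returns
    ``(volume, affine)``.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: volume contains non-finite voxels")
    if reference_shape is not None and tuple(data.shape) != tuple(reference_shape):
        raise ValueError(
            f"{path}: grid {data.shape} does not match reference {reference_shape}"
        )
    if reference_affine is not None and not np.allclose(
        img.affine, reference_affine, atol=1e-4
    ):
        raise ValueError(f"{path}: affine does not match the reference affine")
    uniq = np.unique(data)
    if np.all(np.isin(uniq, (0, 1))):
        vol = data.astype(np.uint8)
    elif binarize_threshold is None:
        raise ValueError(
            f"{path}: volume is not binary and no binarize_threshold was given"
        )
    else:
        vol = (data >= binarize_threshold).astype(np.uint8)
    return vol, img.affine


def write_probability_field(
    field: np.ndarray,
    path,
    affine: Optional[np.ndarray] = None,
    bin_labels=None,
) -> Path:
    """Write a 4D probability field as NIfTI with a bin-label sidecar.

    NaN sentinels survive the round trip (float32 on disk).  The sidecar
    ``<stem>.bins.txt`` lists one label per covariate bin.
    """
    path = Path(path)
    field = np.asarray(field, dtype=np.float32)
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(field, affine), str(path))
    if bin_labels is None and field.ndim == 4:
        bin_labels = [str(t) for t in range(field.shape[-1])]
    if bin_labels is not None:
        sidecar = path.with_name(path.name.split(".")[0] + ".bins.txt")
        sidecar.write_text("\n".join(str(b) for b in bin_labels) + "\n")
    return path


def read_probability_field(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj).astype(float), img.affine


def load_manifest(path, binarize_threshold: Optional[float] = None):
    """Read a cohort manifest CSV into subject lesion maps.

    Columns: ``subject_id``, ``covariate``, ``path`` and optionally
    ``group``.  Relative mask paths resolve against the manifest location.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"subject_id", "covariate", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing required columns: {sorted(missing)}")
    subjects = []
    ref_shape = None
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = path.parent / p
        vol, _ = read_lesion_mask(p, binarize_threshold, reference_shape=ref_shape)
        ref_shape = ref_shape or vol.shape
        subjects.append(
            SubjectLesionMap(
                subject_id=str(row.subject_id),
                covariate=float(row.covariate),
                volume=vol,
                group=str(row.group) if "group" in df.columns else None,
            )
        )
    return subjects


# ---------------------------------------------------------------------------
# pipeline driver

_COMMON_KEYS = {"mode", "outdir", "seed"}
_MODE_KEYS = {
    "simulate": {"shape", "n_bins", "subjects_min", "subjects_max", "sigma",
                 "peak_probability", "write_subjects"},
    "aggregate": {"manifest", "bin_start", "bin_stop", "bin_width",
                  "binarize_threshold", "mask"},
    "fit": {"counts", "sizes", "mask", "knot_spacing", "max_iterations",
            "initial_step", "grad_tol"},
    "baseline": {"counts", "sizes", "mask", "method", "sigma"},
    "evaluate": {"estimate", "truth", "mask"},
    "permtest": {"manifest", "mask", "n_permutations", "binarize_threshold",
                 "knot_spacing"},
    "sweep": {"counts", "sizes", "mask", "truth", "spacings"},
}
_REQUIRED_KEYS = {
    "simulate": set(),
    "aggregate": {"manifest", "bin_start", "bin_stop", "bin_width"},
    "fit": {"counts", "sizes"},
    "baseline": {"counts", "sizes", "method"},
    "evaluate": {"estimate", "truth"},
    "permtest": {"manifest"},
    "sweep": {"counts", "sizes", "truth", "spacings"},
}


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _validate(cfg: dict) -> str:
    if "mode" not in cfg:
        raise ValueError("config is missing required key: mode")
    mode = cfg["mode"]
    if mode not in _MODE_KEYS:
        raise ValueError(f"unknown pipeline mode: {mode!r}")
    allowed = _COMMON_KEYS | _MODE_KEYS[mode]
    unknown = set(cfg) - allowed
    if unknown:
        raise ValueError(f"unknown config keys for mode {mode!r}: {sorted(unknown)}")
    missing = _REQUIRED_KEYS[mode] - set(cfg)
    if missing:
        raise ValueError(f"config is missing required keys: {sorted(missing)}")
    return mode


def _provenance(cfg: dict, outdir: Path):
    canon = yaml.safe_dump(cfg, sort_keys=True)
    block = {
        "config_sha256": hashlib.sha256(canon.encode()).hexdigest(),
        "seed": cfg.get("seed", 0),
        "version": __version__,
        "config": cfg,
    }
    (outdir / "provenance.json").write_text(json.dumps(block, indent=2, default=str))


def _load_mask(cfg, shape):
    if cfg.get("mask"):
        m, _ = read_probability_field(cfg["mask"])
        return m > 0
    return np.ones(shape, dtype=bool)


def run_pipeline(config) -> dict:
    """Execute one pipeline stage from a config mapping or YAML file.

    Modes: simulate, aggregate, fit, baseline, evaluate, permtest, sweep.
    Unknown keys are rejected rather than silently ignored.  Returns a
    summary dict; artefacts are written under ``outdir``.
    """
    cfg = _load_config(config)
    mode = _validate(cfg)
    outdir = Path(cfg.get("outdir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    _provenance(cfg, outdir)
    summary: dict = {"mode": mode, "outdir": str(outdir)}

    if mode == "simulate":
        sim = SimulationConfig(
            shape=tuple(cfg.get("shape", (91, 109, 91))),
            n_bins=int(cfg.get("n_bins", 60)),
            subjects_per_bin_range=(
                int(cfg.get("subjects_min", 1)),
                int(cfg.get("subjects_max", 50)),
            ),
            smoothing_sigma=float(cfg.get("sigma", 0.8)),
            peak_probability=float(cfg.get("peak_probability", 0.45)),
            seed=seed,
        )
        R, N, truth = simulate_cohort(sim)
        write_probability_field(R.astype(np.float32), outdir / "counts.nii")
        np.savetxt(outdir / "sizes.txt", N, fmt="%d")
        write_probability_field(truth.theta_true, outdir / "theta_true.nii")
        write_probability_field(
            sim.resolved_mask().astype(np.float32), outdir / "mask.nii"
        )
        summary["n_subjects"] = int(N.sum())

    elif mode == "aggregate":
        subjects = load_manifest(cfg["manifest"], cfg.get("binarize_threshold"))
        binning = CovariateBinning.regular(
            float(cfg["bin_start"]), float(cfg["bin_stop"]), float(cfg["bin_width"])
        )
        mask = _load_mask(cfg, subjects[0].volume.shape)
        R, N = accumulate(subjects, binning, mask=mask)
        write_probability_field(R.astype(np.float32), outdir / "counts.nii",
                                bin_labels=binning.labels)
        np.savetxt(outdir / "sizes.txt", N, fmt="%d")
        summary["n_subjects"] = int(N.sum())
        summary["n_bins"] = binning.n_bins

    elif mode == "fit":
        R, _ = read_probability_field(cfg["counts"])
        N = np.loadtxt(cfg["sizes"]).astype(int).reshape(-1)
        mask = _load_mask(cfg, R.shape[:3])
        opt = OptimizerConfig(
            initial_step=float(cfg.get("initial_step", 1e-3)),
            max_iterations=int(cfg.get("max_iterations", 50)),
            grad_tol=float(cfg.get("grad_tol", 1e-4)),
        )
        theta, C, diag = fit_map(
            R.astype(np.int32), N, kernel=int(cfg.get("knot_spacing", 2)),
            mask=mask, config=opt,
        )
        write_probability_field(theta, outdir / "theta.nii")
        write_probability_field(C, outdir / "coefficients.nii")
        diag.as_frame().to_csv(outdir / "fit_trace.csv", index=False)
        summary["iterations"] = diag.iterations
        summary["converged"] = diag.converged
        summary["objective"] = diag.objective_trace[-1]

    elif mode == "baseline":
        R, _ = read_probability_field(cfg["counts"])
        N = np.loadtxt(cfg["sizes"]).astype(int).reshape(-1)
        mask = _load_mask(cfg, R.shape[:3])
        method = cfg["method"]
        if method == "average":
            out = average_baseline(R, N)
        elif method == "smoothed_average":
            out = smoothed_average_baseline(R, N, float(cfg.get("sigma", 1.5)), mask)
        else:
            raise ValueError(f"unknown baseline method: {method!r}")
        write_probability_field(out, outdir / f"{method}.nii")
        summary["method"] = method

    elif mode == "evaluate":
        est, _ = read_probability_field(cfg["estimate"])
        truth, _ = read_probability_field(cfg["truth"])
        mask = _load_mask(cfg, est.shape[:3])
        value, report = mse(est, truth, mask, return_report=True)
        pd.DataFrame([{"mse": value, **report}]).to_csv(
            outdir / "mse.csv", index=False
        )
        summary["mse"] = value

    elif mode == "permtest":
        subjects = load_manifest(cfg["manifest"], cfg.get("binarize_threshold"))
        groups = sorted({s.group for s in subjects})
        if len(groups) != 2:
            raise ValueError(f"permtest needs exactly two groups, found {groups}")
        mask = _load_mask(cfg, subjects[0].volume.shape)
        res = two_group_max_t_test(
            [s for s in subjects if s.group == groups[0]],
            [s for s in subjects if s.group == groups[1]],
            mask,
            n_permutations=int(cfg.get("n_permutations", 500)),
            seed=seed,
        )
        nib.save(nib.Nifti1Image(res.stat_map.astype(np.float32), np.eye(4)),
                 str(outdir / "tstat.nii"))
        nib.save(nib.Nifti1Image((1 - res.p_corr_map).astype(np.float32), np.eye(4)),
                 str(outdir / "one_minus_pcorr.nii"))
        nib.save(nib.Nifti1Image(res.z_map.astype(np.float32), np.eye(4)),
                 str(outdir / "zstat.nii"))
        np.savetxt(outdir / "null_max_stats.csv", res.null_max_stats, delimiter=",")
        summary["n_significant"] = int(np.nansum(res.p_corr_map < 0.05))

    elif mode == "sweep":
        R, _ = read_probability_field(cfg["counts"])
        N = np.loadtxt(cfg["sizes"]).astype(int).reshape(-1)
        truth, _ = read_probability_field(cfg["truth"])
        mask = _load_mask(cfg, R.shape[:3])
        table = knot_spacing_sweep(
            R.astype(np.int32), N, [int(h) for h in cfg["spacings"]], mask, truth
        )
        table.to_csv(outdir / "knot_sweep.csv", index=False)
        summary["best_spacing"] = int(table.loc[table["mse"].idxmin(), "knot_spacing"])

    return summary
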