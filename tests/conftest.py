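"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pytest

import wmhatlas as wa


@pytest.fixture(scope="session")
def small_cohort():
    """Fast cohort for optimiser/evaluation unit tests (16x18x16, 6 bins).

    Uses an explicit two-bump base probability map with moderate levels so
    the tiny grid still carries lesion signal.
    """
    shape = (16, 18, 16)
    x, y, z = np.ogrid[: shape[0], : shape[1], : shape[2]]
    bump = lambda c, s: np.exp(
        -((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2) / (2 * s**2)
    )
    base = np.clip(0.02 + 0.45 * bump((5, 6, 8), 2.5) + 0.4 * bump((11, 12, 8), 3.0), 0, 0.5)
    cfg = wa.SimulationConfig(
        shape=shape, n_bins=6, subjects_per_bin_range=(2, 8), seed=5,
        mask=np.ones(shape, bool), base_probability=base,
    )
    R, N, truth = wa.simulate_cohort(cfg)
    return {
        "R": R,
        "N": N,
        "truth": truth.theta_true.astype(float),
        "mask": cfg.resolved_mask(),
        "config": cfg,
    }


@pytest.fixture(scope="session")
def scaled_cohort():
    """The standard scaled-down simulation fixture (45x54x45, 20 bins)."""
    cfg = wa.scaled_down_config(seed=1)
    R, N, truth = wa.simulate_cohort(cfg)
    return {
        "R": R,
        "N": N,
        "truth": truth.theta_true.astype(float),
        "mask": cfg.resolved_mask(),
        "config": cfg,
    }


@pytest.fixture(scope="session")
def scaled_fit(scaled_cohort):
    """Spline-model fit of the scaled-down fixture at knot spacing 2."""
    theta, C, diag = wa.fit_map(
        scaled_cohort["R"], scaled_cohort["N"], kernel=2, mask=scaled_cohort["mask"]
    )
    return {"theta": theta, "C": C, "diag": diag}
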