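"""Steepest-ascent MAP fitting with a safeguarded Armijo-Wolfe line search.

The coefficient field is fitted by maximising the binomial log-posterior
over the unconstrained latent field.  The search direction is the gradient
itself; the step size comes from a polynomial (quadratic-interpolation)
line search satisfying the Armijo sufficient-increase condition and, where
attainable within the safeguard bracket, the Wolfe curvature condition.

Step-size policy: the very first step tries the configured initial step
``gamma0`` (default 1e-3); every subsequent line search is safeguarded into
the bracket [0.1 * gamma0, 0.5 * gamma0], starting at the upper bound and
interpolating downwards on Armijo failure.  Iteration stops when the
decrease of the gradient 2-norm falls below ``grad_tol`` or after
``max_iterations`` steps (defaults 1e-4 and 50).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from . import cohort as _cohort
from .posterior import (
    DEFAULT_EPSILON,
    ModelState,
    grad_wrt_latent,
    latent_from_coefficients,
    log_posterior,
)
from .splines import Kernel1D, make_kernels, normalized_convolve, ALL_AXES

__all__ = [
    "OptimizerConfig",
    "FitDiagnostics",
    "DegenerateInitialization",
    "wolfe_line_search",
    "default_initial_coefficients",
    "fit_map",
]


class DegenerateInitialization(ValueError):
    """Raised for all-zero / all-one initial coefficient fields.

    At the box boundary the tanh reparameterisation saturates
    (sech^2(lambda) ~ 0), the gradient vanishes and the iteration cannot
    leave the starting point, so such starts are rejected up front.
    """


@dataclass
class OptimizerConfig:
    initial_step: float = 1e-3
    step_lower_frac: float = 0.1
    step_upper_frac: float = 0.5
    max_iterations: int = 50
    grad_tol: float = 1e-4
    wolfe_c1: float = 1e-4
    wolfe_c2: float = 0.9
    max_line_search_trials: int = 12
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self):
        if not (0.0 < self.wolfe_c1 < self.wolfe_c2 < 1.0):
            raise ValueError("require 0 < c1 < c2 < 1")
        if self.initial_step <= 0 or self.grad_tol <= 0:
            raise ValueError("initial_step and grad_tol must be positive")
        if not (0.0 < self.step_lower_frac < self.step_upper_frac <= 1.0):
            raise ValueError("require 0 < step_lower_frac < step_upper_frac <= 1")


@dataclass
class FitDiagnostics:
    """Per-iteration traces of the fit; the objective trace never decreases."""

    objective_trace: list = field(default_factory=list)
    grad_norm_trace: list = field(default_factory=list)
    step_trace: list = field(default_factory=list)
    converged: bool = False
    iterations: int = 0
    messages: list = field(default_factory=list)

    def as_frame(self):
        import pandas as pd

        n = len(self.objective_trace)
        return pd.DataFrame(
            {
                "iteration": np.arange(n),
                "objective": self.objective_trace,
                "grad_norm": self.grad_norm_trace,
                "step": [np.nan] + list(self.step_trace),
            }
        )


def wolfe_line_search(
    objective: Callable[[np.ndarray], float],
    gradient: Callable[[np.ndarray], np.ndarray],
    lam: np.ndarray,
    direction: np.ndarray,
    gamma0: float,
    config: OptimizerConfig,
    phi0: Optional[float] = None,
    dphi0: Optional[float] = None,
    allow_initial_step: bool = False,
) -> tuple[float, dict]:
    """Find an ascent step along ``direction`` from ``lam``.

    Returns ``(gamma, info)`` where ``info`` records the objective at the
    accepted point, the gradient there when it was evaluated, and which of
    the two Wolfe conditions hold.  Trial steps are confined to
    ``[step_lower_frac * gamma0, step_upper_frac * gamma0]`` (except for an
    optional first trial at ``gamma0`` itself); new trials come from
    quadratic interpolation of the line function, safeguarded to shrink by
    a factor in [0.1, 0.5] per rejection.  If the curvature condition is
    unattainable inside the bracket the bracket bound is returned with the
    Armijo condition holding; if no Armijo step is found within the trial
    budget the safeguarded minimum step is returned with a warning.
    """
    phi = lambda g: objective(lam + g * direction)
    if phi0 is None:
        phi0 = objective(lam)
    if dphi0 is None:
        dphi0 = float(np.vdot(gradient(lam), direction))
    if dphi0 <= 0:
        raise ValueError("direction is not an ascent direction (g.d <= 0)")
    c1, c2 = config.wolfe_c1, config.wolfe_c2
    lo = config.step_lower_frac * gamma0
    hi = config.step_upper_frac * gamma0
    t = gamma0 if allow_initial_step else hi
    best_armijo = None  # (gamma, phi)
    info: dict = {}
    for _ in range(config.max_line_search_trials):
        phit = phi(t)
        armijo = phit >= phi0 + c1 * t * dphi0
        if not armijo:
            if t <= lo * (1.0 + 1e-12):
                break
            # quadratic model of the line function through (0, phi0),
            # slope dphi0 and (t, phit); its maximiser, safeguarded
            denom = 2.0 * (dphi0 * t - (phit - phi0))
            t_new = dphi0 * t * t / denom if denom > 0 else 0.5 * t
            t = max(min(t_new, 0.5 * t), 0.1 * t, lo)
            continue
        best_armijo = (t, phit)
        g_new = gradient(lam + t * direction)
        dphit = float(np.vdot(g_new, direction))
        if dphit > c2 * dphi0:
            # step too short for curvature; expand within the safeguard
            if t >= hi * (1.0 - 1e-12):
                info.update(phi=phit, grad=g_new, armijo=True, curvature=False)
                return t, info
            t = min(2.0 * t, hi)
            continue
        info.update(phi=phit, grad=g_new, armijo=True, curvature=True)
        return t, info
    if best_armijo is not None:
        g, p = best_armijo
        info.update(phi=p, armijo=True, curvature=False)
        return g, info
    warnings.warn("line search found no admissible step; returning safeguarded minimum")
    info.update(phi=phi(lo), armijo=False, curvature=False)
    return lo, info


def default_initial_coefficients(
    R: np.ndarray,
    N: np.ndarray,
    kernels: Sequence[Kernel1D],
    mask: np.ndarray,
) -> np.ndarray:
    """Smoothed per-bin average, the recommended optimiser initialisation.

    The empirical average R/N is filled across empty bins by temporal
    interpolation and then smoothed with the model's own spline kernel (one
    normalised-convolution pass), so the starting point already lies in the
    span of the basis.
    """
    avg = _cohort.empirical_average(R, N)
    avg = _cohort.fill_empty_bins(avg, N)
    init = normalized_convolve(avg, mask, kernels, ALL_AXES)
    init = np.nan_to_num(init, nan=0.0)
    return np.clip(init, 0.0, 1.0)


def fit_map(
    R: np.ndarray,
    N: np.ndarray,
    kernel: Kernel1D | Sequence[Kernel1D] | int = 2,
    mask: np.ndarray = None,
    config: Optional[OptimizerConfig] = None,
    init: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, FitDiagnostics]:
    """MAP estimate of the 4D lesion probability field.

    Parameters
    ----------
    R, N : count field (x, y, z, t) and per-bin cohort sizes (t,).
    kernel : knot spacing (int), a single kernel, or four per-axis kernels.
    mask : 3D or 4D brain mask; voxels outside contribute nothing.
    config : optimiser settings; defaults follow the reference protocol.
    init : initial coefficient field in [0, 1]; default is the smoothed
        per-bin average.

    Returns ``(theta_hat, C_hat, diagnostics)``; ``theta_hat`` is NaN
    outside kernel reach of the mask and lies in [0, 1] elsewhere.
    """
    config = config or OptimizerConfig()
    if isinstance(kernel, (int, np.integer)):
        kernels = make_kernels(int(kernel))
    elif isinstance(kernel, Kernel1D):
        kernels = (kernel,) * 4
    else:
        kernels = tuple(kernel)
    if mask is None:
        mask = np.ones(R.shape[:3], dtype=bool)
    mask4 = np.asarray(mask)
    if mask4.ndim == 3:
        mask4 = np.broadcast_to(mask4[..., None] > 0, R.shape)
    else:
        mask4 = mask4 > 0

    eps = config.epsilon
    user_init = init is not None
    if init is None:
        init = default_initial_coefficients(R, N, kernels, mask4)
    init = np.asarray(init, dtype=float)
    if init.shape != R.shape:
        raise ValueError("initial coefficient field shape must match R")
    if np.nanmin(init) < -1e-12 or np.nanmax(init) > 1 + 1e-12:
        raise ValueError("initial coefficients must lie in [0, 1]")
    if user_init:
        # an all-zero / all-one start saturates tanh and cannot move; when
        # the *data-derived* default is at the boundary it already is the
        # boundary solution, so only user-supplied starts are rejected
        inside = init[mask4]
        if np.all(inside <= eps) or np.all(inside >= 1.0 - eps):
            raise DegenerateInitialization(
                "initial coefficient field is constant at the box boundary "
                "(all-zero or all-one); the tanh parameterisation saturates there"
            )

    lam = latent_from_coefficients(init, eps)
    state = ModelState(latent=lam, kernels=kernels, mask=mask4, epsilon=eps)
    diag = FitDiagnostics()

    def objective(latent):
        val = log_posterior(state, R, N, latent=latent)
        if not np.isfinite(val):
            raise FloatingPointError("non-finite objective encountered")
        return val

    def gradient(latent):
        g = grad_wrt_latent(state, R, N, latent=latent)
        if not np.all(np.isfinite(g)):
            bad = np.argwhere(~np.isfinite(g))[0]
            raise FloatingPointError(f"non-finite gradient at voxel {tuple(bad)}")
        return g

    obj = objective(lam)
    G = gradient(lam)
    gnorm = float(np.linalg.norm(G))
    diag.objective_trace.append(obj)
    diag.grad_norm_trace.append(gnorm)

    for it in range(1, config.max_iterations + 1):
        diag.iterations = it
        dphi0 = float(np.vdot(G, G))
        if dphi0 == 0.0:
            diag.converged = True
            diag.messages.append("zero gradient")
            break
        gamma, info = wolfe_line_search(
            objective,
            gradient,
            lam,
            G,
            config.initial_step,
            config,
            phi0=obj,
            dphi0=dphi0,
            allow_initial_step=(it == 1),
        )
        new_obj = info.get("phi", objective(lam + gamma * G))
        if not info.get("armijo", False) and new_obj < obj:
            diag.messages.append(
                f"iteration {it}: no ascent step found; stopping"
            )
            diag.iterations = it - 1
            break
        lam = lam + gamma * G
        state.latent = lam
        obj = new_obj
        G = info.get("grad")
        if G is None:
            G = gradient(lam)
        new_gnorm = float(np.linalg.norm(G))
        diag.objective_trace.append(obj)
        diag.grad_norm_trace.append(new_gnorm)
        diag.step_trace.append(gamma)
        # signed test: stop as soon as the norm no longer decreases by
        # more than grad_tol (a transient increase also stops)
        if (gnorm - new_gnorm) < config.grad_tol:
            diag.converged = True
            diag.messages.append(
                f"gradient-norm decrease below {config.grad_tol:g} at iteration {it}"
            )
            gnorm = new_gnorm
            break
        gnorm = new_gnorm

    theta = state.probability()
    C = state.coefficients()
    return theta, C, diag
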