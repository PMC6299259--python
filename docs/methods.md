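# Methods

## The estimation problem

Input: per-subject 3D binary lesion masks on a common grid, a scalar
covariate per subject, and a 3D brain mask.  Subjects are binned along
the covariate (half-open intervals `[e_k, e_k+1)`, last bin closed — a
declared convention; bin width is user-set).  The per-voxel, per-bin
lesion counts `R` out of bin sizes `N` are binomial observations of an
unknown probability field `θ(x, y, z, t)`.  Voxelwise maximum likelihood
(`R/N`) is unbiased but noisy — bins can hold one subject or none — so
`θ` is constrained to the span of a smooth basis.

## Spline representation

`θ` is a separable 4D cubic B-spline expansion of a coefficient field
`C` that lives on the full voxel grid; the knot spacing `h` enters as
the dilation of the sampled 1-D kernel `B3(k/h)`, support `|k| ≤ 2h−1`.
Evaluation is four sequential 1-D convolutions.  Because the kernel
tails cross the mask edge, the raw convolution is divided by the same
convolution applied to the mask indicator ("normalised convolution"):
constants are then reproduced exactly at every in-mask voxel, and the
kernel's overall scale cancels, so the taps are used un-normalised.
Out-of-mask voxels contribute nothing to the numerator.  `θ` is a convex
combination of in-mask coefficients, hence stays in `[0, 1]` whenever
`C` does.

Default knot spacing is 2 voxels on each spatial axis and 2 bins on the
covariate axis (the best setting in the knot-spacing sweep); the four
spacings are independently configurable because nothing forces the
covariate-axis scale to match the spatial one.

## MAP estimation

With a uniform prior the log-posterior is the binomial log-likelihood
(additive constants dropped).  Numerical choices:

- **Probability clamp** `ε = 1e−6` inside logarithms and gradient
  denominators: the likelihood is singular at `θ ∈ {0, 1}`, which
  all-zero or all-lesion voxels genuinely reach.  Where the clamp is
  active the gradient contribution is zero (the clamp is flat).
- **Box constraint** via `C = (1 + tanh λ)/2`; the chain-rule factor is
  `sech²(λ)/2`.  A printed side constraint `Σ C_i = 1` in the source
  formulation is *not* enforced: it is inconsistent with `θ` being a
  probability rather than a density, and with coefficient images that
  are visibly not normalised.
- **Gradient** `∂L/∂C_k`: the residual image
  `(R/θ − (N−R)/(1−θ)) / D` (with `D` the normalising image) correlated
  with the kernel; symmetry makes correlation equal convolution.  This
  is the exact derivative of the normalised-convolution model and
  matches central finite differences to < 1e−5 relative error (tested).
- **Optimiser**: steepest ascent.  First iteration tries the full
  initial step `γ0 = 1e−3`; each line search confines trials to the
  safeguard bracket `[0.1 γ0, 0.5 γ0]`, starting at the upper bound,
  shrinking by quadratic interpolation (safeguarded to a factor in
  `[0.1, 0.5]` per rejection) while the Armijo sufficient-increase
  condition fails, and expanding toward the bracket top while the weak
  Wolfe curvature condition fails.  If curvature is unattainable inside
  the bracket (e.g. a locally linear objective) the bracket bound is
  returned with Armijo holding, so accepted steps never decrease the
  objective and the trace is monotone.  Wolfe constants `c1 = 1e−4`,
  `c2 = 0.9`.
- **Stopping**: stop when the *decrease* of the gradient 2-norm falls
  below `1e−4` — a signed test, so a transient increase also stops —
  or after 50 iterations.  The signed reading is deliberate: with an
  absolute-difference reading the rule can never fire in regimes where
  `‖G‖` creeps upward.  Note the tolerance is absolute, so the
  iteration count at which it fires depends on problem size; on the
  scaled-down simulation the decrease stays near 2×10⁻³ per iteration
  and the fit runs to the 50-iteration cap while improving the
  objective only marginally past its initialisation.
- **Initialisation**: the per-bin empirical average, empty bins filled
  by linear interpolation along the covariate axis, smoothed once with
  the model's own spline kernel (self-consistent: the start lies in the
  basis span), then mapped through `atanh`.  User-supplied all-zero or
  all-one starts are rejected — `tanh` saturates there and the
  iteration cannot move; when the *data* makes the default start
  boundary-valued (e.g. every subject lesioned) it already is the
  boundary solution and is returned.

Empty covariate bins need no special handling in the likelihood: their
terms vanish (`R = N = 0`).

## Baselines

`Average = R/N` per bin (NaN sentinel for empty bins) and
`Smoothed_Average(σ)`: mask-aware Gaussian smoothing of the average
along all four axes (σ in voxel/bin units, identical across axes,
truncated at 4σ), using the same edge normalisation as the model so
constants survive at the mask boundary.  Smoothing across the covariate
axis as well as space is a declared choice; sentinel voxels are excluded
from the smoothing support and propagate to the output.

## Simulator

Each subject is a thresholded smoothed Gaussian field: standard-normal
noise is added to a latent mean `μ(x)` at in-mask voxels, smoothed with
a Gaussian kernel `K` (σ = 0.8 voxels, truncated at 4σ, mask-aware),
and thresholded at zero — smoothing correlates neighbours, so lesions
are clustered blobs rather than salt-and-pepper voxels.  The exact
per-voxel lesion probability is `θ_true = Φ(K∗μ / √(K²∗M))`, which the
Monte-Carlo frequency over 20 000 simulated subjects reproduces within
three binomial standard errors per voxel (tested at moderate
probabilities, where that normal band is statistically meaningful).

The latent mean is the probit of a target probability map,
`μ = Φ⁻¹(clip(p, 1e−4, 1−1e−4))`: in the no-smoothing limit this makes
`P(lesion) = p` exact, and it keeps near-zero background at near-zero
probability.  Note the variance term sharpens the link — the effective
truth is `Φ(Φ⁻¹(p)/s)` with `s ≈ 0.21` for σ = 0.8 — so base
probabilities below ≈ 0.3 collapse towards zero and only regions near
the peak survive as lesion cores.

The built-in target map emulates a WMH frequency atlas: four
anisotropic super-Gaussian plateau blobs (`exp(−r¹⁶/2)`) flanking the
midline as anterior/posterior periventricular caps, max-combined,
peaking at 0.45, modulated by a logistic ramp of the bin index
(midpoint 0.55, width 0.18 of the bin range) so probability rises
monotonically with "age".  The plateau-with-rim profile is chosen
because (a) real smoothed frequency maps are locally flat at the
lesion-smoothing scale, which narrow Gaussian bumps are not — under the
probit link those lose all lesions — and (b) plateau extents can be
sized to keep the map sparse (≥ 95 % of in-mask voxel-bin pairs below
0.01) while maximising the surviving core volume within that bound.
Defaults: 91×109×91 volumes, 60 bins, 1–50 subjects per bin (uniform);
the scaled-down protocol uses 45×54×45, 20 bins, 1–24 subjects per bin
(≈ 250 subjects).  A user base map (3D, ramp-modulated, or full 4D) can
replace the synthetic blobs.

What a green test does *not* establish: the synthetic truth carries far
less low-probability "carpet" than a real cohort frequency map — the
sparsity bound plus the probit collapse cap the error mass well below
what heavier real-world maps produce — so absolute MSE levels here are
smaller than those reported for real-map-driven simulations, while the
estimator *ordering* (spline ≈ moderate smoothing ≪ raw averaging;
heavy smoothing worst among smoothed variants at full scale) is the
meaningful, reproduced content.  Per-bin subject counts as low as 1
also make the Average baseline's MSE strongly seed-dependent.

## Permutation inference

Two-group comparison: per-subject binary maps are smoothed with the
model's spline kernel (variance stabilisation for binary data — a
declared choice), a pooled-variance unpaired t statistic is computed per
voxel (zero-variance voxels get t = 0, flagged), and family-wise error
is controlled by the null distribution of the image-wide max |t| under
random relabelling.  Corrected p-values use the add-one rule
`p = (1 + #{null maxima ≥ |t|}) / (n_perm + 1)`; z-scores are the signed
inverse-normal transform of p.  Covariate-effect test: the statistic is
the per-voxel least-squares slope of the fitted `θ̂` across bins (the
simplest monotone-trend measure); the null permutes subjects' covariate
values and refits per permutation, with failed fits redrawn and logged.

## Known limitations

- No spatial prior beyond the spline smoothness; no posterior
  uncertainty (point MAP estimate only).
- Registration, segmentation and resampling are out of scope: masks
  must already be binary and on the common grid.
- The absolute convergence tolerance makes the iteration count
  scale-dependent; on dense problems the optimiser often runs to the
  iteration cap while changing the smoothed-average initialisation only
  slightly (the initialisation is already near-optimal).
- The covariate-effect permutation test refits the model per
  permutation and is therefore expensive at full scale.
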