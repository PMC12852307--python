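# Methods

This note records the modelling assumptions, numerical choices and known
limitations behind `cohortgp`. It is written for users who want to know
exactly what the package computes, and why the defaults are what they are.

## Gaussian-process engine

Every emulator is an exact single-output GP. The model for standardized
training data `y = f(X) + ε`, `ε ~ N(0, σ_n²)`, is a GP with parametric mean
`h(θ)ᵀβ` (constant, or linear-plus-constant in every input; default linear)
and a stationary ARD kernel — squared-exponential by default, Matérn-5/2 as
an alternative. Kernels may be structured as a product of components acting
on disjoint input blocks; the Gram matrix is then the elementwise product of
the component correlation matrices (used by the latent-feature emulator).

Numerical choices:

* **Standardization.** Inputs are affinely mapped per dimension to [0, 1]
  over the training design; outputs to zero mean / unit variance. All
  reported quantities are back-transformed. This keeps hyperparameter
  optimization well-scaled regardless of the simulator's units.
* **Hyperparameter estimation.** Type-II maximum likelihood: L-BFGS-B on the
  log hyperparameters with analytic gradients. Mean coefficients are
  profiled out by generalized least squares at every likelihood evaluation
  (the envelope theorem makes the profiled gradient exact), or held fixed
  when supplied. Defaults: 5 restarts (restart 0 from the heuristic start —
  lengthscales 0.5 on the unit cube, unit signal variance, noise 1e-2 —
  later restarts from seeded log-normal perturbations), objective tolerance
  1e-6, bounds `lengthscale ∈ [1e-3, 1e3]`, `σ_f² ∈ [1e-8, 1e4]`,
  `σ_n² ∈ [1e-9, 1e2]` on the standardized scales. The best-of-restarts
  likelihood is non-decreasing in the restart budget by construction.
* **Jitter.** A nugget of `1e-8 × σ_f²` is added to the Gram diagonal,
  escalating tenfold on Cholesky failure up to 1e-2 of the diagonal scale
  before a conditioning error is raised. In the noiseless limit the
  posterior mean interpolates training data to within jitter × ‖α‖; on
  very smooth data with near-singular Grams this can reach ~1e-4, which is
  the price of an exact-interpolation model.
* **Fixed extra noise.** The likelihood covariance optionally includes a
  fixed per-point noise vector or a full noise covariance matrix, used to
  propagate reference-emulator uncertainty into the discrepancy GP.
* **Posterior sampling.** Joint draws use the Cholesky factor of the full
  posterior covariance with a relative nugget of 1e-10 of its largest
  diagonal entry; exactly degenerate posteriors return the mean. Marginal
  sampling is available. All sampling is seeded and bit-reproducible.

Serialization is a versioned JSON document (hyperparameters, transforms,
training data); no binary formats.

## Individual baseline

One GP per member per output, trained only on that member's rows — the
cohort-size-independent baseline. Subsampling to a budget m is uniform
without replacement from the member's training split, with a per-member
seeded stream (a CRC-stable hash of the member id), so a member's emulator
is bit-identical regardless of which other members exist. Matched-budget
ensembles split a total budget B as ⌊B/I⌋ per member, remainders going to
the first members in id order.

## Latent-feature emulator

The hybrid dataset concatenates rows `((θ_j; l_i), f_i(θ_j))` in member
order, then row order. The kernel is the product of a parameter-space
component and a latent-space component, each with its own ARD lengthscales
and the same family by default. Parameter and latent columns are
standardized independently (each to [0, 1] over the training rows) before
kernel evaluation; this choice is configurable by passing explicit
lengthscales. Latent vectors for held-out members are assumed known (as
when they come from a shape model); estimating latents from data is out of
scope.

The PCA extractor is a generic stand-in for anatomy-specific shape models:
latents are projections of centered per-member descriptor vectors onto the
top principal directions, with each mode's sign fixed by making its
largest-magnitude loading positive (reproducibility across BLAS builds).

The leave-one-member-out study reserves one member entirely, trains the
latent emulator on subsamples of the remaining members' 80% training splits
at each total budget, and evaluates on (a) left-in members' test rows —
member-level R² values are averaged — and (b) the held-out member's test
rows. The matched individual ensemble receives the same total budget split
evenly; in the left-out case each left-in emulator predicts the held-out
test rows and the scores are averaged.

## Discrepancy emulator

The new member is `f_{I+1} = Σ aᵢ fᵢ + δ`, with δ a GP on θ. Weights are
learned per output (outputs are emulated independently throughout). The six
strategies are dispatch options of one trainer:

* single-reference strategies pick the reference uniformly at random
  (seeded; re-drawn per evaluation replicate);
* the lasso solves `argmin_a Σ_j (y_j − Σᵢ aᵢ μ̂_i(θ_j))² + λ‖a‖₁` with no
  intercept and unstandardized predictors (weights stay interpretable
  mixture coefficients). The λ grid defaults to 20 log-spaced values
  spanning `[1e-4, 1e2] × max|Xᵀy|/m`; λ is chosen by seeded k-fold
  cross-validation (default 5 folds), ties broken toward the sparser
  solution. λ = 0 reduces exactly to least squares.
* weight-as-hyperparameter strategies maximize the marginal likelihood of
  the new member's outputs under mean `Σ aᵢ μ̂_i + h β` and covariance
  `Σ aᵢ² K̂ᵢ + K_δ + σ_n² I`, where `K̂ᵢ` are the full reference posterior
  covariance matrices at the training inputs. Weights are unconstrained in
  sign, bounded to [−10, 10] for optimizer stability, and initialized from
  the least-squares (cohort) or lasso (indicator) solution.
* the indicator strategy selects its support with a relative threshold
  `max(1e-6, 1e-3 × max|a|)`: reference-emulator error of order 1e-4
  otherwise survives as numerical-dust coefficients when cross-validation
  picks a near-zero λ. Elsewhere (reported `WeightVector.support`,
  `lasso_fixed`) the absolute tolerance 1e-6 applies.

When δ is fitted to residuals (fixed-weight strategies), the weighted
reference predictive variance `Σ aᵢ² κ̂ᵢ(θ_j, θ_j)` is added as fixed
per-point noise, consistent with the additive predictive variance; a
"plain residual" mode (`reference_noise="ignore"`) is available for
comparison. Joint strategies condition δ with the full reference covariance
as fixed noise. The structural non-identifiability of (a, δ) is accepted —
only predictions matter, not the weights themselves.

Prediction combines means and variances additively:
`mean = Σ aᵢ μ̂ᵢ(θ) + μ_δ(θ)`, `var = Σ aᵢ² κ̂ᵢ(θ, θ) + κ_δ(θ, θ)`.
Training touches only the new member's m rows and the already-fitted
references.

## Validation protocol

* `R² = 1 − RSS/TSS`; negative values mean worse than predicting the mean.
* Posterior R² averages R² over draws from the emulator posterior (1000 by
  default), drawn **jointly** over the test set (full covariance); marginal
  mode is available. Observation noise is not added to R² draws.
* ISE is the percentage of test points with `|y − μ| ≤ 2σ` (boundary
  inclusive), computed with the predictive sd including observation noise;
  a calibrated Gaussian predictive gives ≈ 95.4%.
* Splits are uniform 80:20 (`|train| = round(0.8 n)`); training subsets are
  re-drawn 5 times by default and scores averaged. The reported sd pools
  posterior draws across replicates, so it reflects both posterior and
  subsampling variability. In cohort-level tables, member-level mean R²
  values are averaged.

## Synthetic cohorts

Members share smooth basis functions `φ_b(θ)` (seeded mixtures of 10
Gaussian radial bumps with centers just outside the unit cube and widths
0.25–0.7, so the functions are smooth on [0, 1]^k and exactly evaluable
anywhere); member weights `w_b(l)` vary smoothly over latent space with
lengthscale `latent_smoothness` (latents uniform on [−1, 1]^d); an
independent member-specific term is scaled by `discrepancy_scale` (γ), and
optional iid Gaussian noise is added from a stream isolated from designs and
true functions. Designs are Latin hypercubes (one point per equal-width bin
on every margin).

Defaults mirror the whole-heart electrophysiology case-study shape
(19 members, 6 parameters, 9 latent modes, 180 simulations, 2 outputs) with
zero observation noise, since the emulated simulators are deterministic.
Small γ produces the high-similarity regime where transfer helps; large γ
produces members whose outputs vary wildly, where it may not.

What the generator does **not** emulate: the sharp gradients, boundary
effects and parameter interactions of real cardiac simulators, latents that
are genuinely PCA scores of anatomies (here they are uniform coordinates),
or heteroscedastic simulator error. Passing tests therefore demonstrate the
correctness and relative ordering of the methods under the assumed additive
latent structure, not clinical-grade accuracy on real ensembles.

## Experiment sizes

The test suite and the acceptance script run desk-scale versions of the
studies: cohorts of 5–19 members, 2–6 parameters, 40–180 simulations per
member, 2 optimizer restarts, and 200–500 posterior draws where full tables
use 1000. These sizes were chosen so the full suite completes in well under
a minute while leaving the observed effects (budget halving, support
recovery) far from their decision thresholds.

## Known limitations

* Exact GPs only: cost is O(n³) in the training size; the pooled latent
  emulator is the first to feel this (n = Σ mᵢ).
* No multi-output (correlated-output) GPs; outputs are emulated
  independently by design.
* Latent-feature extrapolation to members far from the training cohort is
  unreliable — left-out R² can be poor or negative, which the
  leave-one-member-out study makes visible rather than hiding.
* Additive discrepancy only; a multiplicative correction must be handled by
  transforming outputs (e.g. log) before training.
* Weight learning is per output; no sharing of support across outputs.
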