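# Methods

## Scope and data model

The package estimates component-wise tree biomass (trunk, branch, leaf, root;
oven-dry kg) from three predictors — diameter at breast height *D* (cm), total
height *H* (m) and crown radius *CR* (m) — for trees classified into three
stand-development groups: young (age ≤ 5 yr), middle-aged (≤ 15 yr) and
mature (> 15 yr). The literal class definitions leave ages in (5, 6)
unassigned; by default they fold into the middle class so every positive age
classifies, and a `strict=True` switch restores the literal intervals with
rejection. Total biomass is always the derived sum of the four components and
is never stored or modelled as an independent input.

Field dry weights are computed per component as Σ over segments of
fresh weight × mean(dry/fresh) over that segment's oven-dried subsamples.
Root biomass by data definition excludes fine roots below 2 mm; that is a
sampling convention, not a computation. When crown radius is not measured
directly, `crown_radius_from_widths` halves the mean of two perpendicular
crown widths; because field protocols differ on whether the published "crown
radius" was already halved, this conversion is opt-in and a CR column on
input is always taken verbatim. Group summary SDs use the n−1 divisor, the
standard choice for field-biometrics reporting.

## Candidate allometries and bias correction

Six log-linear forms per component and group (M1–M6, see the README) are fit
by OLS on natural logs; the log transform linearises the power law and
absorbs the multiplicative heteroscedasticity typical of biomass data, so no
additional weighting is applied. The lognormal retransformation bias is
removed with the Baskerville correction factor CF = exp(σ²/2).

Degrees of freedom for σ²: the classical CF presentation divides the residual
sum of squares by n − 2, which is exact only for two-coefficient models. The
default here is n − k for a k-coefficient candidate, so three- and
four-coefficient forms are not biased; `cf_df="paper"` forces n − 2 uniformly
for emulation of the older convention. The coefficient covariance is
σ²(X′X)⁻¹ under the same convention. Only natural logarithms are supported.

## Evaluation and selection

R² and MAPE are computed on the back-transformed, CF-corrected kg scale, not
the log scale. MAPE is the primary criterion; R² can reward overfitting
because it rises mechanically with added predictors. Selection per component
and group: a candidate is *eligible* only if every slope coefficient is
significant in a two-sided t-test (df = n − k) at α = 0.05 (strict p < α,
configurable); the intercept does not gate eligibility, since a tabulated
model with a non-significant intercept is still scientifically usable.
Among eligible candidates the lowest MAPE wins; ties (after rounding MAPE and
R² to 6 decimals, so float noise cannot manufacture distinctions) break by
higher R², then fewer coefficients, then lower model index. The
parsimony-then-index tie-break is a policy choice to make selection
deterministic — exact MAPE/R² ties occur in practice (e.g. when ln(D²H)
almost perfectly proxies b·lnD + c·lnH). If no candidate is eligible the
lowest-MAPE candidate is returned flagged as a fallback with a warning;
real datasets can produce this, so failing hard would be worse.

Exact interpolation (σ² = 0) is handled as the limit: a nonzero coefficient
is exactly determined (p = 0) and a zero coefficient is indistinguishable
from absent (p = 1). A zero standard error with positive residual variance
indicates a degenerate design and is an error.

## The additive SUR system

The four selected equations are re-estimated jointly by iterated feasible
GLS: per-equation OLS for starting residuals; Σ̂ᵢⱼ = (1/n) Σₜ eᵢ(t)eⱼ(t);
GLS on the stacked system with weight Σ̂⁻¹ ⊗ Iₙ; repeat until the largest
absolute coefficient change is below `tol` (default 1e-8) or `max_iter`
(default 100) is reached, in which case the last iterate is returned with
`converged=False` and a warning. Σ̂ is reported from the converged residuals.
Choices:

- **Σ̂ divisor n** (maximum-likelihood convention): the equations carry
  different coefficient counts, so no single df correction is exact;
  `sigma_divisor="df"` switches to the geometric-mean df correction.
- **Per-equation σ² and CF from the final system residuals** with the n − k
  convention: the joint system *is* the logarithmic regression once SUR has
  converged, so its residuals are the right basis for the correction factors.
- **The total-biomass line is a deterministic identity, not a fifth
  estimated equation**: the observed total is by construction the exact sum
  of the observed components, so a fifth equation adds no information, and
  the CF-weighted sum has no separately defined error term. Predicted total
  = Σ of bias-corrected component predictions, computed (never re-fitted), so
  additivity holds to machine precision. An experimental
  `total_as_equation=True` mode appends the arithmetic-scale total line and
  solves the stacked nonlinear system by Gauss–Newton (CFs held fixed within
  each iteration) for comparison with legacy system-fitting software; it
  mixes kg-scale and log-scale residuals in one covariance and is provided
  for experimentation only.
- **Degenerate cases**: a numerically singular Σ̂ (condition number > 1e12)
  is an error, with an optional ridge jitter on the diagonal behind an
  explicit flag (off by default). Noise-free data, where OLS already
  interpolates and Σ̂ is numerically zero, short-circuits to the OLS solution
  — the correct limit, since reweighting by a zero covariance is undefined.

Two classical equivalences serve as standing regression tests: with identical
regressor matrices across equations, or with Σ̂ forced diagonal, SUR
coefficients equal per-equation OLS (Kruskal). An independent dense oracle —
explicit 4n × Σk block design with a Kronecker weight matrix and whitened
least-squares solves — confirms the blockwise implementation to 1e-8.

## Synthetic inventory generator

The generator is the package's stand-in for the unpublished field data and
defines the conditions under which everything is tested:

- **Group sizes 18/19/35** (72 trees) and **per-group truncated-normal D**
  with mean/SD/min/max equal to the published group summaries (young:
  6.317 ± 2.759 cm on [2.5, 13.1]; middle: 12.747 ± 2.132 on [9.3, 16.8];
  mature: 23.12 ± 5.092 on [15.6, 36.3]). Truncated normal was chosen because
  exactly those four statistics are reported; sampling is by rejection with a
  cap of 10,000 attempts per draw.
- **ln H and ln CR as linear links on ln D** with Gaussian residuals. No
  joint (D, H, CR) distribution is published; the link coefficients are
  calibration constants chosen once from the published means and SDs assuming
  a within-group log-log correlation of about 0.9, so that generated H and CR
  land in the published envelopes. They are labelled as calibration constants
  in the source, not published values.
- **True biomass coefficients = the published jointly estimated (SUR)
  values** per group and component, on each group's selected model form.
- **Log-scale error SD 0.15 per component** (CFs near 1.01 — mild, realistic
  retransformation bias) with **cross-component correlation 0.5** by default;
  both overridable.

What the generator does *not* emulate: spatial or plot-level structure,
measurement error on predictors, age variation within groups, non-lognormal
error tails. Passing tests therefore demonstrate correctness of the
estimators under the model's own assumptions, not robustness to violations
real inventories may show.

## Diagnostics

Allocation fractions are computed per tree and then averaged within groups
(the mean of points on the simplex), not as ratios of group-mean biomasses;
the two differ whenever allocation covaries with tree size, and the per-tree
convention is the one consistent with published allocation percentages.
Group differences are tested with classical one-way fixed-effects ANOVA
(Welch's variant would be a natural extension but is not implemented).
Normality of total-biomass prediction residuals — observed minus predicted
totals on the kg scale — is tested with Shapiro–Wilk (scipy's Royston
approximation, 3 ≤ n ≤ 5000) and reported with normal Q-Q pairs at Blom
plotting positions (i − 0.375)/(n + 0.25), a common convention chosen here
as none is prescribed by the field protocol.

## Problem sizes used in tests and the acceptance script

Monte-Carlo checks use n = 2000 per group for predictor moments, n = 5000
for error-covariance and cross-correlation recovery, n = 300 for SUR
coefficient recovery, 200 replicates at n = 40 for the SUR-vs-OLS efficiency
comparison, 10,000 trees for correction-factor bias, and 2000 replicates for
ANOVA size and Shapiro–Wilk p-value uniformity. These sizes put Monte-Carlo
standard errors comfortably inside the asserted 3σ bands while keeping the
whole suite fast.

## Known limitations

- Only the log-linear (natural-log) forms are fitted; no nonlinear
  least squares on the original scale.
- No information criteria (AIC/BIC): selection is by MAPE, R² and
  coefficient significance only.
- The SUR system imposes no cross-equation parameter restrictions and no
  within-equation heteroscedasticity weighting.
- The synthetic generator's H/CR links are calibrated stand-ins; conclusions
  about link-model misspecification cannot be drawn from it.
- `total_as_equation` is experimental (see above) and not recommended for
  production estimates.
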