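# Methods

## Traits, scales, and standardization

The package works with three male traits: pronotum width (PN, mm, a body
size index) and mean dorsal / lateral darkness (MD, ML, pixel darkness in
0–255, proxies of thoracic melanism). Three scalings are supported, each
recorded on the trait table so transforms can be reversed exactly:

- **variance standardization** — (x−mean)/SD per trait, n−1 denominator
  everywhere. This is the scale on which selection gradients are estimated,
  so β and γ are per-phenotypic-SD.
- **mean standardization** — x divided by a reference taxon's trait mean
  (the *P. a. americana* museum means for cross-matrix work). This makes
  selection, variance and divergence dimensionless and directly comparable
  across matrices that were measured with slightly different protocols.
- **natural log** — supported for sensitivity analyses; errors on
  non-positive values.

Rows with any missing trait are dropped with a logged count; there is no
imputation.

## Selection gradients and canonical analysis

Relative fitness is w/mean(w). The linear model gives β; the full quadratic
model (linear + squared + pairwise product terms) gives γ, with the
squared-term coefficients doubled by default so that γ is the Hessian of
the quadratic approximation (a flag disables the doubling). β is reported
from the linear-only model, matching the conventional two-model
presentation; fits run through statsmodels OLS. Minimum sample sizes are
enforced (n > p+1 linear, n > p(p+3)/2 + 1 quadratic).

Canonical analysis diagonalizes γ; eigenvalues are reported in descending
order with θᵢ = mᵢ·β. m_max is the axis of the most negative eigenvalue.
Eigenvector signs are normalized so the largest-|loading| entry is
positive; since an eigenvector's sign is arbitrary, comparisons with
published loadings should align signs first (the tests do).

**Eigenvalue permutation test.** Fitness values are shuffled across
individuals (the phenotype distribution is held fixed, which is the
quantity the analysis conditions on), γ is re-estimated and
re-diagonalized, and null eigenvalues are rank-matched to the observed ones
by descending order. p = (1 + #{null as-or-more extreme in the observed
sign direction})/(n_perm + 1), one-tailed per axis by default (two-tailed
by flag). The (1+b)/(n+1) estimator avoids zero p-values. Calibration is
verified in the test suite: under a flat surface the most-negative-axis
test rejects at 4–6% nominal 5% (500 replicates × 200 permutations, n=50).

## Projection pursuit

Because γ's canonical axes inherit estimation error (and are biased toward
low-variance directions), the dominant surface direction is also estimated
directly: over random unit directions (Gaussian draws normalized to the
sphere) the scalar projection Z·a is smoothed against relative fitness with
a cubic smoothing spline (`scipy.interpolate.make_smoothing_spline`), and
the direction maximizing cross-validated explained deviance wins. The
smoothing grid −10..10 (step 2) is interpreted as the log of the spline
penalty. Scoring uses 5-fold cross-validation R² with seeded folds shared
across candidate directions (a leave-one-out score would need the smoother
hat matrix, which scipy does not expose). To keep the search tractable all
starts are screened at the middle grid value, the top 20 sweep the full
grid, and the best direction per grid value is refined by coordinate ascent
on the sphere. The result records the winning direction per smoothing
value; ridge-like surfaces should be stable across the grid, and the tests
require |corr| ≥ 0.95 across grid values for a planted one-dimensional
surface. Tied abscissae are merged to weighted means before the spline fit.

## P- and D-matrix estimation

**P** is the sample covariance (n−1) of a trait table. With a grouping
factor (rearing year), each group's columns are first divided by the
group's own trait means, then one covariance is taken over the pooled rows
— between-year shifts in multivariate means are removed without touching
within-year covariance structure. Note that after this pooling the result
is on the mean-standardized scale and, when group means differ
appreciably, equals the sample-size-weighted average of the per-group
mean-standardized covariances. Element-wise SEs come from a delete-one
jackknife: SE² = ((n−1)/n)·Σ(θ₍ᵢ₎ − θ̄)².

**D** is the covariance (n−1) of mean-standardized taxon mean vectors,
every taxon weighted equally regardless of its specimen count; the default
reader filter keeps taxa with at least 4 males. A MANOVA moment estimator
(MS_between − MS_within)/n₀, with n₀ the standard unbalanced-design
coefficient, is provided for individual-level data grouped by taxon; its
negative eigenvalues are truncated at zero with a log entry. A REML mixed
model would additionally give element-wise uncertainties but is out of
scope here; the moment estimator is the supported individual-level route.

Published matrices are printed ×100 (P) and ×10 (D) for readability; all
computation in this package is on the unscaled matrices, and the loaders
return unscaled values.

## Alignment and directional variance

ρ(a,b) = |a·b|/(‖a‖‖b‖). The permutation null shuffles each trait column
independently (pure permutation, no replacement), which destroys
covariance while preserving marginals, then recomputes the covariance
matrix and its designated extreme eigenvector; the reference vector is
held fixed and treated as error-free. p = (1 + #{ρ_null ≥ ρ_obs})/(n_perm+1).
Because marginal variances are preserved, this null retains any alignment
signal carried by the variances themselves: it asks specifically whether
the *covariance* structure sharpens the alignment. Near-degenerate extreme
eigenvalues (gap < 1e-8·trace) trigger a warning — the eigenvector is then
poorly identified and ρ should be interpreted cautiously.

e(m) = mᵀAm is the variance of A along m (directions renormalized with a
warning if not unit length). The random-direction average draws k uniform
unit vectors (Gaussian-normalize method); its expectation is trace(A)/p,
which the tests verify to 1% at k = 10⁵.

## Flury common-principal-components hierarchy

Two groups with covariance estimates S₁, S₂ and Wishart effective sample
sizes nᵢ = Nᵢ−1. Model fits:

- equality: pooled S̄ = ΣnᵢSᵢ/Σnᵢ; χ² = ΣnᵢlnΔ with Δ = det(S̄)/det(Sᵢ).
- proportionality: Σᵢ = ρᵢΣ by alternating ML updates
  (ρᵢ = tr(Σ⁻¹Sᵢ)/p, Σ = Σnᵢ Sᵢ/ρᵢ /N), scale fixed by ρ₁ = 1.
- CPC: common eigenvector matrix B minimizing Σnᵢ ln det diag(BᵀSᵢB),
  found by pairwise Jacobi-style rotations with the rotation angle of each
  pair solved by exact bounded 1-D minimization (monotone descent;
  convergence when the largest sweep angle < √tol; flat objectives from
  degenerate eigenvalues are left unrotated).
- CPC(1): one shared component; each CPC column is profiled as the
  candidate and the best is polished by direct search on the sphere, ties
  broken toward the largest pooled eigenvalue.

All likelihood-ratio statistics are χ² = Σnᵢ ln(det Σ̂ᵢ/det Sᵢ) against the
unrelated model ("jump-up"; the trace terms cancel at each constrained
MLE), with df 6/5/3/2 for equality/proportionality/CPC/CPC(1) at p = 3.
Step statistics are differences of adjacent jump-up values and therefore
sum to the equality χ². AIC counts free parameters relative to equality
(0/1/3/4 at p = 3, k = 2): AIC = χ²_jumpup + 2·(df_equality − df_jumpup).
No small-sample (Bartlett) correction is applied. Model selection: lowest
AIC ("model building") or the highest model in the hierarchy whose jump-up
test is not rejected at α = 0.05 ("jump-up"). On the published P/D pair the
AIC rule selects CPC; the jump-up rule as defined also stops at CPC, since
both equality and proportionality are rejected against unrelated at any
conventional level.

## Sexual dimorphism

d = √((μ_m − μ_f)ᵀ S⁻¹ (μ_m − μ_f)) on the mean-standardized scale. The
metric S is configurable: a supplied reference P, or a pooled within-taxon
both-sex covariance. Summary tables carry per-trait SDs but not
within-taxon covariances, so the pooled metric assembled from summaries is
diagonal (variances pooled with n−1 weights); pass a full reference P when
correlations should enter the metric. Taxa missing a sex, or with female
n < 2, are skipped with a log entry.

## Synthetic-data generator

Defaults emulate the study design: a selection sample of 44 males; a
two-year rearing sample of 50 + 58 with a small between-year mean shift;
37 taxa with 4–13 males each. Phenotypes are multivariate normal with the
published P (converted to the raw trait scale via the reference means);
taxon means are MVN around the published grand mean with the published D
plus within-taxon sampling noise P/n_k, and per-taxon SDs come from the
actual within-taxon draws. Two fitness surfaces:

- `quadratic_exact`: expected fitness max(0, 1 + βᵀz + ½zᵀγz) on the
  standardized scale with the published β, γ as defaults. The truncation
  at zero (quadratic surfaces are unbounded below) affects ~1% of draws
  under the defaults and shifts the estimand: the population OLS
  projection of the truncated surface has eigenvalues
  (0.201, −0.102, −0.543) rather than the planted (0.181, −0.094, −0.522).
  Recovery tests therefore target the truncated-surface projection
  (computed from population normal equations with 10⁶–2×10⁶ Monte-Carlo
  moment draws), plus a machine-precision check on an untruncated
  construction.
- `gaussian_surface`: expected fitness exp(−½(z−θ)ᵀΩ⁻¹(z−θ)); the default
  Ω puts weak curvature everywhere and strong stabilizing curvature along
  the published m_max. For z ~ N(0,R) the quadratic regression estimates
  β = R⁻¹μ*, γ = R⁻¹(Σ* − R + μ*μ*ᵀ)R⁻¹ with Σ* = (R⁻¹+Ω⁻¹)⁻¹ and
  μ* = Σ*Ω⁻¹θ; this closed form is the oracle for the recovery tests
  (note R is the trait correlation matrix — marginal standardization does
  not whiten correlated traits).

Realized fitness is the expected value (`none`), a Poisson count, or a
Bernoulli mated/not indicator scaled to a mean mating rate of 0.5
(default, matching a mating-success study design). All generators are pure
functions of (config, seed).

**What the synthetic tests do not show.** The generators are Gaussian with
exactly the assumed surface forms; they contain no measurement error, no
phylogenetic structure among taxa (a star phylogeny, as in the original
analysis), no temporal or spatial covariates of mating success, and no
skew or outliers. Passing recovery tests demonstrates correctness of the
estimators under their own assumptions, not robustness to violations.

## Numerical choices and limitations

- Covariance and SD denominators are n−1 throughout (this reproduces the
  published D variances from the taxon table; n does not).
- Permutation p-values use (1+b)/(n_perm+1) and are floored at
  1/(n_perm+1).
- Eigenvector sign convention: largest-|loading| entry positive; ρ-based
  tests are sign-free.
- FG rotations converge when the largest pairwise angle in a sweep falls
  below √tol (tol = 1e-10); non-convergence raises with diagnostics.
- The alignment permutation null preserves marginal variances; when the
  reference direction is close to a coordinate axis of small variance, the
  null can itself align well and the test is conservative. The published
  P-alignment (ρ = 0.78) is essentially unreachable under this null
  (p < 10⁻⁴); the D-alignment null (ρ = 0.82) is not, so its permutation
  p-value is substantially larger than the originally reported one — the
  package reports what its stated null implies.
- Reported problem sizes in the test suite (e.g. 500 calibration
  replicates × 200 permutations; recovery at n = 2×10³ and 5×10⁴) were
  chosen as the smallest sizes at which the Monte-Carlo error is clearly
  below the tolerances being asserted.
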