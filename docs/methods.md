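# Methods

## Model

Let y be a length-n trait vector over taxa (countries matched to
languages in the motivating application), X an n × k design with
intercept, Σ the matrix of shared root-to-tip path lengths on a rooted
tree with branch lengths in time units, and D the matrix of pairwise
great-circle distances between sample locations. The model is

y ~ N(Xβ, σ²·V),  V(λ, ϕ) = (1−ϕ)(1−λ)·I + (1−ϕ)λ·Σ* + ϕ·W,

with λ, ϕ ∈ [0, 1]. Σ* is Σ scaled to unit diagonal
(Σ*ᵢⱼ = Σᵢⱼ/√(hᵢhⱼ), hᵢ the root-to-tip depth); W maps distances to a
unit-diagonal similarity. Writing γ = (1−ϕ)(1−λ) and λ′ = (1−ϕ)λ, the
three weights partition 1 and are interpreted as the proportions of
modelled covariance that are independent, ancestral, and spatial. They
are proportions of modelled covariance, not of explained variance.

**Scale convention.** On an ultrametric tree Σ has the constant h on its
diagonal, so mixing (1−λ)h·I + λΣ and mixing unit-diagonal components
differ only by the global factor h, which the profiled σ² absorbs. We
adopt the unit-diagonal convention throughout so that I, Σ* and W sit on
a common variance scale and λ, ϕ read directly as covariance
proportions. For non-ultrametric trees (they arise here only as
branch-length-perturbed posterior surrogates) the geometric-mean scaling
√(hᵢhⱼ) is the natural generalization and keeps the diagonal exactly 1.

**Spatial similarity.** Raw distances cannot serve as a covariance
(zero diagonal, growing with separation). The default transform is the
linear decay w = 1 − d/d_max with d_max taken from the supplied matrix,
so the most distant pair has similarity 0 and the diagonal is 1; an
exponential kernel exp(−d/ρ) (ρ defaulting to d_max/3) is available as
an option. Distances use the haversine formula on a sphere of radius
6371.0 km. The linear transform is not guaranteed positive semidefinite;
see the repair policy below.

## Estimation and testing

σ² and β are profiled analytically at fixed (λ, ϕ):
β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y, σ̂² = rᵀV⁻¹r/n (maximum likelihood, not REML),
giving the profiled log-likelihood
ℓ = −n/2·log(2πσ̂²) − ½log|V| − n/2. The (λ, ϕ) grid is exhaustive on
[0, 1]² with step 0.02 (51 points per active axis); all 2601 Cholesky
factorizations are batched. Exact log-likelihood ties are broken toward
the smallest λ, then the smallest ϕ — parsimony toward the null.

Nested models (both weights / λ only / ϕ only / neither) are compared by
likelihood-ratio tests with χ² reference and df equal to the number of
freed parameters (1 for the single-parameter tests, 2 for the joint
test). Because the null pins a weight at the boundary of [0, 1], the
plain χ² reference is conservative; a ½χ²₀+½χ²₁ mixture option exists
for df = 1 but is off by default. Coefficient standard errors use the
unbiased residual scale rᵀV⁻¹r/(n−k) and a t reference with n−k degrees
of freedom, so at λ = ϕ = 0 the fit reproduces OLS inference exactly
(the sample sizes this model is used at — n ≈ 44 — are small enough for
the normal/t distinction to matter).

**Numerical policy.** V is factored by Cholesky. If factorization fails,
the smallest eigenvalue is inspected: below −1e−8 the matrix is treated
as genuinely indefinite and the fit errors; in (−1e−8, 0] the matrix is
ridged by 1e−10 + |min eig| (just enough to clear numerical noise) and
refactored. During the grid search a non-positive-definite V at a grid
point (possible at large ϕ with an indefinite W) sets that point's
log-likelihood to −∞ and excludes it from the argmax; only if every
point fails does the search error. Singular designs (collinear columns)
error immediately.

## Posterior-tree ensembles

Phylogenetic uncertainty is propagated by refitting the full grid on
every tree of a posterior sample (W is tree-independent and computed
once) and summarizing each parameter — λ′, ϕ, γ and every β — by its
mean and 95% HPD across trees, with significance reported as the mean
p-value across trees. The HPD is the shortest contiguous window of
sorted per-tree values containing ⌈0.95·n⌉ points, with ties resolved to
the lowest window; no kernel smoothing, since grid estimates are
discrete multiples of the step. Summaries are order-independent in the
tree list.

## Indicator preprocessing

Development-index panels (countries × years) are collapsed to one score
per country in a fixed order: (1) drop years missing for more than one
country; (2) z-score each remaining year across countries (n−1
denominator) to remove common secular trends; (3) average each country's
available standardized years. The order matters — averaging raw years
first would let trending years dominate — and a test asserts the two
orderings genuinely differ. A one-way ANOVA with country as the factor
and yearly values as replicates (run on raw values by default; an option
uses standardized values, as the description of the published procedure
is ambiguous on this point) reports F and η² = SS_between/SS_total to
justify the collapse. Bivariate screens are OLS with intercept and
t-based intervals. When religion percentages enter a regression design,
the residual "other" category is excluded to avoid the dummy trap; such
coding judgements (e.g. which countries count as formerly communist)
belong in the input table, not in code.

## Synthetic data

The generator makes every stage testable without external data and
defines the conditions under which the recovery results hold:

- **Trees:** pure-birth (Yule, rate 1) trees, tips relabeled in a fixed
  traversal order for per-seed determinism. Posterior-like variation is
  emulated by multiplying each branch by a lognormal variable with unit
  mean (σ_log = 0.1 by default), which preserves expected depths but
  breaks exact ultrametricity — handled by the covariance normalization.
- **Coordinates:** uniform in a lat 5–65°, lon −10–90° box, roughly the
  Eurasian span of the motivating study. Empirically the linear W from
  such boxes is positive definite.
- **Traits:** exact draws from N(Xβ, σ²V(λ, ϕ)) via Cholesky. In
  addition, `latitude_gradient_trait` builds an archetypal
  geographically autocorrelated trait — a standardized smooth function
  of latitude (cos lat, temperature-like) plus iid noise — generated
  from coordinates alone, so a correct fit must assign it to ϕ with
  negligible λ′; a test asserts exactly that.
- **Defaults:** n = 44 taxa (the study's sample size), σ² = 1 for
  weight-recovery experiments, σ² = 0.25 with β = −0.7 on a Bernoulli(½)
  binary covariate for fixed-effect recovery, grid step 0.02
  — matching the published analysis where stated, otherwise chosen once
  as realistic for this setting.

What the generator does **not** emulate: the real correlation between
phylogeny and geography produced by cultures expanding across the
landscape (coordinates here are independent of the tree), missing data,
non-Gaussian traits, and measurement error in the indices. Passing
recovery tests therefore show the estimator works when the model is
true; they do not bound the collinearity between ancestry and proximity
in real data, where single fits can share credit between λ′ and ϕ (the
worked example in the README shows exactly this on one draw).

## Problem sizes

The replicate counts used by the test suite and the acceptance script —
200 replicates for weight recovery, 500 for null calibration, 100
(ensembles of 3 perturbed trees) for fixed-effect recovery, 100 random
5–10-tip trees for the covariance oracle — were chosen as the smallest
sets that make the Monte-Carlo bands stable; the driver scripts under
`analysis/` use 25 replicates as a quick desk-scale illustration of the
same experiments.

## Known limitations

- (λ, ϕ) are estimated on a grid; no continuous refinement is attempted,
  so estimates are multiples of the step and HPDs can have zero width
  when every tree lands on the same grid point.
- The distance→similarity transform is a modelling choice the data
  cannot fully adjudicate; results at large ϕ can depend on it.
- Plain χ² LRT p-values at the boundary are conservative rather than
  exact.
- Listwise deletion is the only missing-data strategy in the regression.
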