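# psgls — joint phylogenetic–spatial generalized least squares

Cross-cultural traits — development indices, institutions, practices —
are not independent observations: countries inherit culture vertically
along language-family trees, and they exchange it horizontally with their
neighbours. `psgls` implements a generalized least squares regression
that models both sources of non-independence at once and asks how much of
the covariance in a trait each one accounts for.

The error covariance is a weighted mixture

```
V(λ, ϕ) = γ·I + λ′·Σ* + ϕ·W,        γ = (1−ϕ)(1−λ),  λ′ = (1−ϕ)·λ,
```

where Σ\* is the unit-diagonal Brownian-motion covariance implied by an
ultrametric phylogeny (shared root-to-MRCA path lengths), W is a
unit-diagonal similarity matrix built from pairwise great-circle
(haversine) distances between sample locations, and γ + λ′ + ϕ = 1.
λ measures ancestry signal, ϕ spatial signal. The pair (λ, ϕ) is
estimated by maximum likelihood over an exhaustive grid on [0, 1]² with
0.02 increments (51 × 51 = 2601 points; the scale σ² is profiled
analytically at each point), and tested with likelihood-ratio tests among
the four nested models (both / λ only / ϕ only / neither). Regression
coefficients for ordinary covariates (e.g. religion percentages, a
communism indicator) are estimated inside the same GLS. To propagate
phylogenetic uncertainty, the whole fit is repeated over a posterior
sample of trees and each parameter is reported as its mean, 95% highest
posterior density interval, and mean p-value across trees.

The package is aimed at comparative analyses of cultures or countries
linked by a language phylogeny, but nothing ties it to that setting: any
ultrametric tree plus coordinates works.

## Layout

- `src/psgls/` — the library: tree I/O and phylogenetic covariance
  (`phylo`), haversine distances and spatial similarity (`spatial`), the
  GLS model with grid search and LRTs (`model`), posterior-tree ensembles
  (`ensemble`), indicator-panel preprocessing (`indicators`), and the
  synthetic-data generator (`simulate`).
- `analysis/` — numbered driver scripts that run the full pipeline on
  synthetic data and write tables under `results/`.
- `scripts/acceptance.py` — recomputes the headline quantities from
  scratch (see below).
- A small CLI (`psgls fit`, `psgls simulate`) wraps the two entry points.

## Worked example

Simulate a strongly phylogenetic trait (true λ = 0.9, ϕ = 0) for 44 taxa
on a Yule tree with a 25-tree perturbed "posterior", then fit it:

```sh
python analysis/01_simulate_data.py
python analysis/02_single_tree_fit.py
python analysis/03_ensemble_fit.py
```

which prints (single generating tree, then the 25-tree ensemble):

```
ML weights on tree 1: lambda = 0.94, phi = 0.36 (lambda' = 0.602, gamma = 0.038)
log-likelihood -32.988; LRT p: lambda = 3.49e-07, phi = 0.000116, joint = 4.98e-07

parameter      mean    hpd_lo    hpd_hi       mean_p stars
lam_prime  0.611248  0.601600  0.633600 3.571646e-07   ***
      phi  0.353600  0.340000  0.360000 1.188441e-04   ***
    gamma  0.035152  0.025600  0.039600 5.092010e-07   ***
intercept -0.232105 -0.255666 -0.209775 6.401102e-01
```

The ancestry test is decisive (λ̂ = 0.94, p ≈ 3·10⁻⁷) and its HPD across
trees is tight. A nonzero ϕ̂ also appears on this particular draw: tree
expansion across the landscape makes ancestry and proximity genuinely
correlated, which is why single draws can share credit between λ′ and ϕ.
Across replicates the estimates centre on the truth —
`analysis/04_identifiability.py` repeats the fit at several true
(λ, ϕ) pairs and reports, at 25 replicates each, mean λ̂ = 0.90 for purely
phylogenetic traits, mean ϕ̂ = 0.80 for purely spatial traits, and an 8%
rejection rate of the ancestry test under the null (the boundary null
makes the plain χ² reference conservative).

`analysis/05_indicators.py` runs the indicator preprocessing on a
synthetic development panel: drops years missing for more than one
country, z-scores each year across countries, averages per country, and
shows the country ANOVA (η² = 0.958 on that panel) that justifies
collapsing years.

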