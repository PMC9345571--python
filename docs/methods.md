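# Methods

## The estimation problem

A closed population of unknown size `N` is sampled by `K` lists
(sampling events, service rosters). Individual `j`'s capture history is
the binary vector `(y_j1, ..., y_jK)`; the all-zero history is
unobservable, so the data are the counts of the `2^K − 1` observable
histories, with observed total `n`. Every estimator in this package is
an extrapolation rule for the unobserved count `n0 = N − n`. The
difficulty is fundamental: without assumptions on how encounter
probabilities vary, `N` is not identified, and different plausible
models can fit equally well while extrapolating very differently. The
package exists to measure that gap under controlled conditions.

## Synthetic data

Encounter indicators are beta-Bernoulli: `y_jk ~ Bernoulli(p_jk)` with
`p ~ Beta(β₁, β₂)`. Shapes are solved from a mean `m` and coefficient
of variation `cv` via `s = (1−m)/(m·cv²) − 1`, `β₁ = ms`,
`β₂ = (1−m)s`, feasible iff `m(1+cv²) < 1`. The study grid uses
`m ∈ {0.025, 0.05, 0.10, 0.15, 0.20}` at `cv = 0.85` (Beta standard
deviations 0.021–0.170), `N ∈ {1,000; 10,000; 20,000}`, `K = 5` lists
truncated downstream to cumulative sets of 2–5, and 400 replicates per
cell (36,000 samples in the full design). These grid values are the
study conditions, not tuning knobs.

Pattern constructions (the taxonomy is classical; the composition
mechanics below are this package's own choices, since only the marginal
ingredients are pinned down by the taxonomy):

- **Mh** — one Beta draw per individual, constant over lists. This is
  the construction under which the closed-form first-encounter
  expectation `E[p₁(k)] = B(β₁+1, β₂+k−1)/B(β₁, β₂)` holds exactly; it
  is decreasing in `k` (the easily-seen are seen first) and its partial
  sums give the expected observed fraction used to validate the
  generator.
- **Mt** — one Beta draw per list, shared by all individuals.
- **Mb** — constant first-capture probability `m`; after an
  individual's first capture their probability is multiplied by
  `behavior_multiplier` (0.5 in the study) for all later lists.
- **Mth** — individual draw times `(list draw / m)`, clipped to [0, 1];
  **Mbh** — behavioral multiplier applied to the individual draw;
  **Mtbh** — all three composed.

These composites preserve each effect's marginal mean while creating
the intended dependence signatures, but they are *one* choice among
several defensible ones, and the clipping in Mth slightly inflates
effective heterogeneity. Pooled-cell performance numbers are sensitive
to this choice (see Limitations). All-zero histories are removed at
generation and again after truncation to fewer lists, since an
individual seen only on list 5 is unobservable in a 3-list analysis.

Seeding: one master seed per study; each sample's seed derives
deterministically from (master, replicate, pattern, mean, N) through a
`SeedSequence`, so any cell is re-runnable in isolation and reruns are
byte-identical.

## LLM-AIC

Observable counts are independent Poisson cells with
`log μ_ω = x(ω)'β`. Covariates: number of captures `c(ω)` (M0/Mh/Mb
families), per-list indicators (Mt families), post-first-capture
exposure `K − f(ω)` with `f` the first-capture list (behavioral
families), and a heterogeneity column `h(c)` with `h(0) = 0`
(Poisson2 `2^c − 1`, Darroch `c²/2`, Gamma3.5 `−log(c+3.5)+log 3.5`).
Fits use iteratively reweighted least squares (statsmodels GLM);
`AIC = −2·loglik + 2·(#coefficients)`.

Abundance: for M0/Mt/Mh/Mth every covariate vanishes at the all-zero
history and the generative model is loglinear there too, so
`N̂ = n + exp(β̂₀)` is the model's own extrapolation. For behavioral
models that convention is *inconsistent* (the exposure covariate has no
natural value at the unobserved cell; on an exact Mb table it inflates
N by ~40%). Instead the fitted coefficients are back-transformed to the
behavioral parameters — recapture probability `c = expit(β̂_captures)`,
first-capture probability from the behavior coefficient — and the zero
cell is `exp(β̂₀)(1−p)c / (p(1−c))`, which recovers `N` exactly on an
exact Mb table. This follows the "improved" loglinear abundance
estimators tradition used by the standard R implementations.

Selection: the AIC comparison menu holds Mb, Mt, Mbh(Poisson2), and
Mh/Mth under each correction; the winning *family* is what model
matching reports, and the recorded estimate is the Poisson2 variant of
that family (the correction whose estimates the benchmark tabulates).
With a Poisson2-only pool, Mbh nests Mh with one extra parameter and
falsely wins ≈16% of Mh-generated samples (the χ²₁ > 2 tail); the
multi-correction menu restores the high match rates seen in practice,
because on heterogeneous data a better-fitting Mh variant must be
beaten before Mbh can claim the family. For K = 2 only {M0, Mt} are
estimable (3 cells) and the Mt fit is saturated, reproducing the
Petersen estimator `n₁n₂/m` exactly.

Intervals: profile likelihood over integer `N`. The multinomial profile
at a candidate `N` is computed by completing the table with `N − n` in
the zero cell (a Poisson GLM refit for intercept-extrapolating models;
direct numerical maximization with the back-transformed zero cell for
behavioral models) and the interval is
`{N : 2(l_max − l(N)) ≤ χ²₁(0.95)}`, found by climb-and-bisect with a
deviance tolerance at integer resolution. The upper bound is capped at
`n(1 + 20)` by default; hitting the cap and one-sided profiles are
flagged, not silently truncated. Estimates beyond `10^9` are retained
in summaries and rendered with the `> 10^9` sentinel.

## LLM-BMA

All decomposable (chordal-graph) loglinear models on the K lists —
8, 61, 822 for K = 3, 4, 5, enumerated by brute force with a
chordality test and junction-forest factorization — carry a
hyper-Dirichlet prior with per-cell hyperparameter `δ = 2^−K`; a margin
over a subset `A` inherits `δ·2^{K−|A|}` per cell, so every margin is a
symmetric Dirichlet with total concentration 1. The marginal likelihood
of a completed table (observed cells plus `n0` in the zero cell) is the
multinomial coefficient times the product over cliques of
Dirichlet-multinomial normalizers divided by the same over separators,
all in log-Gamma arithmetic; summing it over all completed tables at a
fixed total equals 1, which the tests verify by enumeration.

The posterior is computed *exactly* on the integer grid
`n0 = 0..n0_max` (no Laplace approximation — exactness on a finite
grid is affordable here because the per-margin log-Gamma vectors are
shared across the hundreds of models containing that margin). Study
runs use `n0_max = 10·N_true`, the "known within an order of magnitude"
premise. The prior on `N` is `p(N) ∝ 1/N` restricted to the grid
(configurable to uniform); the prior over models is uniform. The point
estimate is the posterior median of `N` and the interval the central
0.95 quantiles of the averaged posterior. K = 2 is rejected: with three
observable cells the averaging set degenerates, matching the
reference-implementation limitation.

## BLCM

A truncated stick-breaking Dirichlet-process mixture of
product-Bernoulli capture profiles: at most `K* = 10` classes,
`V_c ~ Beta(1, α)` sticks with the last stick absorbing the remainder,
`α ~ Gamma(0.25, 0.25)`, and `λ_ck ~ Beta(1, 1)` capture probabilities.
Gibbs cycle: (1) class-assignment counts per observed history and for
the `n0` augmented all-zero individuals (multinomial conditionals on
sufficient statistics, so the per-iteration cost is independent of N);
(2) `λ` from Beta conditionals; (3) sticks; (4) `α` from its Gamma
conditional; (5) `n0 ~ NegBin(n, 1 − p0)` with `p0` the current mixture
probability of the all-zero history (the `1/N`-prior form). Point
estimate: posterior median of `N = n + n0`.

Numerics: stick fractions are drawn through their log-Gamma
representation (`Gamma(a+1)` boost) because linear-scale draws
genuinely underflow — a Beta draw rounds to 1.0 when one class holds
nearly all mass, and a `Gamma(α)` draw with small `α` rounds to 0 —
which would poison `log(1−V)` in the `α` update. Non-finite conditional
parameters raise; they are never clamped. If `p0` underflows to exactly
0, `n0` is 0 with a logged warning.

Chain lengths: the package default is a 10,000-iteration burn-in with
100,000 retained-phase iterations thinned by 10; the `paper_full`
preset (500,000 / 5,000,000 / 100) matches the full-study
configuration and is hours-scale; the `desk` preset
(1,000 / 5,000 / 5) is used by the reduced acceptance runs and gives
split-chain R̂ < 1.05 on log N for the designs simulated here. With
`max_classes = 1` the sampler agrees with an exact grid-integration
posterior for the one-class model, which the tests check.

## Evaluation

RMSE `√(1/m Σ(N − N̂ᵢ)²)`, bias `mean(N̂) − N`, and 0.95-interval
coverage per (N, E(p), K, method) cell, pooled over the six generating
patterns — the analyst never knows the true pattern, so pooled
performance is the operative measure. Non-finite and `> 10^9` estimates
stay in the means (producing the sentinel renderings) rather than being
excluded; failed fits count as non-covering. Relative RMSE (RMSE/N) is
emitted for cross-size comparison. Model matching tabulates the AIC
winning family against the generating pattern for the five
loglinear-generating patterns.

## Problem sizes used in the shipped checks

The analytic and structural layers are exact and instant. The
simulation layer uses the anchor cell N = 1,000, E(p) = 0.200, five
lists: the loglinear comparison at the full 400 replicates per pattern
(GLM fits are cheap), and the two Bayesian estimators at 50 replicates
per pattern with the `desk` MCMC preset — the package's chosen
desk-scale trade-off between Monte-Carlo error and turnaround.

## Known limitations

- The composite-pattern constructions (Mth, Mbh, Mtbh) are recorded
  choices, not uniquely determined by the pattern taxonomy; pooled
  RMSE/bias in cells dominated by those patterns shifts by tens of
  individuals under alternative defensible constructions. Agreement
  with published pooled anchor-cell values is therefore qualitative
  (same ordering of methods, same scale) rather than exact; the
  per-pattern Mh/Mt/Mb quantities, whose constructions are pinned
  down, reproduce closely.
- The model-averaged posterior is exact Bayes for the decomposable
  hyper-Dirichlet family (its intervals are calibrated when data come
  from that family, which the tests verify by simulation). Under strong
  beta-Bernoulli heterogeneity the average concentrates on dense graphs
  that attribute the list dependence to interaction rather than to a
  large unseen stratum, so its credible intervals can sit low and
  narrow — reported coverage for this estimator on heterogeneous data
  is implementation-sensitive across the literature's tools.
- The Chao-style lower-bound heterogeneity model is not in the
  correction set, so the AIC menu is slightly less protective of the
  Mh family than a workflow that includes it.
- The generator models sampling inhomogeneity only; real key-population
  surveys add refusal, mark misidentification, and population openness,
  none of which are modeled. Passing tests show estimator behavior
  under the stated stochastic models, not under field conditions.
- BLCM chain-length defaults are tuned to the simulated designs;
  sparser data (smaller E(p), K = 2) mixes more slowly and may need the
  longer presets.
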