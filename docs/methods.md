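# Methods

## Model and estimand

The package works on a causal directed acyclic graph G over named variables
in which each node obeys the local Markov property: conditional on its
parents it is independent of its non-descendants.  For a specific directed
path X₁ → X₂ → … → X_K → Y the quantity of interest is the effect
transmitted along that path alone, expressed through per-edge average
causal effects ACE{A → B | do(x′), do(x″)} = E[B | do(A=x′)] − E[B | do(A=x″)].

Because each node on the path is confounded with its on-path parent only
through the child's remaining parents, every edge effect is identified by
back-door adjustment for C = parents(B) \ {A}.  Under either of two
homogeneity conditions — the conditional slope ∂E(Y|c, x₂)/∂x₂ does not
depend on c, or the conditional mediator shift E(X₂|c, x₁′) − E(X₂|c, x₁″)
does not depend on c — the path effect factorizes into the product of the
per-edge effects, divided by ∏ᵢ(xᵢ′ − xᵢ″) over the interior mediators when
those are estimated on a level-contrast scale.  The package computes the
product in all cases and documents that its causal reading requires one of
these no-interaction-with-C conditions; no test of the condition is
performed.  With the derivative (regression-slope) convention for
continuous children the divisor is identically 1, which is the default.

Estimators:

* **continuous child** — OLS of B on (A, C); estimate is the coefficient of
  A, variance from the usual OLS covariance.
* **binary child** — model-based standardization: a main-effects logistic
  model of B on (A, C) is fitted and predicted risks are averaged over the
  empirical covariate distribution at A = 1 and A = 0.  The nonparametric
  stratified sum Σ_c P̂(c)[P̂(B|1,c) − P̂(B|0,c)] is available as
  `estimator="stratified"`; the two coincide exactly for saturated models
  and serve as mutual cross-checks.  A `"coef"` effect scale (raw logistic
  coefficient of A) exists for sensitivity analyses.
* **ordered discrete child** — the mean difference written as a sum of CDF
  differences over adjacent levels; reduces exactly to the binary risk
  difference for two levels.  Note the level ordering is load-bearing,
  hence unordered level declarations are rejected.

Interaction terms are not added to adjustment models (main-effects only);
this is a known limitation when the no-interaction conditions fail badly.

## Two-group statistic and inference

With disjoint samples for the two conditions, PSE_g = ACE_g/S_{ACE_g} and
the test statistic for H₀: PSE₁ = PSE₀ is the studentized difference.  The
standard error S_ACE has no canonical estimator; two are provided:

* **bootstrap** (default for reporting): standard deviation of the path
  product over B resamples drawn with replacement within the group
  (B = 500 for SEs, 1000 for CIs by default; degenerate resamples are
  skipped and counted, >10% skips is an error);
* **delta**: the product (Sobel) formula Var(∏eᵢ) ≈ Σᵢ(∏_{j≠i}eⱼ)²Var(eᵢ)
  over the per-edge model variances, treating edge fits as uncorrelated and
  the empirical covariate distribution as fixed.

The permutation and bootstrap tests and the Monte-Carlo harness use the
delta standardization: the statistic is then a closed-form function of each
resample, which keeps the resampling single-level (a bootstrap SE inside
every permutation would add a third resampling tier at ~100× the cost for
no change in permutation validity, which only requires exchangeability
under H₀).  Var(PSE₁ − PSE₀) is estimated as Var(PSE₁) + Var(PSE₀) since
the groups are independent samples; the bootstrap variance of the
standardized quantity is used rather than asserting the asymptotic value 1,
because finite-sample standardizations are noisy.

The permutation statistic is the plain difference PSE₁ − PSE₀ (the
permutation distribution supplies its own scale); p-values are two-sided
with the add-one convention (1 + #{|T_b| ≥ |T_obs|})/(B + 1), so p ≥
1/(B+1).  An exact variant enumerates all label assignments for small
samples.  Bootstrap resampling is stratified by condition so group sizes
stay fixed.

Bootstrap intervals: `normal` (θ̂ ± z·se_B), `basic` (order statistics of
θ* at indices ⌈(B+1)q⌉ clipped to [1, B]), `percentile` (the reflected
2θ̂ − θ* form) and `bca`.  **Naming caution:** the `basic`/`percentile`
labels here follow the formulas as this method family prints them, which
is swapped relative to the most common textbook convention; the aliases
`percentile_classic` → `basic` and `basic_classic` → `percentile` map the
conventional names onto the formulas.  BCa uses the median-bias constant
z₀ = Φ⁻¹(#{θ* < θ̂}/B) and the jackknife-skewness acceleration; the
jackknife is leave-one-out for small samples and leaves out one of 25
equal blocks per group above 250 rows per group (remainder rows always
kept), a standard grouped-jackknife approximation adopted so BCa stays
usable inside Monte-Carlo loops.  If every θ* falls on one side of θ̂ or
the jackknife variance is zero, BCa is unavailable and the order-statistic
interval is substituted with a warning.

## Graph handling

Paths are enumerated by exhaustive simple-path search (the intended graphs
have tens of nodes; a configurable `max_paths` ceiling errors out instead
of silently truncating), ordered shortest-first then lexicographically.
Parallel paths are analyzed one at a time — the statistic targets a single
specific path, so "merging" direct and indirect routes is reported as the
list of enumerated paths rather than by collapsing edges.  Simplification
removes exactly the nodes with no directed route into the path or its
adjustment sets, interpreted structurally as graph reachability; such nodes
cannot open a back-door path, so removal leaves every estimand unchanged
(property-tested).  All orderings (nodes, paths, covariates) are
deterministic so outputs are byte-reproducible at a fixed seed.

## Synthetic data generator

Binary networks are generated node by node in topological order:

  root ~ Bernoulli(p₀),   child ~ Bernoulli(expit(α₀ + Σⱼ βⱼ(paⱼ − p₀))),

with per-condition coefficient maps; "a vs b" means β = a in the control
condition and β = b in the case condition on that edge, so δ = b − a.
Continuous networks replace the Bernoulli draws with child = α₀ + Σβⱼpaⱼ +
N(0, σ).  Fixed constants, chosen once as symmetric and non-degenerate
defaults: α₀ = 0, p₀ = 0.5, σ = 1, and every non-differential edge at 0.5
in both conditions.

Two calibration choices deserve emphasis.  First, binary children are
driven by **centered** parent values (paⱼ − p₀).  With raw 0/1 parents and
positive coefficients, prevalences drift toward 1 down the graph and risk
differences saturate, which makes power *non-monotone* in the coefficients;
centering keeps every node near prevalence ½ in both conditions without
affecting identification (it only shifts each child model's intercept).
Second, stated grid sample sizes are read as **totals** split equally
across the two conditions, as in a case-control study of "N subjects".
Both choices, and the treatment of the fourth target-path edge in the
δ grids (differential by default, toggleable), are exposed as parameters.

What the generator emulates: a faithful causal Markov factorization with
main-effects logistic/linear mechanisms, exchangeable subjects, and exactly
the declared between-condition differences.  What it does not emulate:
interactions, unmeasured confounding, selection, measurement error, or
model misspecification (real mechanisms are not main-effects GLMs).  A
passing simulation therefore shows correctness of the estimators and the
calibration of the tests under the generating model, not robustness of the
method on real data.

## Monte-Carlo harness and problem sizes

`run_mc` repeats generate → test → record-rejection with per-replicate RNG
streams spawned from a single root seed (results independent of evaluation
order); rejection rates carry the binomial Monte-Carlo standard error
√(r(1−r)/reps).  `table_experiment` instantiates the standard grids T1–T8.
Defaults are 1000 replicates with B = 199 permutations; the test suite and
the acceptance script run reduced desk-scale versions (200 replicates for
type-I cells, 120–150 for power cells) chosen so the whole evaluation
completes in minutes on one CPU, with all comparisons carried out at
tolerances of ±0.07 absolute or 3 Monte-Carlo standard errors.

The resampling engine exploits that in an all-binary network each edge
regression depends on the data only through the counts of (child, design
pattern) cells: a logistic fit on any row subset becomes a binomial IRLS
over ≤ 2^p patterns, and all permutations/resamples of one dataset are
evaluated in a single batched Newton iteration (`numpy` batched solves).
The batched and per-subset routes agree to ~1e-11 and the in-package GLM
fits are cross-checked against statsmodels in the test suite.

## Known limitations

* The product's causal interpretation needs the no-interaction-with-C
  condition; the package computes it regardless and leaves the judgement to
  the analyst.
* The delta-method path SE ignores between-edge estimation covariance
  (edges share rows); the bootstrap SE does not and is the default for
  reported standard errors.
* Model-based standardization extrapolates into empty covariate strata;
  the stratified estimator errors there instead — both behaviours are
  deliberate and selectable.
* Discrete (3+ level) children are supported in the single-shot estimators
  but not in the batched resampling engine (binary and continuous only).
* No multiple-testing correction is applied across enumerated paths; raw
  per-path p-values are primary, and the number of paths tested is
  reported so a Bonferroni bound can be formed by the reader.
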