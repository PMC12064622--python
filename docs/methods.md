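# Methods

This note documents the models, estimation choices and simulation design
behind `difverse`, including the decisions that were genuinely open and
why they were resolved the way they were.

## The measurement model

Item responses are ordered categories k = 0..K−1 following the graded
response model: one discrimination a > 0 per item and strictly increasing
thresholds b_1 < … < b_{K−1} on the cumulative logits,

    P(X ≥ k | θ) = logistic(D · a · (θ − b_k)).

The metric constant **D defaults to 1.0** (pure logistic). Parameter files
declare their own constant in a header; a file on the normal-ogive
convention (D = 1.702) is converted on read by a·D_file/D_internal, which
leaves every response probability unchanged. Being explicit here avoids
the silent factor-of-1.7 mistakes that plague mixed-convention workflows.

The latent trait is reported both on its native metric (reference mean 0,
sd 1) and as a T-score, 50 + 10·θ.

### Estimation

Marginal maximum likelihood via EM:

* **Quadrature:** 61 equally spaced nodes on [−6, 6], weighted by the
  (group-specific) normal density and renormalized. This is ample for
  estimation, where only expected counts per node matter.
* **E-step:** person-by-node posteriors from the current item parameters
  and group priors; expected response counts per (item, category, node).
* **M-step:** per item, the expected complete-data likelihood is maximized
  by L-BFGS with an analytic gradient; ordering of thresholds is enforced
  by optimizing (log a, b_1, log-increments). Group means/sds (all but the
  reference group, fixed at N(0,1)) update from posterior moments.
* **Start values:** a = 1, thresholds from normal quantiles of the
  cumulative category proportions.
* **Convergence:** maximum absolute parameter change < 1e-4, at most 500
  cycles; non-convergence raises an error carrying the last iterate. The
  marginal log-likelihood is tracked and is non-decreasing (a property the
  test suite asserts).
* **Sparse categories:** categories unobserved in an analysis subset are
  collapsed into the adjacent lower observed category; the collapse map is
  recorded on the results object and logged. An item with fewer than two
  observed categories is a hard error naming the item.
* **Missing responses** are dropped from the likelihood (MAR), never
  imputed.

Multigroup fits share item parameters across groups; partial-invariance
fits free the parameters of a designated item set per group while anchors
stay shared, which is what identifies the comparison of group trait
distributions under DIF.

### Scoring

EAP under the applicable group's parameters and normal prior, on **401
equally spaced nodes over [−8, 8]** — deliberately finer and wider than
the estimation grid because posterior sds for a 35-item bank are ~0.2 and
the reported θ should not carry visible quadrature error. Against a
10,001-point reference integration the default grid agrees to better than
1e-4 in both posterior mean and sd. A person with no observed responses
gets the prior back (θ = prior mean, se = prior sd). EAP (rather than ML)
scoring is used throughout: it is well-defined for extreme response
patterns and is the convention in this family of instruments; the choice
is configuration, not a claim about what any particular study did.

## DIF statistics

Conditioning variable is the **EAP θ** computed under the analysis cell's
parameter source (fixed "published" calibration, or the multigroup
estimate from the cell's own comparison subset). Per item, three nested
proportional-odds models are fit:

    M1: item ~ θ        M2: M1 + group        M3: M2 + θ×group

* Groups enter as indicator contrasts against the reference; with three
  groups the likelihood-ratio degrees of freedom scale accordingly.
* **Age adjustment** (one multiverse factor) adds a linear age term and
  age×group interactions to *all three* models, so every DIF test is
  conditional on age and the nested structure stays valid. Age is
  standardized within the analysis subset.
* Reported statistics: χ²(M1,M2) (uniform), χ²(M2,M3) (non-uniform),
  χ²(M1,M3) (total) with exact telescoping χ²₁₂ + χ²₂₃ = χ²₁₃; the three
  pseudo-R² changes between M1 and M3 (Cox–Snell, Nagelkerke, McFadden);
  and the beta change |β_θ(M2) − β_θ(M1)| / |β_θ(M1)|.
* **Flagging criteria** (the criterion × threshold factors): LRT on the
  total test with raw, Bonferroni- or Benjamini–Hochberg-adjusted p-values
  at α ∈ {0.02, 0.05}; pseudo-R² change ≥ {0.02, 0.03, 0.05}; beta change
  ≥ {0.01, 0.05}. The LRT family flags on the total M1-vs-M3 test because
  the multiverse treats "LRT" as one criterion; the uniform/non-uniform
  split remains available for item-level postmortems. The beta criterion
  is the proportional change of the θ coefficient (the lordif convention);
  an absolute-change variant is selectable.
* The proportional-odds likelihood is maximized by L-BFGS with analytic
  gradients and log-difference-parametrized cuts. Complete separation is
  detected by coefficient divergence (|β| > 15) and reported as an error;
  rank-deficient designs are rejected naming the collinear columns. A
  non-converged item is marked invalid, excluded from flag denominators
  and logged, with the cell marked partial.
* No iterative purification of θ: the canonical grid is a plain
  single-pass specification grid, and purification would entangle the
  cells' conditioning variables.

## The multiverse

Five factors: comparison (all three groups or one of the three pairs),
age adjustment (no/yes), parameter source (published/estimated), criterion
and threshold. The canonical criterion–threshold set is 11 non-LRT combos
(3 pseudo-R² × 3 thresholds + beta × 2) plus 6 LRT combos (3 multiplicity
variants × 2 α), giving 4 × 2 × 2 × 17 = **272 cells, 176 non-LRT**. The
factor levels are fully configurable (YAML/JSON), so alternative
decompositions are one config edit.

Cells differing only in criterion/threshold share identical model fits:
execution caches one set of per-item statistics per (comparison, age,
source) base configuration — 16 base analyses — and applies criteria as a
second pass. A naive per-cell execution path exists solely as a
correctness oracle; the test suite verifies bit-identical output. GRM
fits are additionally cached per comparison (they do not depend on the
age factor), and "published"-source θs do not depend on the comparison
subset at all.

Aggregation reports the histogram of per-cell flag counts, per-item flag
counts and percentages on both the all-cells and the non-LRT basis
(denominators: number of cells of that basis), per-factor-level breakdowns
(denominator: basis cells × items), and the post-hoc consistency set:
items flagged in **strictly more than 10%** of non-LRT analyses.

## DIF impact

* **Paired scoring:** every person scored under the fully invariant
  calibration and under the partial-invariance recalibration (their own
  group's records and group prior). Agreement is summarized as the mean
  difference (partial − full) and Bland–Altman limits mean ± 1.96 sd.
* **Item-level impact:** Σ w(θ)·|E_ref(X|θ) − E_focal(X|θ)| per item, with
  w the normalized histogram of the reference group's EAP estimates on the
  θ grid — an expected-score gap weighted by where reference respondents
  actually sit.
* **Effect sizes:** Cohen's d between groups on partial-model T-scores,
  pooled sd, with the normal-approximation CI
  d ± 1.96·√((n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂−2))); a bootstrap CI is
  available behind a flag.
* Test characteristic curves for the DIF-item subset are emitted per
  group, exposing the direction of the distortion: a group whose curves
  sit higher at fixed θ is under-estimated when scored with reference
  parameters.

## Assumption diagnostics

* **Loevinger's H** from pairwise covariances against their maximum given
  the item margins (computed via the comonotone identity
  E[XY]max = Σ_{s,t} min(P(X≥s), P(Y≥t))); item H and scale H with a
  seeded nonparametric bootstrap SE (default 500 resamples,
  complete cases). Pairwise-complete data for the point estimates. The
  monotonicity rule is H > 0.3. Note the scale H is a ratio of summed
  covariances, not an average of item coefficients.
* **Yen's Q3**: residuals x − E[X|θ̂] correlated across items, listwise
  per pair; pairs with fewer than 3 joint observations are undefined.
  Default rule |Q3| > 0.2; a signed comparison is selectable since the
  convention differs between authors.
* **Polychoric correlations** by two-step ML (thresholds from the
  inverse-normal margins, ρ by bounded likelihood maximization over the
  bivariate-normal cell probabilities; 0.5 continuity correction for
  empty cells).
* **Bifactor indices**: minres factoring of the (PSD-smoothed) polychoric
  matrix, promax rotation, Schmid–Leiman transform through a one-factor
  solution of the factor correlations; then ECV = Σλ_g²/(Σλ_g²+ΣΣλ_s²) and
  ω_H = (Σλ_g)²/implied total variance, with verdicts at ECV ≥ 0.6 and
  ω_H ≥ 0.8. Defaults to 3 group factors (body-region subdomains motivate
  at least 2); **factors with negligible extraction strength (sum of
  squared loadings below max(10% of the largest factor, 0.2)) are dropped
  before rotation** — rotating noise factors leaks general variance into
  spurious specifics and biases ECV downward on genuinely unidimensional
  data, which is exactly the case the index must get right. Heywood cases
  are clipped at 0.995 communality. Confirmatory fit indices (CFI/TLI/
  RMSEA/SRMR, M2) are out of scope; the ECV/ωH + Q3 battery carries the
  dimensionality judgment.

## Synthetic data

`simulate_item_bank` draws a ~ U(1.0, 2.5) and sorted thresholds
~ U(−2, 2) (minimum gap 0.05). `inject_dif` realizes uniform DIF as an
elementwise threshold shift and non-uniform DIF as a discrimination
multiplier for the focal group. Responses are drawn by inverse-CDF from
the category probabilities; everything is a pure function of
(config, seed).

The **three-country fixture** emulates a translated-item-bank study:

| group | n | θ mean | θ sd | age mean (sd), truncated 18–88 |
|---|---|---|---|---|
| USA | 1600 | 0.027 | 1.226 | 44.27 (16.15) |
| Germany | 1000 | 0.137 | 1.028 | 44.93 (14.54) |
| Argentina | 1001 | 0.277 | 0.784 | 35.58 (11.84) |

θ means are the groups' published instrument means re-expressed as
(T−50)/10; θ sds are the observed T-score sds /10, retaining the salient
feature that the Argentinian sample is both younger and more homogeneous.
Age is coupled to θ through a Gaussian copula with r = −0.2 (older
respondents report somewhat lower physical function) so that the
age-adjustment factor of the multiverse is non-vacuous; the true θ–age
relation in any real sample is unknown, so this is a stated assumption.

Four designated DIF items mirror the canonical flagged pattern: uniform
+0.5 logits (Germany), uniform −0.5 (Argentina), one large uniform +1.0
(Argentina), and one **non-uniform slope doubling** (Argentina). The
slope doubling deserves a note: a milder slope change (×1.5) produces
χ² ≈ 1–4 and ΔR² ≈ 0.001 at these sample sizes — invisible to every
criterion including the raw LRT, because conditioning on an estimated θ
absorbs most of a modest interaction. A doubling on a low-threshold item
is the smallest change of this kind that the pseudo-R² and beta criteria
detect without saturating (≈20% of non-LRT cells flag it, vs ≈55–74% for
the uniform items and <6% for any clean item). This mirrors the field's
experience that non-uniform DIF is barely detectable by effect-size
criteria at realistic n.

### What the generator does and does not emulate

It reproduces the group sizes, trait separations, age margins and DIF
structure of a three-sample translation study, under an exactly
unidimensional GRM with locally independent items and MAR-free complete
data. It does **not** emulate multidimensional content clusters, response
styles, panel-quality artifacts, floor/ceiling respondents beyond what
the GRM implies, or item-bank-specific parameter values (no proprietary
calibration is copied; banks are drawn). Passing tests therefore certify
the machinery — calibration of error rates, recovery, identities, cache
correctness — not the substantive conclusions one would draw from any
real dataset.

## Operating characteristics (what the validation studies measure)

* **Parameter recovery:** 20 items × 5 categories, n = 2000, one fit:
  corr(â, a) ≈ 0.98, corr(b̂, b) ≈ 0.999 (thresholds ≥ 0.95 and slopes
  ≥ 0.90 are the asserted floors).
* **Type-I error:** 500 null two-group replicates (n = 500/group, 12
  items, thetas scored under the generating bank): total-LRT rejection at
  α = 0.05 lands in [0.03, 0.07]; Bonferroni and Benjamini–Hochberg rates
  are below the raw rate by construction and empirically ≈ 0.003.
* **Power:** a +1.0-logit uniform shift at n = 500/group is detected by
  the α = 0.05 LRT in essentially 100% of 200 replicates.
* **End-to-end injection recovery:** on the 3601-person fixture the four
  injected items are exactly the top four by non-LRT flag percentage and
  exactly the >10% consistency set.

Problem sizes throughout (replicate counts, n per group, item counts) are
chosen so each study pins its target quantity with a comfortable binomial
or Monte-Carlo margin while keeping a full validation run in the
minutes range on a single core.

## Known limitations

* The EM uses fixed rectangular quadrature; with < 61 nodes or traits far
  outside [−6, 6] the discretization would bias group-sd estimates.
* The bootstrap SE for scale H resamples complete cases only.
* The Schmid–Leiman bifactor solution inherits the indeterminacies of
  exploratory factoring (rotation choice, number of group factors); ECV
  from over-extracted solutions is only protected by the
  factor-retention rule described above.
* Only the lordif-style ordinal-logistic framework is implemented — no
  Mantel–Haenszel, anchor-based IRT-LR, Rasch comparisons or multigroup
  CFA; those are different instruments, not missing features.
* Cohen's d CIs are normal-approximation by default; for very small
  groups use the bootstrap flag.
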