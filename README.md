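# difverse

Multiverse differential-item-functioning (DIF) analysis for graded-response
item banks.

When a patient-reported outcome measure — say a physical-function item bank —
is translated into other languages, items must behave the same way across
language groups: two respondents at the same trait level should have the
same response probabilities regardless of country. Violations of this
measurement invariance are called *differential item functioning*. The
standard ordinal-logistic DIF workflow, however, hides a thicket of analytic
choices: which groups to compare, whether to adjust for age, where the item
parameters conditioning the trait come from, which flagging criterion to use
and at what threshold. Different defensible choices flag different items.

`difverse` treats that thicket as the object of study. It runs the *entire*
factorial grid of defensible specifications — a multiverse analysis — and
summarizes how often each item is flagged across all of them, so that the
DIF verdict rests on the stability of a finding rather than on one arbitrary
specification.

## What it computes

**Graded response model (GRM).** Ordered categories k = 0..K−1 follow
cumulative logistic curves

    P(X ≥ k | θ) = 1 / (1 + exp(−D·a·(θ − b_k))),   b_1 < … < b_{K−1},

with marginal-ML estimation (EM over fixed quadrature), single-group,
multigroup (shared items, free group means/sds, reference group N(0,1)) and
partial-invariance variants (DIF items freed per group, anchors shared).
Persons are scored by EAP; T-scores are 50 + 10·θ.

**Ordinal-logistic DIF.** Per item, three nested proportional-odds models:

    M1: item ~ θ            (+ age + age×group when age-adjusted)
    M2: M1 + group
    M3: M2 + θ×group

Uniform DIF shows up as the group main effect (M1 vs M2), non-uniform DIF
as the θ×group interaction (M2 vs M3). Criteria: likelihood-ratio tests
(raw, Bonferroni, Benjamini–Hochberg) on the total M1-vs-M3 test; changes
in Cox–Snell / Nagelkerke / McFadden pseudo-R² (M1 vs M3); relative change
of the θ coefficient (M1 vs M2).

**The multiverse.** 4 group comparisons × 2 age settings × 2 parameter
sources × 17 criterion–threshold combinations = 272 analysis cells (176
without the LRT family). Cells differing only in criterion share the same
model fits, so the grid costs 16 base analyses. Aggregation yields the
flag-count histogram, per-factor breakdowns, per-item flag percentages and
the post-hoc "flagged in more than 10% of analyses" item set.

**DIF impact.** Fully vs partially invariant calibrations are compared via
paired T-scores (Bland–Altman limits of agreement), item-level expected
score gaps weighted by the reference score distribution, test
characteristic curves and between-group Cohen's d.

**Assumption checks.** Loevinger's H (monotone scalability, H > 0.3),
Yen's Q3 residual correlations (|Q3| > 0.2 flags local dependence), and
essential unidimensionality via polychoric correlations → minres
exploratory factoring → Schmid–Leiman bifactor indices (ECV ≥ 0.6,
ωH ≥ 0.8).

**Synthetic studies.** A generator for multi-group GRM data with injectable
uniform (threshold-shift) and non-uniform (slope-change) DIF, including a
three-country fixture (USA n=1600, Germany n=1000, Argentina n=1001; 35
five-category items; age correlated with the trait) with four designated
DIF items.

## Worked example

```python
from difverse.simulate import make_study_fixture
from difverse.multiverse import MultiverseDIF, GridConfig
from difverse.impact import DIFImpact

fx = make_study_fixture(seed=1)           # 3601 persons, 35 items, 4 DIF items
model = MultiverseDIF(
    fx.responses, fx.study,
    grid=GridConfig(groups=("USA", "Germany", "Argentina")),
    published_params=fx.params_reference,  # the "published calibration" arm
    reference_group="USA",
)
results = model.fit()                      # 272 cells, ~80 s on one core
print(results.summary())

impact = DIFImpact(
    fx.responses, fx.study, sorted(results.consistent_items()),
    reference_group="USA",
).fit()
print(impact.summary())
```

prints

```
Multiverse DIF analysis: 272 cells (176 non-LRT), 35 items
consistent DIF items (>10% of non-LRT analyses): ['I06', 'I13', 'I21', 'I22']
most-flagged items (non-LRT basis):
         k_nonlrt  pct_nonlrt  k_all    pct_all
item_id
I21           130   73.863636    202  74.264706
I06           125   71.022727    197  72.426471
I13            97   55.113636    169  62.132353
I22            35   19.886364    107  39.338235
I16            10    5.681818     11   4.044118
I32             1    0.568182     30  11.029412

DIF impact: 4 flagged item(s): ['I06', 'I13', 'I21', 'I22']
mean T-score difference (partial - full): +0.040
95% limits of agreement: [-0.286, +0.365]
between-group Cohen's d (partial-model T-scores):
  group_1 group_2        d    ci_low  ci_high
Argentina Germany 0.214020  0.126139 0.301901
Argentina     USA 0.208553  0.129365 0.287740
  Germany     USA 0.021076 -0.057935 0.100086
```

The four items that carry injected DIF (I06, I13, I21, I22) are exactly the
four most-flagged items across the 176 non-LRT specifications and the only
ones above the 10% consistency cutoff; every clean item stays below 6%.
Accounting for that DIF moves individual T-scores by at most a few tenths
of a point (mean +0.04, limits of agreement ±0.3), i.e. the flagged DIF is
real but practically negligible at the test level — while the between-group
comparison under the corrected model still shows Argentina scoring about a
fifth of a standard deviation above the USA and Germany.

The same pipeline runs from the shell:

```
difverse simulate --seed 1 --out study/
difverse check-assumptions --data study/responses.csv --out diag/
difverse multiverse --data study/responses.csv \
    --params study/params_reference.csv --out mv/
difverse impact --data study/responses.csv --dif-items I06,I13,I21,I22 \
    --out impact/
```

Real data enter through the same CSV formats: a wide response file
(`person_id, group, age, item…`) and an item-parameter file with a
`# metric_constant:` header (1.702-metric files are converted on read).

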