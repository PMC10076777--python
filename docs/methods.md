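# Methods

## Model and procedure

`recurrisk` estimates a three-way recurrence-risk call from bulk tumor
expression by combining two nearest-centroid signatures, one per
high-risk subgroup. The underlying model is that recurrence arises from
(at least) two distinct tumor states, each marked by a coherent
expression program and an elevated recurrence hazard, inside a majority
of low-risk tumors whose recurrences follow a baseline hazard.

Training proceeds in stages (see the README for the operational
summary): cohort eligibility filtering, unsupervised partition of
recurrence tumors into two branches, a per-branch univariate Cox screen,
rank-frequency stability selection over repeated cross-validation,
centroid construction on z-scored expression, and a survival-driven
cutoff per signature. Prediction z-scores new samples with the *frozen
training* per-gene mean and standard deviation, computes each
signature's similarity-difference score, and combines the two decisions
by OR, assigning the subgroup with the larger cutoff-centered margin.

Assumptions worth making explicit:

* **Proportional hazards per gene.** The screen ranks genes by the Wald
  p-value of a univariate Cox fit; genes whose effect is strongly
  time-varying will be mis-ranked.
* **Coherent programs.** The centroid score assumes a subgroup's
  signature genes move together relative to the cohort mean; the score
  is a similarity over the signature's z-profile, not a weighted sum of
  independent effects.
* **No imputation.** Missing expression values are rejected; at
  prediction time up to 5% of signature genes may be absent (dropped
  pairwise), more is an error.

## Survival primitives

All survival statistics are implemented directly from their defining
formulas:

* Kaplan–Meier product-limit curves with Greenwood variance; pointwise
  confidence intervals use the log-log transform (keeps the interval in
  [0, 1] and matches the default of the standard survival packages).
* Two-group log-rank test: hypergeometric variance summed over distinct
  event times, χ² with 1 df.
* Univariate Cox regression maximizing the Efron-corrected partial
  likelihood (Efron is the convention of the package family this field
  uses for tied event times). The optimizer is Newton iteration with the
  step clipped to ±1 on an internally unit-variance covariate scale —
  the univariate partial log-likelihood is concave, so clipped Newton
  from 0 is globally convergent. A coefficient walking to |β| = 15 on
  that scale indicates monotone likelihood (perfect separation); it is
  clamped and flagged not converged. The per-gene screening path
  (`cox_scan`) runs the same iteration vectorized across thousands of
  genes simultaneously. p-values are two-sided Wald tests, the
  per-coefficient p conventionally reported.
* Concordance AUC: probability that a random positive outscores a random
  negative, tied pairs counting 1/2, computed from midranks.

The test suite verifies these against independent brute-force oracles
(hand-summed log-rank, a 10⁻⁴-step likelihood grid search, exhaustive
pair enumeration) and against `lifelines` on tied data.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `prescreen_alpha` | 0.01 | raw per-gene Cox p threshold; uncorrected because the stability stage is the false-positive guard |
| `cv_rounds` × `cv_folds` | 200 × 10 | repeated stratified CV depth for stability selection |
| `top_k` | 150 | rank cut per fold-fit |
| `freq_threshold` | 0.80 | fraction of fold-fits a gene must rank ≤ `top_k` in |
| `n_variance_genes` | 500 | genes used for the recurrence-tumor partition |
| `min_group_frac` | 0.10 | minimum arm size for the cutoff search (prevents degenerate splits) |
| `score_metric` | `uncentered` | centroid similarity (see below) |
| `counting` | `per_fold_fit` | unit for the stability frequency; `per_round` aggregates a round's ten rankings by median rank |

Folds are stratified on event status so every training fit retains
events; a configuration leaving the training fits with fewer than two
events on average is rejected with advice to use fewer folds.

## Numerical and design choices

* **Stability counting unit.** "Top 150 in at least 80% of repetitions"
  is counted per fold-fit (`cv_rounds · cv_folds` fits); the per-round
  alternative (median rank within a round) is available via config. The
  two agree in the limit; per-fold-fit is finer-grained.
* **Prescreen as a filter.** Ranks are computed over the *full* gene
  universe in every fold-fit and the p < 0.01 screen is applied as a
  filter on the stability-selected set. Restricting the ranking universe
  to the screened genes would make the top-150 cut vacuous whenever
  fewer than 150 genes pass the screen and admit every screening false
  positive.
* **Ranking tie-break.** Equal p-values are ordered by larger |β| first,
  then gene id, so results are invariant to the input gene order.
* **Centroid similarity.** The default score is the difference of
  *uncentered* correlations (cosine similarity over z-scores) to the
  high- and low-risk centroids. When a signature's genes move coherently
  in one direction — exactly the structure a prognostic program has —
  the centroid vector is nearly constant across genes, and centered
  Pearson correlation removes that mean component, discarding most of
  the signal. Centered Pearson remains available
  (`score_metric="pearson"`) and is scale- *and* shift-invariant per
  sample, while the uncentered default is scale-invariant.
* **Cutoff search.** Candidate cutoffs are midpoints of adjacent sorted
  unique training scores; the objective is the training log-rank χ²
  under a 10% minimum-arm constraint; χ² ties break toward the more
  balanced split, then the smaller cutoff. The search is resubstitution
  (training scores): selection optimism therefore inflates training
  performance, and reported training HR/AUC should never be read as
  generalization estimates.
* **Zero-variance genes** z-score to 0 and are recorded, so gene lists
  keep their length; the trainer skips them.
* **Subgroup numbering.** Branch order is canonicalized so runs are
  reproducible: with an epithelial marker list, subgroup 1 is the
  marker-low branch (the post-EMT state); otherwise branches are ordered
  by descending size.
* **Eligibility horizon.** Recurrences after 60 months are recoded to
  censored at 60 (the recurrence phenotype is defined within five
  years); each recode is logged per sample.
* **Model files** are schema-versioned JSON containing both signatures,
  the frozen standardization, the configuration hash and seed; loading a
  file from another package version warns, and a file without cutoffs
  installs the documented defaults (−0.0850, −0.0005) with a warning.

## The synthetic cohort generator

`simulate_cohort` emulates the cohort shape this class of study uses:
~220 tumors, ~20% in each of two high-risk classes, 2 000 genes of unit
Gaussian noise around gene-level baselines, a 40-gene program per class
(program 1 down-shifted, split into epithelial-like and
proliferation-like halves; program 2 up-shifted, TGF-β-like), per-gene
effect magnitudes uniform within ±50% of `effect_size` (default 1.0 z),
optional immune-marker depletion in class 1, exponential failure times
(baseline 0.004 events/month, 4× multiplier in the high-risk classes)
and administrative censoring at 41 ± 6 months capped at 60 — matching a
~41-month median follow-up and a ~20–28% event fraction.

What it deliberately does **not** model: count-level noise
(library size, overdispersion), gene–gene correlation beyond the planted
blocks, batch effects, and any coupling between a sample's *expression
level* and its hazard beyond class membership.

### What the default conditions can and cannot show

The default effect size of 1 z-unit per program gene is an intentionally
hard regime, and two information-theoretic limits follow from it:

* A planted 40 × ~11 block at δ = 1 inside a 2 000 × ~30 recurrence
  matrix is *below the detection edge* for submatrix localization, so
  the unsupervised branch partition is near-chance at defaults — no
  clustering method could do better. The partition test therefore uses
  a strong-separation cohort (δ = 2.5), where 2-medoid clustering
  recovers the planted branches.
* Within a branch working cohort (~11 events), a program gene's Cox
  z-statistic is only ≈ 2, because censored high-risk samples carry the
  program but contribute no events, and ~30% of events come from the
  baseline-hazard class and carry no program. Per-gene screening power
  at p < 0.01 is then ~30–45%, so full recovery of a planted program is
  not achievable at defaults; the strong-signal unit tests verify the
  selection mechanics instead.

Consequently, passing tests on the strong-signal cohorts demonstrate the
*correctness of the machinery*, not that the method would succeed on an
arbitrarily weak real cohort; the null-safety test demonstrates the
converse guarantee, that with no planted signal the trained pipeline
does not fabricate held-out survival separation (training runs that find
no stable signature abstain by raising, which counts as non-rejection).

## Problem sizes used in examples and checks

Examples and the reproduction script scale the cross-validation depth to
20 rounds of 10-fold (signatures stabilize well before 200 rounds on
cohorts of this size) and use cohorts of 120–220 samples with 300–2 000
genes; the survival-core oracle checks use 100 random cohorts of n ≤ 12
where brute-force enumeration is exact.

## Known limitations

* Univariate screening cannot represent genes prognostic only jointly;
  penalized multivariate selection is out of scope by design.
* The AUC treats the recorded event flag as the label; samples censored
  early contribute as negatives, which biases the AUC toward 0.5 — a
  caveat whenever censoring is heavy.
* Cutoffs are tuned on training data only; any use of validation data
  for tuning would invalidate the held-out statistics.
* The two-signature structure is fixed; more than two subgroups require
  retraining with a different partition design.
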