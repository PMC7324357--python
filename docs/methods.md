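# Methods

This note documents the statistical procedures, the synthetic-data
model, the numerical choices, and the limits of what the test suite can
demonstrate.

## Scoring model

The DELTA-P score is an unweighted sum of six binary clinical items
(D bulbar/neck weakness, E male erectile dysfunction, L weight loss
≥ 5%, T tobacco use at onset, A age ≥ 50 years, P Karnofsky < 70),
assessed on the 0–3-month window from symptom onset. Thresholds follow
the item definitions: A is inclusive (≥ 50), P strict (< 70). Applying
the onset window is the data provider's responsibility; the reader
stores only the resulting flags.

Two deliberate policies:

* **Females score E = 0, never missing.** This is part of the score's
  definition ("females scored as not affected"), so female patients are
  fully scoreable on the 6-point scale.
* **Missing items make a score undefined.** The original cohort had
  complete items, so a missingness policy had to be chosen here: items
  are never imputed, the affected patients are excluded listwise per
  analysis, and each pipeline stage reports its scoreable n. The
  5-point DLTA-P variant excludes E from both the sum and the
  missingness accounting, so a male with only E unknown still has a
  defined DLTA-P.

## Statistical primitives

These are implemented in the package (rather than delegated) because
their exact conventions matter clinically and are part of the
contract; scipy, statsmodels and lifelines serve as independent oracles
in the test suite.

* **Fisher's exact test**: two-sided p by probability-mass summation —
  all tables with the observed margins whose hypergeometric mass is ≤
  the observed mass count toward p, with relative slack 1e−7 against
  float round-off. This is the dominant convention in clinical software.
  The log-pmf is computed directly via `gammaln` over the whole support.
  Odds ratio is the cross-product ratio with a Woolf (log) interval;
  zero cells get the Haldane–Anscombe 0.5 correction, flagged in the
  result. Empty margins are a structured error.
* **Mann–Whitney U**: exact null distribution (rank-sum recursion) when
  n₁+n₂ ≤ 20 with no ties; otherwise normal approximation with tie
  correction and 0.5 continuity correction. Identical pooled samples
  give p = 1 by definition.
* **Logistic regression**: Newton–Raphson on the full likelihood,
  convergence when the score norm < 1e−8, at most 50 iterations;
  standard errors from the inverse observed information; Wald 95%
  limits on the odds-ratio scale (LCL/UCL), matching the usual clinical
  presentation. Profile-likelihood intervals are deliberately not used.
  Separation is detected by coefficient divergence (|β| > 30) or a
  singular information matrix and raised as an error naming the
  covariate; constant covariates are rejected up front.
* **Median confidence intervals**: exact binomial order-statistic ranks,
  the narrowest symmetric rank pair with ≥ 95% coverage. For n < 6 no
  such pair exists; the whole range is returned with a warning.
* **Survival**: Kaplan–Meier product-limit per group; the median is the
  first time the curve reaches 0.5 (undefined when it never does);
  two-group log-rank with the hypergeometric variance, unstratified. No
  Cox model is fitted.

## ROC analysis

AUC is the pairwise (Mann–Whitney) estimator with ties credited 0.5 —
for integer scores ties are the norm, and this estimator equals the
trapezoidal area under the empirical ROC exactly (property-tested).
Variances, CIs and the paired comparison of two scores on the same
patients use the DeLong placement-value method; the placement values are
computed rank-based so large simulated cohorts stay O(n log n). The
older table-based between-area correlation approach is superseded by
DeLong's consistent nonparametric estimator; this is a documented
deviation from the method the original analysis cited. Disjoint
subgroups are compared with the independent z-test on the two AUCs.
CIs are clipped to [0, 1] and rendered on the percentage scale.

`analytic_auc_from_item_probs` convolves six independent Bernoulli items
per group into exact 7-state score distributions and returns
P(S_case > S_control) + ½·P(equal); it is the closed-form oracle for
simulation checks.

## Cohort pipeline choices

* **Per-score risks** use Wilson 95% intervals, chosen for small-stratum
  behaviour (several strata hold under 10 patients); empty strata have
  undefined (not zero) risk. Totals are conserved by construction and
  fuzz-tested.
* **Item performance** counts, per item used alone as the test: a 1 in
  an SCLC patient and a 0 in a no-cancer patient are correct; the
  reverse cells are incorrect. The **item-versus-rest contrast** is an
  interpretation (the source analysis does not state its method): each
  item's correct/incorrect totals are Fisher-tested against the pooled
  totals of the other five, two-sided, and the minimum-accuracy item is
  flagged.
* The univariable table reports the impotence item both over all
  patients and restricted to males, mirroring the published layout.
  VGCC positivity is encoded by presence of a recorded titre.
* Percentages are rendered rounded to integers as in the published
  tables; the JSON report keeps full precision.

## Synthetic cohorts

The study's patient-level data are not deposited, so the generator
emulates the published group-level structure: n = 87 with SCLC
prevalence 44/87; per-group sex mix (16/44, 17/43 male); per-group item
frequencies taken from the published counts (e.g. smoking 29/44 vs
7/43), with E conditional on male sex; VGCC positivity 42/44 vs 36/43
with log-normal titres of median 448 vs 209 pM (log-SD 1.0 — the source
prints only medians, so the spread is an arbitrary documented choice);
exponential survival with medians 15.6 vs 50 months, NT patients
administratively censored at their follow-up; NT follow-up 36 months
plus an exponential excess with median 23 (median total 59 months); ages
drawn consistently with item A and the published group medians/ranges
(triangular above 50, uniform below). SCLC tumour-detection times are a
mixture — weight 0.91 log-normal centred on 0.5 months (σ = 0.8), 0.07
uniform on (6, 12], 0.02 uniform on (12, 30] — which reproduces the
published "91% within six months, 98% within twelve" in expectation.

Items are conditionally independent given group by default, because only
marginals are published; an exchangeable latent-severity Gaussian copula
(`rho`) is available to stress-test the statistics under dependence. A
seed fully determines the cohort (fixed draw order).

`fixture_table1` is a deterministic 87-patient cohort whose **binary
marginal counts reproduce the published univariable table exactly**.
Each attribute's positives are spread evenly across the group with a
fixed per-attribute rotation offset; the joint structure is therefore a
documented construction with no clinical meaning (the true joint is not
identifiable from the published tables), and quantities that depend on
the joint — per-score risks, the fixture AUC (84.5%), score medians —
are internally consistent but not estimates of the study's own values.
Titre and survival values are spread over {0.5×, 1×, 2×} the published
group medians so the medians are preserved exactly.

What passing tests on synthetic data do **not** show: robustness to the
item dependence, assessor variation, missingness patterns and case-mix
drift of real cohorts; the generator's conditional-independence default
is a simplification the copula mode only partially relaxes.

## Problem sizes and determinism

Stochastic properties are asserted over fixed seed batches (seeds
0..K−1), sized for desk-scale runs: 200 seeds for the titre-contrast
power check, 40–60 for logistic recovery, paired-AUC and log-rank
batches, 50,000 patients for frequency-recovery and analytic-AUC
agreement, 10⁶ draws for the Monte-Carlo AUC oracle, and an exhaustive
enumeration-oracle sweep of all 132,470 contingency tables with total
≤ 40. Hypothesis-based property tests run derandomised.

## Known limitations

* Wald intervals and p-values are first-order; at n = 87 with strong
  effects they can differ visibly from likelihood-ratio or exact
  methods (no exact logistic regression is provided).
* The two-sided Fisher probability-mass convention is one of several;
  mid-p and tail-doubling variants will disagree on some tables.
* No multiple-testing correction is applied anywhere, matching the
  source analysis.
* The screening schedule's "every six months for two years" after the
  month-3 scan is ambiguous; the default grid is {0, 3, 9, 15, 21}
  months with the alternative {0, 3, 6, 12, 18, 24} selectable
  (`high_on_semester_grid`).
* Detection times are data, not modelled: scan sensitivity and tumour
  growth are out of scope.
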