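# Methods

## The cascade

The screening rule is a three-level dichotomize–tally–re-ROC cascade.
Every level reuses one primitive: the empirical ROC curve of a score
against binary case status, with candidate cutoffs at midpoints between
adjacent distinct observed values (flanked by ±∞, so the two degenerate
operating points are always on the curve).  The AUC is computed by the
trapezoid rule over the curve; because every distinct value contributes a
vertex, this equals the Mann–Whitney statistic U/(n₁n₂) with ties credited
½ — the two are asserted equal against a brute-force pair-counting oracle
in the tests.  Significance is a two-sided normal test of AUC = 0.5 with
the Hanley–McNeil exponential-model standard error evaluated at the
observed AUC; simulation in the test suite puts its type-I error at ≈5.8%
for n = 50 + 50 at nominal 5%, adequate for the screening use here (no
claim of exactness in small samples).

Cutoffs maximise Youden's J (an option selects the closest-to-(0,1)
corner instead), with ties broken toward higher specificity and then
deterministically, and classification uses a strict inequality — immaterial
on training data because cutoffs sit at midpoints.  Integer tally
thresholds at the domain and model levels are selected by exhaustive scan
over k = 1…size of "abnormal iff tally ≥ k", ties broken toward the
*smallest* k: for a screening rule sensitivity is the scarcer commodity.
Both tie-break directions are available.

Two degenerate levels collapse by construction rather than by re-ROC: a
single-marker domain inherits its marker's full ROC workup (re-ROC-ing a
binary flag would discard the continuous marker's resolution and report
the flag's AUC, (sens+spec)/2, instead of the marker's), and a
single-domain model inherits the domain result.  This keeps the cascade
exactly equal to a plain single-marker ROC analysis in the fully
degenerate case.

Diagnostic odds ratio, predictive values and the accuracy index are the
standard closed forms; DOR at boundary sensitivity/specificity returns 0
or +∞, with an optional Haldane (+0.5 per cell) correction when raw 2×2
counts are available.  Predictive values default to prevalence 0.0035
(0.35%), a population-screening figure for psychosis-spectrum conditions;
0.30 is the companion high-prior clinical setting, and both appear in
cross-validation reports.

## Missing data

Cutoff fitting and tallying use pairwise deletion.  A missing marker
yields a missing flag — never a silent "normal".  A domain tally is the
sum of observed flags when at least one member is observed, and the
model-level ROC is fitted on subjects with every domain observed (the
natural complete-case set at that level).  The intended pipeline runs the
cascade on an imputed table; the default imputation is the overall
per-variable median, deliberately blind to case labels so no outcome
information leaks into the features.  A per-group median variant exists
solely to probe sensitivity to that convention (it leaks labels and is
flagged as such), and `none` leaves complete-case handling to the cascade.
Imputation never alters an observed value.

## Risk regression

Case risk as a function of the abnormal-domain count is fitted two ways.
The parametric curve is a single-covariate logistic regression
logit(p) = a + b·count, maximised by IRLS (Newton steps on the working
response), converged when the log-likelihood moves < 1e−10 or at 100
iterations; complete separation is detected and flagged rather than left
to diverge.  The test suite checks the score equations Σ(y−p̂) = 0 and
Σx(y−p̂) = 0 and agreement with an independent GLM implementation to 1e−6.
The non-parametric curve is Cleveland lowess: tricube-weighted local
linear fits with windows over subjects (not over the six distinct counts),
default span 2/3 and 3 bisquare robustness iterations (Cleveland's
defaults; the method's discrete covariate makes results insensitive to
modest span changes), evaluated on the integer grid 0…D and clipped to
[0, 1].  Degenerate windows (a single distinct covariate value) are
widened with a warning.  Risks are reported in percent to 2 decimals.

## Cross-validation

Validation is class-stratified k-fold (default 5): cases and controls are
shuffled separately and dealt into near-equal folds, so 67 cases split
14/14/13/13/13.  Within each fold the *entire* cascade — marker cutoffs,
domain thresholds, model threshold — is refitted on the training four
fifths; the held-out fifth contributes sensitivity, specificity, AUC (over
the held-out abnormal-domain counts), DOR, and Bayes PPV/NPV at each
configured prevalence.  Refitting everything is the honest-validation
choice; a `refit_cutoffs=False` mode that freezes full-data marker cutoffs
and refits only the tally thresholds exists to measure how much optimism
lives at the cutoff level, and its outputs are labelled.  Two summaries
are reported because fold aggregation is genuinely ambiguous: metrics on
the concatenated held-out predictions (pooled) and the simple mean of fold
metrics.

A caution the tests document explicitly: the in-sample cascade is
substantially optimistic.  On pure-noise cohorts (all marker AUCs 0.5,
n = 67 + 67) the refitted in-sample model AUC is ≈0.73, because every
cutoff and threshold is chosen to maximise J on the same subjects; the
cross-validated null AUC is ≈0.5.  In-sample numbers from this method
should never be quoted without the accompanying cross-validation.

## The synthetic cohort generator

Patient-level data for the motivating study are not deposited, so the
generator emulates the cohort's *statistical* structure — it makes no
attempt at assay-level realism (no creatinine adjustment, audiogram
traces, or instrument noise models).

* **Marginals.** Each marker is Gaussian in controls (plausible clinical
  means/SDs anchor units; the cascade is scale-free).  Cases are shifted
  by d = √2·Φ⁻¹(AUC) control SDs toward the abnormal tail — under the
  equal-variance binormal model this is the unique shift giving the
  requested AUC, which matters because only AUCs are published per marker.
  Low-abnormal markers negate the shift instead of transforming values.
* **Defaults.** The default panel carries the published per-marker AUCs
  (0.56–0.88 across 21 markers in 6 domains, sizes 3/3/3/1/5/6) and
  per-marker MCAR missingness rates derived from the published per-marker
  observation counts (1 − n/134, spanning ≈0–10%: lab markers ≈0–1.5%,
  sensory-processing markers ≈5–10%).  Cohort size defaults to 67 + 67.
* **Correlation.** Markers in a domain share one latent factor with
  loading √ρ, ρ = `within_domain_correlation` (default 0.3 — domains
  behave as coherent units without collapsing onto a single marker; the
  source tables report no covariances, so one moderate parameter per
  domain is the most that can be justified).  Domains are independent, so
  between-domain marker correlation is zero apart from case status.
* **Severity.** A latent case-intensity score (standard normal, cases
  shifted +2 SD — severity ratings separate the groups far more sharply
  than any marker) drives the functional measures through
  `severity_loading` (default 0.8) plus independent noise, then monotone
  transforms to conventional scales: SIR (symptom-intensity sum), GAF and
  SOFAS (inverted, 1–100), CGI (ordinal 1–7), hospital admission counts
  (Poisson with log-linear intensity), pension flag (thresholded).
  Spearman-based analyses are invariant to the monotone transforms.

What passing tests therefore show: the *pipeline* recovers the decision
structure (≥3-of-5 abnormal domains, model AUC ≈0.95, CV sensitivity
within a few points of in-sample) from data whose marginal discriminations
match the published ones.  What they cannot show: anything about real
assay distributions, non-MCAR missingness, cross-domain dependence beyond
case status, or the published cohort itself.

## Numerical choices and edge cases

* ROC trapezoid vertices are lexicographically sorted by (FPR, TPR) so
  vertical segments at tied FPR integrate correctly.
* Perfect separation gives SE 0 in the Hanley–McNeil formula; the p-value
  is reported as 0 (AUC ≠ 0.5) or 1 (AUC = 0.5).
* Spearman correlation is Pearson on mid-ranks (the standard tie
  correction) with a t-approximation p-value; constant inputs and fewer
  than three complete pairs are rejected as degenerate.
* All randomness flows through one `numpy` Generator seeded from the
  config; identical config ⇒ byte-identical cohort CSV and report files.
* Simulation-backed tests use deliberately modest problem sizes — 200
  replicate cohorts for the threshold distribution, 50 for the
  cross-validation optimism gap, 2000 replicates for test calibration,
  n = 2000 per arm (10 replicates) for generator calibration — chosen so
  the estimator noise is well inside each asserted band.

## Known limitations

* The Hanley–McNeil p-value is approximate; no exact permutation test is
  offered.
* No smooth/parametric ROC fitting, partial AUC, or DeLong paired-AUC
  comparison; no weighted or continuous composite scores (the method under
  study is strictly dichotomous tallying); no variable-selection search —
  panel membership is configuration.
* Lowess on six distinct integer counts is closer to a robust local
  interpolation than to smoothing; it is reported alongside, never instead
  of, the logistic fit.
* The generator's MCAR assumption and single-factor domain structure are
  conventions, not inferences from data.
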