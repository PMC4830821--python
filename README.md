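# panelroc

Hierarchical ROC scoring of multi-domain biomarker panels for case
detection, built for screening studies in which many weak-to-moderate
continuous markers (AUC ≈ 0.56–0.88 each) are combined into a single
dichotomous decision rule.  The motivating application is a psychosis
biomarker panel of 15–21 markers grouped into six functional domains
(visual processing, auditory processing, urinary catecholamines, oxidative
stress, biochemistry–nutrition, middle-ear function), but the machinery is
generic: any case–control table plus a variable→domain map works.

## The method

For markers *X₁…Xₚ* in domains *D₁…D_d* and binary case status *Y*:

1. **Marker level.** Each marker gets an empirical ROC curve; the cutoff
   *c_j* maximising Youden's *J = sens + spec − 1* dichotomises it into an
   abnormality flag (abnormal above or below *c_j*, per the marker's
   abnormal tail).
2. **Domain level.** Flags are tallied within each domain; the integer
   tally is itself ROC-analysed and the Youden-optimal minimum count *k_m*
   declares the domain abnormal.
3. **Model level.** The number of abnormal domains is tallied and
   ROC-analysed once more, giving the case-detection rule
   “case ⇔ ≥ *T* abnormal domains”.

Around the cascade: AUC significance via the Hanley–McNeil normal
approximation; diagnostic odds ratio DOR = [s/(1−s)]·[sp/(1−sp)];
prevalence-adjusted predictive values by Bayes' rule; case risk as a
function of the abnormal-domain count by single-covariate logistic
regression (IRLS) and Cleveland lowess; class-stratified k-fold
cross-validation that refits the entire cascade inside every training
fold; label-blind median imputation; Spearman correlation of panel scores
against external severity/disability measures.

Because the original patient-level data are not publicly deposited, the
package ships a synthetic cohort generator: an equal-variance binormal
model calibrated so each marker reproduces a requested AUC
(shift = √2·Φ⁻¹(AUC)), with a shared latent factor per domain, MCAR
missingness, and severity measures driven by a latent case-intensity
score.  See `docs/methods.md` for model details and limitations.

## Worked example

```sh
panelroc simulate --seed 1 -o cohort.csv
panelroc fit cohort.csv -o model.yaml
```

which prints, for that seed:

```
wrote 134 subjects x 15 markers to cohort.csv
model threshold: >= 3 abnormal domains (AUC 0.980, sens 95.5%, spec 94.0%)
```

i.e. the fitted rule calls a subject a case at ≥ 3 abnormal domains out of
5, discriminating cases from controls with in-sample AUC 0.98.  Then

```sh
panelroc crossval cohort.csv --k 5 --seed 1
panelroc report cohort.csv --seed 1 -o run/
```

cross-validates the rule (refitting every cutoff and threshold per
training fold) and writes the marker/domain/model performance tables, the
risk-by-count table (logistic and lowess, in percent), fold-level CV
results at prevalences 0.35% and 30%, and Spearman correlates against the
simulated severity measures.  The same pipeline runs on any cohort CSV
with `subject_id`, `group` (case/control) and numeric marker columns;
missing values are empty fields.

Library use mirrors the CLI:

```python
import panelroc as pr

table, _ = pr.impute_missing(pr.generate_cohort(pr.default_panel_config(15, seed=1)))
model = pr.fit_panel_model(table.values, table.labels, pr.default_domain_map(15))
print(model.model_threshold, round(model.model_result.auc, 3))  # 3 0.98
```

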