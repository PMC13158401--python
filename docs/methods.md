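# Methods

This note documents the statistical procedures implemented in `lrmscore`,
the assumptions behind them, the defaults and why they were chosen, and what
the synthetic-data validation does and does not demonstrate.

## Problem setting

Within LI-RADS, LR-M lesions are malignant on imaging but not specific for
HCC, so HCC-vs-iCCA entity assignment currently requires biopsy. The package
operationalizes a liquid-biopsy alternative: combine six routine serum
markers with three CD133/2⁺ small-EV subpopulations, let sparse supervised
selection and unsupervised variance analysis prioritize a compact panel, and
distill the result into an integer additive score a clinician can evaluate
by hand. Labels are coded HCC = 0, iCCA = 1 throughout.

## Preprocessing

- **Standardization.** Z-scores with the sample (n−1) standard deviation.
  Statistics are fitted on the training split only and applied unchanged to
  evaluation data; a whole-table mode exists for replication of workflows
  that standardize before splitting, but the default avoids test-set
  leakage. Zero-variance markers raise an error naming the marker.
- **Imputation.** Disease-stratified median imputation (each gap filled with
  the median of that marker within the patient's diagnosis class) is the
  replication-faithful mode and is applied to training data, where labels
  are legitimately known. For evaluation data the default is leakage-safe:
  gaps are filled with the overall training-split median, so labels are
  never consulted at prediction time. EV columns must be complete; only
  serology may carry gaps.
- **Splitting.** Stratified 80:20 by default (class proportions preserved to
  rounding, both classes required in both parts). With 25 + 25 patients an
  unstratified split can leave a test part without one class, making AUROC
  undefined; stratification removes that failure mode at negligible cost.

## Marker prioritization

The L1-penalized logistic objective is

    (1/n) Σ_i log(1 + exp(−(2y_i − 1)(β₀ + x_i·β))) + λ‖β‖₁

with an unpenalized intercept, minimized by FISTA (accelerated proximal
gradient with adaptive restart, step 1/L from the exact Lipschitz constant).
The optimum is certified by the KKT subgradient conditions at tolerance
1e−8 (iteration cap 10⁵); λ_max = max_j |(1/n) Σ_i x_ij (y_i − ȳ)| gives the
exact all-zero solution analytically. The regularization path is computed by
warm starts down a geometric λ grid, recording each marker's first-entry λ.

PCA contributions are `c_m = Σ_{k≤4} |w_{mk}|` with `w` the unit-norm
principal-axis loadings of the standardized training matrix — invariant to
component sign flips. The final panel is the union of the L1 support with
the top-5 contributors; ranking is lexicographic (non-zero coefficients
first by |coefficient|, then contribution, then name). Five contributors
are kept because the contribution ranking of the published analysis listed
five markers; the merge rule itself is a documented design choice, as the
qualitative published description ("merged") does not pin one down.

Penalty strength: the single reported model selects λ by stratified 5-fold
cross-validation maximizing held-out AUROC (a 1-SE variant is available).
Within repeated splits, each split refits at λ = 1/n_train — the strength
implied by the default `C = 1` convention of mainstream logistic-LASSO
implementations — because per-split CV at n = 40 with 8-patient folds is
dominated by fold noise. After selection, the hybrid model is refit on the
selected markers with a small ridge stabilizer (ℓ₂ = 1e−4, Newton
iterations): near-separation is common at n = 40 and an unpenalized refit
would diverge.

## Additive scores

Per-marker cut-offs maximize Youden's J over candidate thresholds placed at
midpoints between consecutive distinct observed values, with ±∞ sentinels
representing the "nobody/everybody scores" classifiers; ties break toward
higher specificity, then the lower threshold (the published operating
points favor specificity). A winning sentinel is materialized as the
nearest observed extreme so cut-offs stay finite without changing
sensitivity or specificity on the derivation data. "Above the cut-off" is
read strictly (a value exactly at the cut-off scores nothing), since
published cut-offs are reported as values, not intervals.

Score variants: hybrid with/without AFP (all cut-offs Youden-derived),
hybrid with AFP fixed at the 20 ng/ml guideline value, and PRISM — five
fixed constants (ALP 439 U/L, CA19-9 16.3 U/ml, CRP 0.87, CD9⁺ 3.2×10⁶/ml,
CD81⁺ 1.06×10⁶/ml) requiring no computation. The total-score threshold T is
Youden-optimal on training totals by default; the fixed published text rule
(0–3 → HCC, 4+ → iCCA) is available because the two conventions disagree in
the source material and both are legitimate.

All markers score in the "above" direction by default, including AFP — the
literal published rule — even though AFP is higher in HCC and carries a
negative coefficient; a direction-aware option per marker exists, and the
repeated-splits additive model uses it (a negative-coefficient marker
scores below its cut-off), since the additive score is the binarized
translation of the fitted model and ignoring the sign converts reversed
markers into anti-signal. CRP values are treated as pure numbers on the
scale of the published medians and cut-offs (whose printed unit labels,
mg/L vs mg/dl, are mutually inconsistent); no unit conversion is ever
applied.

## Evaluation statistics

AUROC is the tie-corrected pair-counting probability (concordant + ½·tied) /
(n₁·n₀), computed from mid-ranks; it equals the trapezoidal area under the
empirical ROC curve, and the identity is asserted in tests at 1e−12.
DeLong's method supplies the AUROC standard error and paired comparisons
from mid-rank placement values (degenerate zero-variance configurations are
flagged and reported with p = 1). Confusion metrics use the plain Pearson
χ² without continuity correction; metrics with an empty margin are reported
as undefined rather than 0. The univariate panel reports Welch t
(Satterthwaite df), Mann-Whitney U (exact when both groups have ≤ 10
observations without ties, mid-rank normal approximation otherwise),
Cohen's d with pooled sd, post-hoc power from the noncentral-t at the
observed d (descriptive only — post-hoc power is a transformation of the
p-value, not new evidence), and the single-marker AUROC. No multiplicity
correction is applied, matching the source analysis.

## Robustness procedures

- **Bootstrap** (B = 1,000): class-stratified resampling so AUROC is always
  defined; percentile 95% CI. Percentile rather than BCa, as only
  percentile intervals are being emulated.
- **Monte Carlo perturbation** (500 iterations per level): every model
  marker value is multiplied by (1 + u), u ~ Uniform[−ε, ε] i.i.d. per cell
  (a truncated Gaussian option exists), with cut-offs and T frozen; the
  AUROC of the perturbed total score is summarized per ε ∈ {5, 10, 20 %}.
  ε = 0 reproduces the deterministic evaluation exactly.
- **Repeated splits** (200 by default): per split — seeded base_seed + index
  so any single split is reproducible in isolation — imputation,
  standardization, L1 selection, ridge refit, and additive-model derivation
  are all redone on the training part, and both models are evaluated by
  AUROC on the untouched test part. Outputs: AUROC distributions,
  per-marker selection frequencies, paired Wilcoxon (normal approximation
  with tie correction; exact enumeration is infeasible at n = 200) and
  paired t p-values. Degenerate splits are redrawn with an incremented
  sub-seed and counted.

## Survival

Groups are dichotomized strictly above vs at-or-below the within-table
median (ties go to the low group). Kaplan-Meier estimation, the log-rank
test, its Gehan-Breslow-Wilcoxon variant (weights each event time by the
number at risk, emphasizing early deaths), and the binary-covariate Cox
model (Breslow tie handling, Wald 95% CI) are delegated to lifelines behind
this module's interface; median OS is the first time S(t) ≤ 0.5, undefined
when never reached. The median-OS-ratio CI uses a stratified bootstrap
(1,000 resamples, percentile) — a method choice, as no standard closed form
exists. Both the partial-likelihood HR and the O/E-ratio approximation that
survival-curve software prints are exported, labeled distinctly. Monotone
likelihood (complete separation of event times) is flagged as unbounded
rather than reported as a finite estimate. Proportional hazards is assumed,
not tested, in this exploratory setting.

## Synthetic cohort generator

Each marker is log-normal per class: `x = exp(log_median + log_sd·z)`.
Medians use the published group values; EV medians (not published) are
placed once so published cut-offs fall between the class medians while
preserving the published fold-changes (CD9⁺ ×2.5, CD63⁺ ×4.2, CD81⁺ ×12.2);
log-sds solve `AUROC = Φ(Δlog-median/√(σ₀²+σ₁²))` for the published
single-marker AUROCs (albumin 0.60 … CRP 0.82). This calibration is
approximate by necessity — the source reports no dispersions. Missingness
is MCAR at 5 % confined to serology; EV columns are complete. Survival is
exponential per class (baseline medians ≈ 390 d iCCA / 907 d HCC), with the
hazard multiplied by exp(log 2.8) for patients above the class-internal
CD9⁺CD133/2⁺ median, an administrative horizon at 1,600 d and light random
censoring (rate 1/4,000 per day), yielding event fractions close to the
reported 23/25 and 20/25. Markers are independent by default; a
Gaussian-copula correlation matrix is accepted.

What passing synthetic tests shows: the statistical machinery is correct
(oracle agreement), the pipeline is leakage-free and deterministic, and
planted structure (median separations, hazard ratios) is recovered at the
rates theory predicts. What it does not show: performance on real LR-M
cohorts, where markers are correlated, distributions are only
approximately log-normal, and missingness need not be random.

### A caveat on split-wise selection frequencies at n = 25/class

The null-marker AUROC in a 25 + 25 cohort has standard deviation ≈ 0.08, so
individual cohort draws regularly (~25–30 % of draws, with four null
markers) contain a generatively null marker whose in-cohort association is
strong (|AUROC − 0.5| > 0.15). Repeated train-test splits of that one
cohort resample the same chance association, so selection procedures
rightly keep choosing the marker — split-resampling cannot distinguish
chance from signal within a single small cohort, only external replication
can. Selection-frequency expectations of the form "null markers rarely
selected" therefore hold on typical draws but not uniformly; the planted
markers' high selection rates and the planted-vs-null rank ordering
aggregated over cohort draws are the stable properties, and those are what
the test suite pins. This mirrors the published analysis itself, whose
weakest marker still appeared in 32.5 % of splits.

## Numerical choices

- FISTA tolerance 1e−8 (KKT residual), cap 10⁵ iterations; CV inner fits at
  1e−6; the repeated-splits fits at 1e−7.
- Youden ties: higher specificity, then lower threshold; floating-point J
  values rounded at 1e−15 before comparison to stabilize ties.
- Bootstrap/MC/splits seeds are derived from the run seed by fixed offsets;
  identical configuration reproduces every artifact bit-for-bit (content
  hashes in the report manifest, which deliberately contains no
  timestamps).
- Problem sizes in the test suite (e.g. 5,000/class for generator
  calibration, 300/arm for hazard-ratio recovery, 200 splits) were chosen
  as the smallest sizes at which the checked asymptotics are
  well-resolved.

## Known limitations

- The additive score's integer granularity makes its AUROC tie-heavy on
  small test sets; discrimination estimates at n = 10 are coarse.
- PCA contributions on near-isotropic data are close to uniform and carry
  little ranking information.
- The generator's independence default understates the correlation between
  EV subpopulations measured on the same platform; LASSO selection behavior
  among correlated markers is therefore not emulated by default.
- Post-hoc power and repeated-splits p-values are descriptive; no
  inferential claims should rest on them.
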