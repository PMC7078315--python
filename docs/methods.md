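# Methods

This note documents the models and procedures `seratrend` implements, the
assumptions behind them, the defaults and why they were chosen, and the
limits of what the synthetic-cohort tests can demonstrate.

## Data model and inclusion rules

A cohort is a set of subjects, each an ordered series of visits carrying
marker concentrations; cases additionally carry months-to-diagnosis per
visit, which must imply a single diagnosis age (tolerance 0.1 yr across a
subject's visits).  All modelling happens on log10 concentrations; the
transform is applied once and the cohort is tagged, so double application
is an error rather than a silent distortion.

Three rules define the analysis sets:

* **Modelling filter** — annual screening samples only (an explicit
  `sample_kind` flag, not a spacing heuristic), case samples taken more
  than 60 months before diagnosis dropped (boundary retained), borderline
  subjects removed entirely.  "Within 1 year" and similar windows are
  closed bounds (≤12, ≤24 months); time-to-diagnosis is carried in months
  and ages in years with an exact factor of 12.
* **Evaluation windows** — `within_1yr` keeps cases whose final retained
  sample is ≤12 months before diagnosis; `yr1_to_2` first removes all case
  samples ≤12 months before diagnosis and then keeps cases whose new final
  sample is ≤24 months out.  Controls are never excluded by time rules:
  the comparison is always against the full control series.
* **Missingness** — a visit missing one marker keeps the visit; that
  marker's indices are computed on the reduced series.  Units whose
  features are undefined (single-visit series for the k≥2 indices) carry
  absent cells and drop out of an analysis only when that analysis uses
  those features, with a logged count.

## Trend indices

Five transforms collapse a series $(t_j, y_j)_{j=1..k}$ into a scalar.
Index 1 is the *unweighted* mean of consecutive gradients: weighting each
gradient by its interval length telescopes to the overall secant slope
$(y_k-y_1)/(t_k-t_1)$, which would make the "consecutive pairs" structure
vacuous; the telescoping form is retained behind `index1_variant=
"telescoping"`.  Index 2 averages per-interval trapezoid areas; the
alternative reading $\sum_j (t_k-t_j)y_j/k$ is available as
`index2_variant="to_last"`.  Index 3 is the sample-SD/mean coefficient of
variation with time ignored; on log10 values a mean near zero makes it
numerically fragile, so a warning fires when |mean| < 0.1.  Index 4 is the
age-weighted mean $\sum t_j y_j/\sum t_j$ (a convex combination of the
values, since ages are positive).  Index 5 is the final measurement, the
single-sample cut-off comparator.

Feature matrices come in two modes.  *Terminal* mode (one row per subject,
full retained series) is the modelling unit; *rolling* mode (one row per
subject-visit, using only data up to that visit) supplies per-visit score
trajectories for the lead-time analysis and visit-level specificity.  A
subject's final rolling row equals its terminal row by construction.

## Variable selection ensemble

Five criteria run on the complete-case terminal matrix; their union is the
candidate pool:

1. **Stepwise AIC** — bidirectional from the intercept-only model,
   AIC = 2p − 2ℓ, deterministic.  Perfect separation is flagged and the
   step is scored under a tiny ridge (1e-6) rather than aborted.
2. **Lasso, first-λ rule** — features standardised to zero mean/unit
   variance (the index scales are heterogeneous, so a common penalty is
   meaningless otherwise), λ scanned from 0 in steps of 0.01 on the
   mean-log-loss scale; the first λ whose active set has ≤3 features wins.
   The fit is an L1 logistic regression (liblinear) with C = 1/(nλ).
3. **Bootstrap lasso** — 200 resamples drawn with replacement *within*
   class (stratified, so no resample is single-class), the first-λ rule
   applied to each; a feature's score is its frequency of inclusion in the
   per-resample top-three active set.
4. **Mean accuracy decrease** — an explicit bagging loop over CART trees
   (√p features per split) so the importance can be measured out-of-bag:
   per tree, each feature is permuted among that tree's OOB rows and the
   accuracy drop averaged over trees.  OOB evaluation is what makes a
   label-independent feature's importance centre on zero; permuting on the
   training rows instead yields systematically positive importances for
   noise features (the forest memorises them), which we verified
   empirically before choosing the OOB loop.
5. **Gini importance** — mean per-tree impurity decrease from the same
   forest.

The pool is the union of the AIC set, the lasso set, and the top-5 by
bootstrap frequency, accuracy decrease and Gini importance (ties broken by
feature name).  All selection operations sort units by id internally, so
results are invariant to row order and fixed entirely by the seed.

## Model search and cross-validation

All logistic models with 1–3 main effects over the pool are enumerated
(lexicographic, deterministic) and scored by leave-one-*subject*-out CV:
in rolling matrices every visit-row of the held-out subject leaves with
it, preventing within-subject leakage.  A fold left with one class falls
back to predicting the training prevalence (counted and reported).  Models
are ranked by cross-validated sensitivity at 90.3% specificity (the
reporting axis of the analysis), ties going to fewer features and then to
name; cross-validated AUC is available as an alternative criterion.
Winners are refitted on all data.

The logistic core is a Newton–Raphson (IRLS) fit with step halving, exact
to statsmodels' ML estimates at tolerance (cross-checked in the test
suite) but fast enough for the ~10⁵ fold-fits of an exhaustive search.  On
separable data the likelihood plateaus near zero while coefficients
diverge; iteration stops on that plateau, the separation is flagged, and
the whole-data refit is retained under a 1e-6 ridge for numerical
stability.  Wald standard errors come from the observed information.

**A note on pooled LOOCV scores.**  Pooling out-of-fold probabilities
across folds biases the null cross-validated AUC *downward*: leaving a
case out lowers the training prevalence by ~1/(n−1), shifting its
out-of-fold score below the controls'; when the fitted slope is near zero
this dominates and the pooled AUC can collapse toward 0 (we measure mean
≈0.33 at n=60, ≈0.41 at n=400 under label shuffling, reproduced exactly
by an independent per-fold statsmodels fit).  This is the documented
pessimistic bias of pooled leave-one-out scoring and is inherent to the
prescribed procedure, not an implementation artefact; the guarantee
cross-validation actually provides — no optimism under the null — is what
the test suite asserts.  With real signal the effect is negligible.

## Evaluation

* **Fixed-specificity threshold** — the smallest threshold with at least
  the target fraction of control scores strictly below it; scores at or
  above the threshold are positive (ties positive: conservative for
  specificity claims and deterministic).  The default specificity unit is
  the control *visit* (rolling scores): with ~175 control annual samples,
  158/175 and 167/175 reproduce the 90.3%/95.4% operating points that 31
  control subjects alone cannot produce; subject-level specificity is
  retained as an option.  Case positivity is judged at each case subject's
  final eligible unit.
* **Sensitivity CIs** — 2000 stratified bootstrap replicates (cases and
  controls resampled independently), threshold *and* sensitivity
  recomputed per replicate, percentile 2.5/97.5; the bootstrap median is
  reported alongside the plug-in estimate.
* **AUC** — Mann–Whitney with ties counted half; variance by DeLong's
  structural components; Wald 95% CI truncated to [0,1].  Verified against
  pair-counting exhaustively and against R's pROC on a frozen instance.
* **McNemar** — exact one-tailed on discordant case calls, alternative:
  the model is more sensitive than the reference;
  p = P(X ≥ b), X ~ Bin(b+c, ½), p = 1 with no discordance.
* **Hosmer–Lemeshow** — deciles of predicted risk with ties kept
  together, χ² = Σ(O−E)²/(E(1−E/n_g)), df = groups−2, degenerate groups
  merged downward.
* **Univariate screen** — D'Agostino–Pearson normality gate at α = 0.05 on
  both groups chooses between Welch's t and Mann–Whitney (two-sided);
  groups under n = 8 (below the normality test's validity floor) default
  to Mann–Whitney with a warning.

## Lead time

Per-visit case scores are pooled on a years-to-diagnosis axis and smoothed
with locally weighted quadratic regression (tricube weights, default span
0.75, 200-point grid); pointwise bands come from the linear-smoother hat
rows with a global residual variance.  The crossing time is, scanning from
the earliest time toward diagnosis, the first time after which the curve
stays at or above the threshold through to diagnosis ("sustained", robust
to early blips; `first_touch` is available).  Lead-time gain is
(model crossing − reference crossing) × 12 months, positive when the model
turns positive earlier; it is antisymmetric under swapping the roles and
absent when either curve never qualifies.  Controls' time axis (years
since final sample) is used only for display, never for crossings.

## Synthetic cohort generator

The generator emulates the nested case–control serum set the analysis was
designed for.  Log10 concentration of marker m at a visit is

    b_m + s_m(type) · max(0, t − t_changepoint) + Normal(0, log10(1+CV_m))

with subject baseline b_m ~ Normal(μ_m, σ_m).  The change-point linear
rise was chosen because it admits an analytic oracle (`oracle_scores`
returns the noise-free value at each subject's final visit) for
parameter-recovery tests.  log10(1+CV) converts a stated assay CV into a
log-scale SD exactly in the small-CV limit of multiplicative error.
Visits sit on an annual grid with Normal jitter (SD 0.05 yr), nudged to
strict ordering; diagnosis falls Uniform(0–12) months after the final
visit, so the ≤1-year evaluation rule is exercised by default.

Defaults reproduce the study conditions: 31 controls, 9 Type I + 30 Type
II + 10 borderline cases, 3–10 annual visits, entry age Normal(61, 5)
truncated to the 50–74 screening window, and the ten-marker panel with the
assays' intra-assay CVs (CA125 4% … glycodelin 22%).  CA125 rises
strongest near diagnosis (0.55 log10/yr for Type II from 24 months out);
HE4, CHI3L1, PEBP4 and AGR2 rise modestly with earlier change points;
LRG1, FSTL1, SLPI, glycodelin and DNAH17 are uninformative so selection
has genuine noise to reject.  A separate 3-informative/7-noise benchmark
panel at ~3× the evaluation-set scale backs the recovery tests; its
informative markers' change points are staggered (18/30/36 months) so a
multimarker model can legitimately beat the single final-value cut-off on
both sensitivity and lead time.

What the generator does *not* emulate: assay drift and batch effects,
age–concentration trends, case–control matching (both groups share one age
distribution), tumour-growth kinetics, ROCA-triggered repeat samples, and
within-subject correlation beyond the stable baseline.  Passing recovery
tests therefore demonstrates that the pipeline recovers structure *of this
generative form*, not that the models would transfer to real serum data.

## Pipeline and determinism

`run_pipeline` executes simulate → read → filter → log10 → features →
select → search → evaluate (both windows × both strata, against the
`CA125{5}` reference) → leadtime, each stage reading from and writing to a
run directory so stages can be rerun in isolation, and finishes with a
MANIFEST of SHA-256 checksums.  One global seed expands to per-stage seeds
by fixed offsets (simulate +0, select +1, evaluation bootstrap +2); two
runs with the same config are byte-identical.  A run at the default study
scale takes ~20 s on one core; the heaviest test (20-seed parameter
recovery at 3× scale) runs inside five minutes.

## Known limitations

* The pooled-LOOCV null bias described above: cross-validated AUCs of
  near-null models are conservative, not centred on 0.5.
* With strongly informative generative slopes the synthetic task is close
  to separable, so top models often reach sensitivity 1.0 and ties are
  resolved by model size; real assay data would not be this clean.
* The Hosmer–Lemeshow test is undefined for models whose predictions
  collapse to fewer than three distinct values (e.g. fully separated
  fits); the pipeline reports calibration as unavailable in that case.
* Loess crossing times inherit smoothing bias near the change-point
  corner; the acceptance-level check uses a small span and dense points to
  keep that within one grid step, and real use should treat crossings as
  estimates with the displayed bands, not sharp onsets.
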