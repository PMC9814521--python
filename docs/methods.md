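# Methods

`cmpanel` implements a panel-discovery protocol for matched case–control
proteomic cohorts, of the kind used to search for circulating-microparticle
(CMP) protein classifiers of placenta accreta spectrum (PAS) in second- and
third-trimester plasma. This note records the models, the defaults and why
they are what they are, the numerical choices, and what the synthetic-data
validation does and does not establish.

## The discovery protocol

Input is a samples × proteins matrix of log-scale intensities and a binary
case/control label per sample. One *iteration* consists of:

1. **Split.** A stratified random 80/20 train/validation split. Stratification
   by case status is essential at these sample sizes (35 cases): unstratified
   splits can lose a class from a CV fold.
2. **Screen (train only).** L1-penalized logistic regression over a
   glmnet-style penalty path (20 penalties, geometric, from the smallest
   penalty that zeroes every coefficient down to 1/100 of it). The penalty is
   chosen by 5-fold cross-validated binomial deviance with the one-standard-
   error rule: the strongest penalty whose CV deviance is within one SE of
   the minimum. Proteins with nonzero coefficients form the candidate set.
   The 1-SE rule is deliberately parsimonious; under weak or absent signal
   it frequently returns the empty set, in which case the iteration is
   skipped and logged — this is by design, not an error.
3. **Rank (train only).** Each candidate is scored by the mean AIC of its
   single-predictor logistic fit over B = 50 bootstrap resamples of the
   training set (an ensemble feature-selection step); candidates are ordered
   by ascending mean AIC, ties broken lexicographically by protein id. A
   candidate constant on the training set gets a sentinel score of +inf and
   ranks last.
4. **Search (train only).** Every non-empty subset of the top 10 ranked
   proteins with at most 5 members (637 subsets) is scored by stratified
   5-fold cross-validated AUC on the training set. Selection is
   lexicographic: greatest mean fold-AUC; then (ties within 1e-9) smallest
   fold-AUC standard deviation; then smallest panel; then protein ids. The
   winner is refit on the full training set.
5. **Validate.** The refit panel scores the untouched 20%; one external AUC
   (rank/Mann–Whitney definition: concordant pairs plus half the ties over
   all case–control pairs) is recorded, with a Hanley–McNeil standard error
   as its spread, since a single validation set affords no resampling spread.

The protocol repeats for `n_iterations` (default 1000) fresh splits. Panels
are aggregated by protein-id set (coefficients ignored) and ranked by mean
external AUC (descending), mean external-AUC SE (ascending), selection count
(descending). Because distinct 5-protein subsets rarely repeat exactly,
`WorkflowResult.protein_selection_frequency()` gives the per-protein
selection rate, which is the stable aggregate readout; the reported
`top_panel` also carries the pooled mean external AUC over *all* retained
iterations alongside its own per-panel mean, the two defensible readings of
"the panel's mean AUC".

**Chance-level control.** The entire protocol is rerun with permuted labels:
one fresh permutation per workflow run (class counts preserved), external
AUCs pooled across runs. Observed and permuted AUC collections are compared
with a two-sided Mann–Whitney rank-sum test (AUCs are bounded and decidedly
non-normal; a Welch t-test sits behind a flag), and exported as Gaussian-KDE
curves (Silverman bandwidth, 512-point grid padded by four bandwidths) for
the observed-vs-permuted density figure. An all-tied vector degenerates the
normal approximation (0/0); the test then returns the statistic at its null
expectation with p = 1, and the density is drawn as a narrow Gaussian bump.

## Statistical primitives

- **Logistic fits** are a batched Newton/IRLS solver (linear predictor
  clipped at ±30, steps damped to max-norm 10, ridge 1e-10 on the Hessian,
  gradient tolerance 1e-8). Batching matters: the subset search performs
  ~3200 small fits (n ≤ 84, ≤ 6 parameters) per iteration, and solving each
  size class as one stacked `linalg.solve` keeps the 1000-iteration protocol
  tractable on one CPU. Perfect or quasi-complete separation — inevitable
  occasionally with 5-protein panels on 84 samples — is *kept*, flagged via
  `separated` (log-likelihood within 1e-6·n of zero, or a coefficient beyond
  25 on standardized predictors), because dropping separated fits would bias
  selection toward weaker panels; their scores still rank validation samples
  and AUC remains well defined. AIC is 2(p+1) − 2lnL.
- **Benjamini–Hochberg** is the hand-written step-up (sort, scale by m/rank,
  cumulative minimum from the largest rank, clip at 1, original order
  restored), validated in tests against brute force and statsmodels.
- **Chi-square** tests are Pearson without continuity correction by default
  (a correction flag exists); a zero margin or a single-level variable is a
  *degenerate table*, reported as a flag in summaries rather than raised.
- **Wilcoxon rank-sum** uses exact enumeration when both arms have ≤ 25
  untied values, otherwise the normal approximation with tie correction.
- **Differential screen**: per-protein Welch t-test on log2 intensities, one
  value per subject per trimester with trimesters analyzed separately — at
  one quantified value per sample the usual mixed-effects protein model
  reduces to exactly this two-group comparison. Missingness is handled
  pairwise-complete; proteins with fewer than two values in either arm are
  untestable and excluded from the BH family. Significance requires both a
  linear fold change ≥ 2 (|log2FC| ≥ 1, threshold inclusive) and BH-adjusted
  p < 0.05.

## The cohort simulator

The generator emulates the *structure* the protocol assumes, starting at the
quantified protein table (no spectra, peptides, or acquisition artifacts):

- 35 cases, matched 1:2 to controls on gestational age at sampling (±1 week)
  and fetus number; paired draws at ~26 (T2) and ~35 (T3) weeks (SD 2).
- Protein values on the log2 scale: per-protein baseline means ~N(20, 2),
  unit total variance split between a subject-level random effect shared by
  the two draws (variance ρ, default 0.5 — a plausible tracking of a
  subject's proteome across trimesters) and draw-specific noise (1 − ρ).
- A planted panel (default 5 proteins) shifted additively by `effect_size`
  standard deviations in cases, in both trimesters; all other proteins have
  exactly zero case–control difference. No protein–protein correlation.
- Missing cells masked completely at random (default 5%, a modest
  protein-level DIA-like rate); imputation is deliberately left to the
  analysis stages (training-median imputation in the workflow,
  pairwise-complete testing in the differential screen).
- Clinical covariates drawn to match the study population's contrasts
  (cases older, more previa, cesarean-history bins 65.7/20/14.3% vs
  78.6/14.3/7.1%, PAS grades 27:7:1 with per-grade ultrasound detection
  11.1/57.1/100%). The classifier never sees them, mirroring the
  protein-only panels.
- `n_proteins` defaults to 500 — a stand-in for a quantified CMP matrix, as
  the true post-filtering protein count is study-specific; it is ordinary
  config.

Everything is a pure function of the config including its seed; per-stage
and per-iteration seeds derive from one root via `SeedSequence.spawn`, and
no stage touches global RNG state. `reference_cohort()` is separate from the
simulator: a deterministic clinical table carrying the exact categorical
composition above, for worked examples and arithmetic checks.

What passing synthetic tests does *not* show: real CMP data have correlated
proteins, batch structure, intensity-dependent missingness and non-normal
tails, none of which the generator produces. Recovery rates here are
best-case; the value of the synthetic harness is falsification (leakage,
miscalibration, and bookkeeping errors would show) rather than a promise of
field performance.

## Calibration subtleties

Two properties of the protocol are easy to mis-measure and worth recording:

- **External AUCs from one cohort are correlated.** Iterations share the
  dataset, so a cohort's lucky spurious features recur across splits; under
  a global null the per-cohort mean external AUC has a between-cohort SD of
  roughly 0.06 even at many iterations. Chance-level calibration (mean 0.5)
  is therefore estimated by pooling iterations across *independent* null
  cohorts (the acceptance suite uses 30 cohorts × 20 iterations; the
  acceptance script 15 × 15), not from a single cohort. The same effect
  explains permuted-label means that sit a few hundredths off 0.5 in any
  one dataset.
- **Retention under the null is low (~35%)** because the 1-SE screen
  returns empty candidate sets on noise; retained-iteration summaries are
  conditional on the screen finding something.

## Problem sizes used in validation

The automated suite runs the full protocol at reduced replication chosen as
the package's own accuracy/runtime balance: planted-recovery at 200
iterations (d = 1, 5 planted in 500 proteins, n = 105), permuted pooling of
150–200 iterations, monotonicity in d over {0, 0.5, 1.0, 1.5} at 25
iterations each (with 0.05 Monte-Carlo slack on recovery fractions and 0.02
on mean AUC), null calibration as above, 1e5 protein-replicates for the
differential type-I rate, and byte-identity of two 50-iteration end-to-end
runs. Oracle-equivalence checks (AUC vs pairwise enumeration, BH vs brute
force, subset enumeration vs an independent bitmask enumerator) use 1000
random instances each.

## Known limitations

- The ensemble feature-selection step is one defensible reading of
  "bootstrap-averaged univariate AIC"; other ensemble schemes (multivariate
  resampled fits, rank aggregation) would rank differently in edge cases.
- The mean-external-AUC panel ranking favors one-off lucky panels at small
  iteration counts; use the selection-frequency readout alongside it.
- Hanley–McNeil SE assumes the binormal-ish large-sample regime; at 21
  validation samples it is a rough spread, used only for tie-breaking and
  reporting.
- Trimesters are processed independently; the paired structure is used only
  by the simulator, not exploited by the classifier.
- No clinical covariates in the classifier, and no attempt to normalize
  beyond the log scale — upstream processing is assumed done.
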