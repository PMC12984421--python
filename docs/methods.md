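# Methods

`uromethyl` re-implements, as a tested library, a urine cell-free-DNA
(cfDNA) analysis for non-invasive bladder-cancer detection: windowed
methylation features from whole-genome enzymatic methyl-seq counts,
differential-methylation marker selection, tissue–urine concordance,
copy-number (CNV) and tumor-fraction features, per-modality boosted-tree
classifiers, and an equal-weight ensemble with exhaustive feature-subset
search. Because the underlying sequencing data are not publicly available,
every stage is driven and validated by a synthetic cohort generator with
known ground truth; this note documents the model, the generator, the
estimators, and the numerical choices.

## The measurement model

Input is a per-sample, per-CpG table of methylated/unmethylated read counts
(bedGraph-like TSV, 0-based half-open coordinates). The genome is tiled
into fixed 300-bp windows; windows overlapping a blacklist interval by at
least 1 bp are removed before any analysis. The average methylation
fraction of window *w* in sample *s* pools counts over the CpGs in the
window:

    AMF_s(w) = sum_i meth_i / sum_i (meth_i + unmeth_i)

A window is missing for a sample when its pooled read total is below 30
(`coverage_rule: window_total`; a stricter `per_cpg` variant drops the
window when any covered CpG has < 30 reads — the pooled rule is the default
because AMF itself is defined on pooled counts). Global methylation is the
mean AMF over covered windows; its inversion `1 − GM` is the per-sample
feature, since tumors are globally hypomethylated. Samples whose
CHH-context cytosine conversion efficiency is below 97% fail QC.

## Marker selection

Markers are called by contrasting cancer **tissue** AMF against healthy
**urine** AMF — deliberately across biofluids, because tissue shows the
undiluted tumor methylome while healthy urine is the background against
which urine tests operate. Per window: Welch's unequal-variance t-test
(scipy), Benjamini–Hochberg correction across all tested windows
(statsmodels), then strict thresholds FDR < 1e-5 and |ΔAMF| > 0.25, with a
support filter of ≥ 12 healthy and ≥ 4 cancer observations before testing.
Windows with zero variance in both groups have an undefined p and are
skipped. Direction (hyper/hypo) is the sign of ΔAMF. BH is applied over the
whole testing universe at once, not per chromosome.

## Tissue–urine concordance

For each window, the concordance of a matched tissue–urine pair is

    (AMF_urine − AMF_healthy) / (AMF_tissue − AMF_healthy)

with the healthy baseline the per-window mean over healthy urine samples.
Under a tumor/background mixture the expected ratio is exactly the urine
tumor fraction, so positive values indicate directional agreement.
Denominators below 1e-6 in absolute value make the pair undefined for that
window; the per-window summary is the median ratio over defined pairs, and
"positive concordance" means median > 0 strictly. Fractions of positive
windows are reported separately for marker and background (all other
support-passing) windows; on mixtures with tumor fraction > 0 the marker
fraction is strongly enriched, as the marker definition predicts.

## CNV profiles and the tumor-fraction estimator

Read counts in 1-Mbp bins are scaled to equal totals; the panel-of-normals
baseline is the per-bin median over scaled healthy samples, and the profile
is `log2(scaled_sample / baseline)` (missing where the baseline is zero).
Note the profile is defined only up to the scaling constant: a genome with
net gains is deflated overall.

Tumor fraction is estimated by a deliberately simple deterministic stand-in
for HMM-based tools: the mixture identity for a clonal integer copy number
*c* at tumor fraction *tf* is

    E[log2 ratio] = log2((1 − tf) + tf·c/2)

The estimator (1) median-centers the profile (valid while most bins are
copy-neutral), (2) over a tf grid (0–0.75, step 0.01) assigns each bin the
state c ∈ {0..4} minimizing squared deviation plus a parsimony penalty
λ·|c − 2| (λ = 0.02), choosing the tf with the lowest total cost, ties to
the smaller tf, and (3) re-estimates tf as the median over called
non-diploid bins of the per-bin inversion `(2^r − 1)/(c/2 − 1)`, after
re-centering on the called-diploid bins. Step 3 removes the upward bias the
penalty induces at low tf (penalty savings favor larger amplitudes), and
the median is robust to a few mis-called noise bins. The |c − 2| scaling of
the penalty breaks the exact aliasing between state 3 at tf and state 4 at
tf/2. Known limits: events below the per-bin detection threshold
(amplitude ≲ 2 bin-noise sd) are missed, and the few bins that do get
called overestimate tf (winner's curse) — visible as |error| ≈ 0.1 at
tf = 0.1 with noise sd 0.05, while tf ≥ 0.2 is recovered within a few
points. tf = 0 always returns an all-diploid state vector. No GC or
mappability correction is applied (the simulator emits unbiased counts);
there is no segmentation or subclonality, and no claim of numerical
equivalence to HMM estimators.

## Models and evaluation

Two gradient-boosted tree classifiers — methylation (marker-window AMFs)
and CNV (all-bin log2 ratios) — are evaluated by 10-repeat stratified
3-fold cross-validation (30 fits per model). Within every fold, missing
values are imputed with per-feature medians of the *healthy training*
samples of that fold; the same stored medians impute any later-transformed
set, so validation and test data never influence the learned state. The
hyperparameters are fixed (no search): max_depth 3, eta 0.01
(methylation) / 0.1 (CNV), 200 rounds, subsample 0.7, column subsample 0.6,
min child weight 5. The learner is pluggable behind a scorer contract; the
default maps these onto scikit-learn's `GradientBoostingClassifier`
(`colsample_bytree → max_features`, `min_child_weight → min_samples_leaf`
as nearest analogues) because xgboost is not part of the supported
environment. Stratified folds are used to avoid degenerate folds at n ≈ 70.

Four per-sample features on a [0,1] scale — methylation score, CNV score,
inverted global methylation, tumor fraction — are combined by an
equal-weight sum (the mean of the selected subset). All 15 non-empty
subsets are scored by repeated-CV AUC of the subset mean over out-of-fold
modality scores (weights are fixed; nothing is refit per subset); per
repeat the AUC is the mean over the three validation folds. The winning
subset has the highest median per-repeat AUC, ties broken by smaller
subset, then lexicographic order. Final models are retrained on the full
training split and applied once to the held-out test split. The operating
threshold is the smallest score achieving ≥ 80% specificity on healthy
*training* scores (a config flag switches to test-set quantiles for
reproduction studies). Evaluation reports rank-based AUC, the confusion
matrix at the operating point, comparison and OR-combination with a binary
mutation test (positive when either test is positive), and Vickers–Elkin
net benefit `TP/n − (FP/n)·pt/(1 − pt)` over a threshold-probability grid
with treat-all/treat-none references.

On the instability of the subset search: with 10 repeats the median
per-repeat AUC of each subset carries sampling noise of a few AUC points,
and subsets that differ only by a near-constant feature (the inverted
global methylation varies by ~0.02 while model scores span [0,1]) are
near-ties. The exact argmax selector is therefore unstable between the
{methylation, CNV} pair and its supersets; see the limitations section.

## The synthetic cohort generator

The generator states a world mirroring the study design: a marker cohort
of 14 cancer tissues and 14 healthy urines (plus matched urine samples of
the tissue donors for concordance), 31 cancer + 41 healthy training urines
and 37 cancer + 20 healthy test urines; 300-bp windows; 1-Mbp CNV bins; a
heavily hyper-skewed DMR set (default 200 hyper, 10 hypo); a mutation
panel that is positive for a cancer sample with probability 30/37 and
always negative in healthy samples.

Signal model per sample: a per-window healthy baseline is drawn once per
cohort from Beta(0.6, 0.25) (bimodal, mostly methylated). Each sample adds
a global background offset (Normal, sd 0.02) and independent per-window
noise (Normal, sd 0.05), clipped to [0,1] — between-subject global and
per-locus methylation variability, which in real methylomes far exceeds
read-sampling noise; without it, samples are binomial-exact replicates and
classifiers become unrealistically perfect. The tumor methylome shifts
hyper-DMR windows by +`dmr_effect` (default 0.3) and hypo windows by the
negative, and lowers all other windows by a stage-dependent global
hypomethylation (NMIBC 0.02, MIBC 0.05). DMRs are planted in windows whose
baseline leaves room for the full effect (hypermethylation at
CpG-island-like unmethylated regions). A fluid sample mixes healthy and
tumor profiles at tumor fraction tf — tissue tf = 1, urine tf drawn per
stage (NMIBC uniform 0.1–0.4, MIBC 0.3–0.6; free parameters, not
calibrated to any published figure), plasma tf scaled by 0.3 — and per-CpG
methylated reads are Binomial(depth, p) with Poisson(50) depth. CNV bin
counts scale with `(1 − tf) + tf·c/2` (default clonal events: a 3-copy
gain over 30% of bins, a 1-copy loss over 10%) with log-normal noise,
sd 0.1 in log2 units. All randomness derives from one seed through keyed,
independent streams (genome / patient / sample), so resizing one split
cannot perturb another — the no-leakage tests rely on this.

What the generator does **not** emulate: fragment-level or fragmentomic
structure, sequencing errors or conversion failure beyond a scalar
efficiency, GC/mappability bias, clonal hematopoiesis background,
patient-specific CNV breakpoints (events are shared across cancer
patients), correlated methylation between neighboring windows, and
covariates such as age or smoking. A green pipeline test therefore
establishes internal correctness of the estimators and the split
discipline on a mixture world — not clinical performance.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open (BED) everywhere; bedGraph input is
  assumed 0-based; a 6-column dialect with a percent column is accepted.
- `conversion_efficiency` with a zero denominator raises (sample flagged
  unevaluable) rather than returning a value.
- `global_methylation` of an all-missing row raises; missing windows are
  ignored, not imputed, at this stage.
- Cosine similarity to the tissue reference uses raw AMF (no centering) on
  the windows covered by the sample and by *every* tissue row; fewer than
  2 shared windows raises. Whether to restrict to marker windows is
  configurable by passing a column subset; all mutually covered windows is
  the default.
- FDR and ΔAMF thresholds are strict inequalities; "AMF difference" is the
  absolute mean difference.
- `threshold_at_specificity` returns a data value (or just above the
  maximum), so tied healthy scores can only raise, never lower, achieved
  specificity.
- The single run seed fans out to per-stage seeds via SHA-256, keeping all
  derived seeds below 2^31.

## Known limitations

- The tumor-fraction stand-in is detection-limited at tf ≈ 0.1 for
  realistic bin noise; its errors there are ~0.1 (overestimates from the
  few loudest bins). Downstream it is only a scalar feature, so this
  mainly widens the feature's noise.
- Both modalities' difficulty scales with the same tumor fraction, so
  their errors correlate; equal-weight averaging of the methylation and
  CNV scores yields only small margins over the best single modality, and
  the 15-subset argmax frequently lands on a near-tied superset containing
  a noise feature. This mirrors a genuine fragility of subset selection by
  repeated-CV argmax at n ≈ 70 rather than a defect of the scoring.
- Threshold transfer from training healthy scores to the test set is
  imperfect when score distributions shift; the reported test specificity
  can deviate noticeably from the 80% target at these sample sizes.
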