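# Methods

`infoshare` re-implements, as a tested pipeline, a resting-state EEG
information-sharing analysis used to characterize behavioral-variant
frontotemporal dementia (bvFTD): weighted symbolic mutual information
(wSMI) connectivity between scalp electrodes, three topographic group
analyses (ROI-pair averages, connectivity versus distance, a two-stage
seed analysis), and repeated-holdout SVM classification from
neuropsychological and connectivity features. Because no patient EEG is
available, a synthetic cohort generator provides ground truth, and the
package's claims are statistical: correct calibration under the null and
reliable recovery of effects of the size the original study reports.

## Connectivity measure

Each channel is reduced to ordinal patterns: the symbol at time *t* is the
permutation sorting the samples `x[t], x[t+τ], …, x[t+(k−1)τ]`. Defaults
are `k = 3` (six symbols) and `τ = 16 ms` (4 samples at 256 Hz). Ties rank
the earlier sample lower (stable argsort), a deterministic convention that
is measure-zero for continuous signals. Symbolic mutual information is

SMI(X,Y) = Σ₍x,y₎ p(x,y) · log₂[ p(x,y) / (p(x)p(y)) ] / log₂ k!

with joint symbol counts pooled over all epochs of one subject before
normalization, so SMI ∈ [0,1]. wSMI multiplies each cell by a 0/1 weight
that removes identical symbol pairs and sign-mirrored pairs (the
permutation of the negated samples); these are the patterns a single
common source seen through volume conduction produces at zero lag. wSMI
can be slightly negative, and it is *not* bounded by SMI for arbitrary
joint tables — removing a cell whose pointwise term is negative raises the
sum. On joints that arise from actual signal pairs, where identical and
mirrored patterns co-occur at least at chance level, wSMI ≤ SMI holds and
the test suite asserts it there.

The τ default was chosen for alpha/beta sensitivity and is verified
empirically: lag-coupled sinusoid pairs at 8–20 Hz yield wSMI an order of
magnitude above identically constructed 2 Hz pairs. τ and `k` remain
configurable.

## Montages and ROIs

All analyses are scalp-level and use only relative geometry, so electrodes
live on an idealized unit sphere and distances are chordal (range [0, 2]).
Two deterministic layouts are built in: the 20-channel 10/20 set at the
classical spherical angles, and a 128-channel cap from near-equal-area
azimuthal rings. Seven ROIs (left/right frontal R1/R2, right/left temporal
R3/R6, right/left posterior R4/R5, central R7) are assigned by a purely
geometric elevation/azimuth sector rule (central above 40° elevation;
frontal within 60° azimuth of the anterior axis; temporal to 130°;
posterior beyond), applied uniformly to both layouts so subsetting
preserves assignments. The reference cap's exact electrode-to-ROI map is
published only graphically, so the sector rule is an approximation that
keeps all seven regions non-empty in both layouts.

## Group analyses

* **ROI pairs.** For each of the C(7,2) = 21 unordered ROI pairs, the mean
  wSMI over all inter-regional electrode pairs (within-ROI pairs excluded)
  is compared between groups with a two-sided unpaired Wilcoxon rank-sum
  test: exact enumeration on midranks when the pooled sample has ≤ 12
  observations, otherwise the normal approximation with tie correction and
  no continuity correction. Benjamini–Hochberg FDR (q = 0.05, via
  statsmodels) flags discoveries, and Cohen's d uses the pooled n−1
  weighted SD. Throughout, positive signs mean controls above patients.
* **Distance profiles.** Connections from a seed ROI's electrodes to all
  ROI-external electrodes are binned by chordal distance into three
  equal-width tertile bins over the observed range (a 0.15-wide sliding
  window stepped by 0.05 is available for p-versus-distance curves; the
  original bin width is unpublished). Group differences per bin use a
  Monte-Carlo label permutation test — statistic |Δ of group means|, all
  bins sharing each shuffle, add-one estimator p = (exceedances+1)/(n+1),
  default 5,000 permutations. The permutation split is canonicalized to
  the smaller group so that swapping group order reproduces identical
  p-values. A within-group bootstrap variant exists behind a flag but is
  off by default; label permutation is the defensible core of the cited
  procedure, whose exact scheme is unpublished.
* **Seed analysis.** Every seed-ROI electrode is tested against every
  ROI-external electrode (rank-sum per connection). Per external
  electrode the map reports the median p over seeds, a signed score
  `sign · (−log₁₀ median p)` — the sign is that of the median of
  W − E[W] across seeds, controls entered first, so scores beyond +1.3
  mean significant patient hypoconnectivity — and the count of
  connections surviving FDR, corrected within each seed ROI separately.
  Stage 2 averages the left and right frontal maps over their shared
  externals, declares a region significant when any of its electrodes
  exceeds +1.3, takes each significant region's five highest-scoring
  electrodes (ties broken by channel label) as new seeds, and re-runs the
  analysis; significant stage-2 externals falling in the frontal ROIs
  become the "new left/right frontal" regions.
* **Demographics.** Summary-statistic group comparisons use the
  pooled-variance two-sample t-test (this, not Welch, reproduces the
  published p-values exactly) and the Pearson chi-squared test without
  continuity correction for the 2×2 sex table.

## Classification

Six connectivity variables (CNVs): two distance-range means (left frontal
over 0–1.45, right frontal over 0.6–1.45, the ranges selected in the
emulated study) and four electrode-set means linking the stage-2-derived
new frontal regions to the left-parietal and right-temporal hub sets. On
cohorts where a seed stage selects nothing (null cohorts), the affected
set falls back to the full scalp ROI and is flagged, keeping the feature
table computable. Nineteen neuropsychological variables (NPVs) complete
the three feature modes (NPV / CNV / BOTH).

The protocol is a repeated random holdout: each of 1,000 repeats trains on
seven randomly drawn subjects per group — features z-scored by training
statistics — and classifies the rest, so a 13 vs 25 cohort always holds
out 6 patients and 18 controls. The SVM is linear with C = 1 (kernel and
hyperparameters are unpublished; this is the smallest defensible choice at
n = 38, and both are configurable). Because test sets are imbalanced, the
"classification rate" reported is mean balanced accuracy, with raw
accuracy alongside. ROC/AUC pool the decision scores of all held-out
subjects across repeats. Hotelling's T² compares the per-repeat
(sensitivity, specificity) pairs of two models with the F approximation;
repeats resample one cohort, so that p-value is descriptive.

## Synthetic cohorts

Defaults emulate the study design: 13 patients vs 25 controls, 20-channel
montage, 60 epochs × 2 s at 256 Hz (the dense cap is supported but slow),
8–20 Hz band. Each channel is 1/f background plus independent band-limited
noise; every ROI pair additionally shares one band-limited source passed
through tanh, received by the second region 16 ms later — exactly the
lagged nonlinear dependence wSMI targets, while zero-lag sharing is nulled
by the mirror weighting. A per-subject log-normal jitter (σ = 0.2) on the
coupling weights creates between-subject variance. For links listed as
altered, the weight is multiplied by (1 − `coupling_drop`) in patients
only, and the removed variance is replaced by channel-independent band
noise so that patient channels keep the same power and spectrum —
without this, unaltered links of the affected ROIs spuriously *gain*
wSMI in patients. `coupling_drop = 0` therefore yields bit-identical
generative laws for the two groups.

The default altered set is every frontal-to-temporal/posterior link
(R1/R2 × R3/R4/R5/R6), the broad mid/long-range frontal hypoconnectivity
with short-range preservation that the emulated study describes; narrower
sets are configurable but dilute the distance-profile deficit below
reliable detectability. `coupling_drop = 0.25` and `base_coupling = 1.5`
were calibrated once, by measuring the subject-level Cohen's d of the
ROI-pair wSMI on altered links over 150 subjects per group: d ≈ 0.99–1.05,
the effect-size regime (0.98–1.11) the study reports as adequately
powered at these group sizes.

NPV scores are truncated-normal draws per variable and group; the four
published global scores use the printed means/SDs, the fifteen subscores
are plausible inventions on the tests' real score ranges. Variables are
drawn independently, which makes NPV-based classification more optimistic
than on real, correlated test batteries — synthetic NPV rates near 1.0
should not be read as clinical performance. The generator also omits
artifacts (blinks, EMG), volume conduction, and any realistic forward
model, so passing tests demonstrate statistical correctness of the
pipeline, not field performance on recorded EEG.

## Validation studies and problem sizes

* **Null calibration** (300 cohorts, shortened recordings of 12 × 1 s
  epochs, since type-I error does not depend on estimator precision):
  pooled rejection rates of the 21 ROI-pair rank-sum tests and the
  tertile-bin permutation tests at α = 0.05 must lie within 0.05 ± 0.03.
* **Recovery** (50 cohorts at the full default design, 500 permutations,
  200 SVM repeats): at least one injected ROI pair flagged with the
  correct sign, a mid- or long-range frontal permutation deficit, and a
  stage-1 seed hotspot on an injected target region must each appear in
  ≥ 80% of cohorts; CNV balanced accuracy must exceed 0.65 there and stay
  within 0.50 ± 0.06 on null cohorts (the ± 0.05 chance band of the
  permuted-label reference, widened for the small-sample pessimism of
  holdout estimates on twelve finite cohorts).

These sizes keep the full suite and the acceptance script at desk scale;
all counts are arguments, so larger replications are one call away.

## Numerical choices and degenerate inputs

Zero pooled SD yields Cohen's d = NaN (flagged) unless means agree (0);
the summary t-test returns p = 1 for identical constant groups and flags
the degenerate unequal-mean case. Empty distance bins carry NaN means and
zero counts rather than zeros. Rank ties use midranks everywhere.
Permutation p-values are floored at 1/(n_perm+1). The master seed fans
out by fixed offsets (cohort +0, permutation tests +1, classifier
holdouts +2), and every stage is bit-reproducible given the seed.
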