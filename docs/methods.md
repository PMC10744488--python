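# Methods

## The IH33 signal

A detected field-potential (FP) train in a 1.5 s EVestG segment is reduced
to the intervals `t[i+33] − t[i]` for every valid index `i` (sliding,
overlapping windows). With ~3.3 ms mean FP gaps this lag-33 interval is
~100 ms, so the histogram probes modulation of the firing pattern near
10 Hz. Overlapping windows are a deliberate choice: non-overlapping
33-FP blocks would give only ~13 intervals per segment, far too few for a
meaningful 25-bin histogram, whereas sliding windows give ~420 (at the
350-FP quality-control minimum and above).

The histogram grid has 25 logarithmically spaced centers
`c_k = 31.2 × 1.0823^k` ms (k = 0…24, ≈ 31–208 ms). The constant ratio was
recovered by fitting the published feature-bin midpoints (68.9, 74.5,
80.6, 87.3, 94.5, 129.6, 140.2, 151.8, 164.3 ms), which all land on this
grid at integer k between 10 and 21; the absolute placement of the edges
is not recoverable from published material, so edges are defined as
geometric midpoints of the centers, with the outer edges extrapolated at
the same ratio. Both parameters are configurable (`BinGrid`). Intervals
falling outside the grid are clipped into the end bins rather than
dropped, preserving unit mass; end bins are excluded from features anyway.

## Quality control

Three exclusion rules run in order, and the first failure is reported:

1. **Non-smooth occurrence curve** — the FP occurrence time versus FP index
   must be semi-linear. Operationalized as: maximum absolute residual from
   a linear fit > 10% of the segment duration, or any single inter-FP gap
   > 20× the median gap. Thresholds configurable; the original criterion
   is qualitative ("stepwise rather than semi-linear").
2. **Too few FPs / short span** — fewer than 350 FPs, or occurrence times
   spanning less than 97% of the segment duration.
3. **Bimodal histogram** — modes are located on a 3-bin moving-average
   smoothed copy of the histogram; mass is partitioned at the deepest
   trough between the two largest modes, and the segment is rejected when
   the smaller side holds more than 10% of the mass. The original
   criterion names the 10% threshold but no detector; this is the
   package's operationalization.

## Derived signals

Per subject, the per-segment histograms are augmented with posture
averages and ear combinations. The supine posture contributes its four
background segments (BGi and RTC BGi of both supine tilts) to the "Supine
average". The upright posture has ten background segments but the original
design uses seven; since the composition is not enumerated, the default
here is the BGi of all five upright tilts plus the RTC BGi of the up/down
and back/forward tilts, and the composition is a parameter. `LR` (bin-wise
sum, renormalized to unit sum so all normalized signals share one scale)
and `L-R` (bin-wise difference, left signed as an asymmetry signal) are
formed for every background signal including the posture averages.
Averages skip missing segments and record the divisor actually used; an
average with no available segments is missing, never zero.

## Feature discovery and selection

Training sets leave 20% of each group out (rounded, at least one subject,
which is why populations below five members are rejected). A repair pass
guarantees every subject is held out at least once across the collection.

Band separation uses SE = SD/√n per bin (the band width is otherwise
unspecified in the source material). A feature requires separating bins on
both sides of a crossing of the two group-mean curves — the stricter
reading of "regions at either side of the crossing"; a flag relaxes this.
Regions are the maximal contiguous separating runs nearest to the
crossing; with several crossings, the one flanked by the most separating
bins wins. The first and last two bins and the three bins at the pooled
mean's peak are never part of a region. The feature value is
`mean(high region) − mean(low region)` with a fixed sign convention —
always high minus low, independent of group order — so the feature is a
monotone index of shift toward longer intervals. The significance gate
applies Shapiro–Wilk at α = 0.05 to each group (an unstated α in the
source; constant samples count as non-normal), then an unpaired t-test if
both pass, otherwise the two-sided Wilcoxon–Mann–Whitney test.

Per training set, the significant candidates enter an exhaustive SVM
search over all subsets of size ≤ 3, scored by training accuracy, with
ties broken by the subset with fewer missing values and then
lexicographically (fully deterministic). `max_candidates` (pipeline
default 10) optionally caps the per-set pool at the smallest p-values
before the combinatorial search; the search over the pool itself is always
exhaustive. Across sets, features are identified by (signal key,
orientation): regions vary between resamples, so the consensus region
keeps the bins present in more than half of a feature's selected
instances. The final subset is chosen among the top-frequency consensus
features (pool of 6) by the highest 10-fold cross-validated test accuracy
recomputed on common regions — the documented interpretation of combining
"most frequently repeated" with "highest test accuracy". A stability check
reruns the whole procedure with fresh resamples (default 3 repeats) and
reports the Jaccard agreement of the final signal keys.

## Classification and fusion

The SVM is linear with C = 1 (kernel unstated in the source; with 2–3
features, tiny cohorts and downstream sigmoid calibration the simplest
margin model is appropriate; RBF is available via `SVMConfig`).
Missing-value handling is leakage-safe and literal about "Z-score
normalized before and after imputation": observed values are standardized
with training statistics, missing entries are imputed in standardized
space with class-conditional training means (pooled training means for
unlabeled or blind rows, whose class is unknown), and the result is
re-standardized. All statistics come from training folds only.

Tilts reaching ≥ 75% averaged test accuracy are informative; if none
reaches the threshold the pipeline falls back to the single best tilt
(with a warning) so downstream stages always run. Pooled features (union
of the informative tilts' final features, plus any externally supplied
feature columns such as averaged-FP-waveform features from a prior
analysis) are re-reduced per training set and re-selected by CV; feature
extraction is not repeated at this stage because the features are known.

Platt calibration uses sigmoid calibration on SVM decision values
(`CalibratedClassifierCV(method="sigmoid", ensemble=False)`, 5-fold). The
class weights W_X^B are the training-averaged recall of class X in
problem B — sensitivity when X is the positive (first-named) class,
specificity when negative — taken from the pooled-feature classifiers'
cross-validation, not the per-tilt ones. Raw scores are the arithmetic
mean of the two weighted probabilities (the score expression wraps exactly
two products); normalized scores divide by the three-score sum, with a
uniform 1/3 fallback (and warning) for the all-zero corner case. The MoCA
gate restricts subjects scoring ≤ 23 to the AD/AD-CVD comparison; exact
score ties resolve in the fixed order AD > AD-CVD > Control (ties have
measure zero in practice; the order makes output deterministic). A subject
missing all features of one binary problem falls back to the single
available problem's weighted probability; a problem with no surviving
features contributes flat 0.5 probabilities through a trivial classifier,
i.e. no evidence.

Blind cohorts are evaluated two ways: the per-problem 5-fold
cross-validation on the blind subjects (the original study's protocol,
`blind_folds=5`) and the direct diagnosis of blind subjects by the
classifiers trained on the training cohort (the stricter out-of-sample
reading, used for the three-way blind metrics).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
the recording physics. Inter-FP gaps are gamma distributed (positive
support; coefficient of variation `gap_cv`, default 0.6), giving unimodal,
approximately log-normal lag-33 histograms. The class effect is a signed
shift of the subject's mean lag-33 interval: `shift_ad` (+10 ms default)
and `shift_adcvd` (−10 ms) relative to the control mean
(`base_mean_interval`, 108.9 ms = 33 × 3.3 ms), with between-subject SD
`within_class_sd` (6 ms). These effect sizes were set so that single-tilt
binary cross-validated accuracies land in a plausible 70–90% band at the
original cohort sizes (measured ≈ 84% mean); they are deliberately not
tuned to reproduce any published table. The shift can be restricted to
chosen (tilt, phase) segments (`shift_segments`) to plant a localized
effect for recovery tests. MoCA, age and sex are drawn per class from the
published demographics (Control MoCA 27.6 ± 1.7, AD 16.4 ± 4.8, AD-CVD
17 ± 4.4); age and sex carry no planted signal effect, mirroring the
reported absence of covariate effects. A `missing_rate` fraction of
segments (default 5%, the reported exclusion rate) is dropped at random.

The fast path `generate_ih33_cohort` bypasses FP simulation and emits
histograms directly: a discretized log-normal curve (log-width
`ih33_log_sd` = 0.25) around the subject's class-shifted mode, sampled as
multinomial counts (`ih33_n_intervals` = 422, the interval count of a full
segment), then combined exactly like real data.

What the generator does not emulate: recording artifacts with structure
(electrode drift, chair jitter), segment-to-segment physiological
variability beyond counting noise, tilt-specific response differences, and
any correlation between MoCA and signal shift within a class. Passing
tests therefore demonstrate that the pipeline recovers the class structure
it assumes, with correct bookkeeping and no information leakage — not that
the published clinical accuracies are reproducible, which would require
the original recordings.

## Problem sizes and numerical choices

Default pipeline runs use 100 resampled training sets (the minimum
full-coverage design is 25 for five-subject groups; the original study
used 1600, which this implementation supports but does not default to) and
the test suite and acceptance script run planted-recovery at 3 repeats ×
100 sets on a 3 × 20 cohort and null calibration at 10 runs × 20 sets on
3 × 15 cohorts with two tilts — sizes chosen to keep a full run in the
minutes range on one CPU while leaving the statistical conclusions
unchanged. All randomness flows from one master seed through tagged
CRC-derived stream seeds, recorded in the run manifest together with every
threshold in effect; identical configuration and seed reproduce
byte-identical numeric outputs.

The command-line interface exposes `simulate`, `build-ih33`, `run-all` and
`evaluate`; the extraction/selection/training/diagnosis stages are folded
into `run-all` (they share in-memory classifier state) but write all their
artifacts — per-tilt performance table, selection report, per-subject
score sheet, confusion matrices, manifest — as standalone CSV/JSON.

## Known limitations

* The null-calibration yield of the discovery stage is intrinsically
  liberal: mutual separation of one-SE bands fires per bin with
  probability ≈ 16% for i.i.d. group means, and the significance test is
  applied to the region the same data selected, so under a global null
  roughly a fifth of signals yield a "significant" candidate per training
  set. The resampling-consensus stage, not the per-set gate, is what
  controls false discoveries.
* Diagnosing the training cohort with classifiers fit on it is optimistic
  even under the null (~75% three-way balanced accuracy measured); blind
  evaluation is the meaningful number.
* No multiple-comparison adjustment is applied across signals or training
  sets, replicating the original design.
* The exact 7-segment composition of the upright background average and
  the original study's bin-edge placement are not recoverable and are
  configurable assumptions here.
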