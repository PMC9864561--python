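# Methods

This note documents the models and procedures implemented in `stmvpa`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data tests do and do not establish about real
recordings.

## Conventions

Time is always milliseconds relative to stimulus onset; decoding
accuracies are percentages (pairwise chance = 50%); correlations are
unitless; voxel grid coordinates are 0-based integers indexing the array
directly. All randomness flows from explicit integer seeds;
`stmvpa.io.derive_seeds` splits one master seed into independent
substreams (kept below 2³¹).

## Synthetic data model

The generator emulates a design with `n_categories` object categories
shown in three depiction types (photo, drawing, sketch). Category
patterns live in an abstract feature space: per depiction,

    P_d = √s · C + √(1 − s) · S_d,

with `C` and `S_d` iid standard normal and `s = shared_fraction ∈ [0, 1]`,
so that corresponding patterns of two depictions have expected correlation
`s`. `s = 1` models a representational format fully tolerant to
abstraction; `s = 0` models depiction-specific formats. This is the knob
behind the cross-decoding recovery tests.

**Epochs.** Channel data are `profile(t) · (M · p) + noise`, where `M` is
a random orthonormal channels × features mixing (orthonormal so injected
signal energy is comparable across seeds), `profile(t)` an alpha function
`(t/τ)·exp(1 − t/τ)` that is zero before stimulus onset and peaks (value 1)
at `peak_ms` (default 100 ms, a stylized early evoked response), and the
noise iid Gaussian per trial/channel/time. The default grid is −100…1000 ms
at 100 Hz (111 samples) and 306 channels, mirroring a typical
whole-head MEG epoch. An optional channel-covariance mode draws a random
SPD covariance to exercise noise normalization. `simulate_staged_epochs`
sums several pattern/profile stages through one shared mixing, planting
distinct geometries at distinct latencies for fusion-latency recovery.

**Betas.** Run-wise patterns are a voxel mixing of the category patterns
plus iid run noise. The mixing depends only on the seed (one "brain"),
while run noise additionally depends on the depiction, so beta sets
simulated for two depictions with the same seed share a voxel mapping and
can be cross-decoded meaningfully. Grid mode plants the signal in a
compact spherical blob inside a null grid for searchlight recovery.

**BOLD.** `design(hrf_index) · β + noise` per voxel, with per-voxel HRF
indices allowed, supporting exact recovery tests of the HRF-selection GLM.

**Gaze.** Fixation noise plus planted saccades with minimum-jerk
displacement profiles; duration scales with amplitude (a stylized main
sequence: 20 ms + 8 ms/deg), so peak velocity comfortably exceeds
velocity-threshold detection criteria at realistic fixation noise
(~0.02° SD).

**What the generator does not model:** MEG forward physics (leadfields),
1/f sensor noise, BOLD autocorrelation, eye-blink artifacts, or any
stimulus-level confounds. Passing tests therefore establish the
correctness and calibration of the *analysis code* under its stated
assumptions — not that real recordings satisfy those assumptions.

## Decoding

**Noise normalization** whitens channels by `Σ^(−1/2)`, where `Σ` is a
shrinkage-regularized (Ledoit–Wolf by default) covariance of epoch
residuals (epochs minus their condition-cell mean), pooled over trials and
time points. It is a preprocessing step applied once to the whole epoch
set before supertrial averaging and decoding — the order in which such
normalization is conventionally applied in MEG pipelines. A fixed
shrinkage weight can be supplied instead; with shrinkage disabled, a
singular covariance raises with guidance rather than producing NaNs.

**Supertrials** average `group_size = 2` same-category trials; within one
assignment repetition every trial is used exactly once, and assignments
are re-randomized across `n_repetitions = 5` repetitions (24 trials →
12 supertrials per category).

**Time-resolved pairwise decoding** evaluates, per time point and per
unordered category pair, a linear SVM (`SVC(kernel="linear", C=1)`) in a
leave-one-supertrial-out scheme: fold *f* holds out supertrial *f* of each
class and trains on the rest. Accuracies are averaged over folds, pairs,
and repetitions. `C = 1` with no hyperparameter search keeps results
seed-stable; a property test asserts robustness of the result to `C`.
Folds whose fit fails are skipped with a warning, never imputed as chance.

**ROI decoding** uses leave-one-run-out folds on run-wise beta patterns
(train on all runs but one, test on the held-out run), averaged over
condition pairs and folds. **Searchlight decoding** applies the same logic
to the betas of all in-mask voxels within Euclidean distance
`radius_voxels = 4` (voxel units, center included — 257 voxels for a full
sphere); the accuracy map is smoothed afterwards with a Gaussian kernel
(FWHM 5 mm at 2.5 mm voxels, truncated at 4 SD), normalized inside the
mask so edge voxels are not biased downward. Centers with fewer than two
in-sphere voxels are skipped and logged.

**Cross-decoding** mirrors the within-type fold structure (train on A
minus fold *f*, test on B's fold *f*) and averages the two train/test
directions, making the operation symmetric in its arguments by
construction; with identical inputs it reproduces within-decoding exactly.

**Temporal generalization** reuses the per-train-time fits to predict all
test time points, so its diagonal is identical (same folds, same fits) to
the time-resolved decoding.

## RDMs and fusion

RDM entries are `1 − Pearson r` between condition patterns (range [0, 2]);
trial- or run-wise patterns are averaged per condition *before* the
distance computation. Zero-variance patterns raise an error naming the
condition rather than emitting NaNs. The lower triangle is extracted in
row-major (i > j) order — fixed and documented because fusion depends only
on consistency. RDM-to-RDM comparison is Pearson on the lower triangles
(Spearman available behind a flag). Fusion correlates each MEG time
point's RDM with a region's fMRI RDM, per subject; group averaging and
inference are the statistics module's job. No cross-validated distances
and no commonality/regression variants are implemented — plain bivariate
1 − r fusion only.

## Statistics

**Sign-permutation tests** flip the sign of per-subject effects (which
must be pre-centered on the null: accuracy − 50, correlation − 0). When
`2^n_subjects ≤ n_perm` all sign patterns are enumerated, making the test
exact; otherwise random flips are drawn with the identity always included,
so the smallest attainable p is `1/n_perm`. Default `n_perm = 10000`;
decoding against chance is one-sided, differences and correlations
two-sided.

**Cluster correction** thresholds pointwise permutation p-values at
`forming_p = 0.001`, clusters suprathreshold points by adjacency
(consecutive samples in time; 4-connectivity for time × time matrices, so
diagonal contact does not merge clusters; 26-connectivity for volumes),
and compares observed cluster sizes against the permutation null of the
maximum cluster size (cluster statistic = size/count, not mass). With
`cross_test_max`, the per-permutation maximum is taken across all supplied
tests (same subjects, shared sign flips) before thresholding — a joint
correction whose threshold dominates each single-test threshold.

**Bootstrap peak latencies** resample participants with replacement
(default 100000 samples), average, and take the latency of the maximum of
each bootstrap average; the CI is mean ± 1.96 SD of that distribution.
Peak detection can be restricted to a window; ties take the first
(earliest) maximum — documented because latency comparisons depend on the
tie rule. Peak differences use the same participant resamples for both
conditions (paired bootstrap), making CIs antisymmetric under argument
exchange at a shared seed.

**TOST equivalence** computes `p = max` of the two one-sided tests that
the mean latency difference exceeds −bound and falls below +bound.
Equivalence bounds are mandatory caller input and are never defaulted.
With subject-level samples the tests are t-tests (SE = SD/√n); with
bootstrap samples the spread of the difference distribution is itself the
standard error and z-tests are used.

**FDR** is the Benjamini–Hochberg step-up procedure (via statsmodels).

## GLM

The HRF library contains 20 peak-normalized double-gamma kernels spanning
peak times 4–8 s crossed with two undershoot depths (0.1, 0.35) — a
parameterized family that keeps the repository self-contained, with
`HRFLibrary.from_array` as a loader hook for externally supplied kernels.
Designs convolve condition boxcars (onset, duration) with a kernel and
sample at scan times; construction is linear in events. The GLM is
ordinary least squares fit once per kernel (task regressors + nuisance +
intercept; rank-deficient designs raise naming the collinear columns), and
each voxel's betas are taken from the kernel minimizing that voxel's mean
squared residual.

Outlier volumes are flagged when the framewise mean absolute intensity
difference exceeds 30× the run-wide mean of differences (computed per
volume over slice-aggregated differences) or when frame-to-frame
displacement exceeds 0.5 mm on any motion axis; flagged volumes are
linearly interpolated between the nearest clean neighbors (edges take the
nearest clean volume, logged). Note the 30× criterion is only meaningful
for realistic run lengths: in very short series a single spike inflates
the run-wide mean enough that the scaled ratio cannot reach 30.
Nuisance components are the top principal components of standardized
noise-voxel series (orthonormal, aCompCor style); tissue-map estimation is
out of scope — the noise-voxel set is a direct input.

## Eye movements

Detection follows the velocity-threshold approach: a 5-sample
moving-window differentiator, per-axis median-based SD estimates
(`√(median(v²) − median(v)²)`), an elliptic threshold at λ = 6 SDs, and a
minimum duration of 3 samples. λ and the duration are exposed because the
underlying algorithm's parameters are conventions, not constants.
Monocular traces are assumed. Saccade amplitude is the onset-to-offset
displacement, which makes detection invariant to constant position
offsets. Slow drifts can be removed with a first-order 0.1 Hz zero-phase
high-pass. QC rules: epochs containing any movement >3° are dropped
(such movements cannot have landed on the stimulus); remaining trials are
flagged on-stimulus if any saccade exceeds 1.5°; subjects are excluded
when strictly more than 5% of experimental (non-catch) trials are
flagged.

## Calibration and problem sizes used in the test suite

The test suite verifies statistical calibration at sizes chosen for tight
Monte-Carlo precision:

- *Chance level*: label-permuted epochs decoded with **one** assignment
  repetition — repetitions reuse the same trials and only inflate the
  count of correlated decisions, so a single repetition keeps the decision
  count as close to the independent-Bernoulli model of the binomial band
  as the leave-one-out scheme allows. The simulation noise is set so that
  intact (unpermuted) within-decoding peaks near 60–70%, a realistic
  single-trial SNR regime for this kind of data. The same SNR is used by
  `scripts/acceptance.py`.
- *Type-I error*: 10⁴ null datasets of 12 subjects, exhaustive (2¹²)
  enumeration, α = 0.001.
- *Cluster FWER*: 500 null datasets of 10 subjects × 50 time points,
  exhaustive (2¹⁰) sign enumeration at forming p < 0.001, α = 0.05. At
  this forming threshold the critical max-cluster size is 1 and the
  attainable level, 1 − (1 − 1/2¹⁰)⁵⁰ ≈ 0.048, sits at the nominal rate;
  cluster-size statistics are discrete, so arbitrary forming thresholds
  can make the attainable level land well below α.
- *Bootstrap coverage*: 200 simulations of 12 subjects with a 100 ms peak
  jittered ±15 ms, 300 bootstrap samples each.

## Known limitations

- The linear-SVM leave-one-out scheme exhibits the well-known
  correlated-decision variance inflation (and, at small sample-to-
  dimension ratios, a small chance bias); the binomial band is therefore
  an approximation whose quality the calibration suite checks empirically.
- Cluster-size inference is conservative under discreteness of the
  max-size null; it controls FWER but does not always attain α.
- The searchlight is exact but not optimized (no incremental sphere
  updates); large grids are computationally expensive.
- The GLM assumes white residuals (no AR modeling) and the HRF family,
  while spanning realistic peak times, is not the empirical library a
  production pipeline would load through the `from_array` hook.
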