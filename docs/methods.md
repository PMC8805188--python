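# Methods

This note documents the models, estimators and numerical choices behind
`rhi_mvpa`, and what the synthetic-data validation does and does not show.

## Analysis model

### Epoch model and preprocessing

An epoch is the closed interval [−0.4, 0.4] s around one stimulation event
(161 samples at 200 Hz; both endpoints included — the sample-count
convention is ours, only the window bounds are fixed by the design).
Epochs are band-pass filtered 1–40 Hz with a two-pass third-order
Butterworth filter applied per epoch and channel; the forward–backward pass
squares the magnitude response and cancels phase. Filtering is done in
transfer-function form, which at order 3 is numerically safe and faster
than second-order sections on many short signals. Artifact rejection
removes any epoch whose absolute amplitude exceeds 165 μV on any EEG
channel, evaluated *after* the band-pass and only on EEG channels (EOG and
other auxiliary channels are excluded); the order of operations is our
choice, flagged for sensitivity testing, since only the threshold itself is
part of the design.

Raw-stage conditioning of continuous recordings (wide-band filtering,
resampling from acquisition rate, ICA-based artifact removal) is treated as
already done; ICA component selection is inherently manual and is not
reimplemented. The synthetic data contain no ocular or muscular artifacts,
so nothing in the validation depends on this.

Epoch selection implements the logic that the illusory state exists only
after the participant's button press: Illusion-condition epochs are kept
iff their event time strictly exceeds the trial's onset; Incongruent and
Real conditions, which have no press, are cut at the participant's *median*
Illusion onset. The strict inequality puts an event exactly at the press
into the pre-onset set. The pre/post split of Illusion trials partitions
epochs by the same rule.

### Decoding

Each epoch is summarized in overlapping bins of 60 ms stepped by 10 ms.
A bin is the closed 13-sample interval centered on a sample, so the bin
labeled c covers exactly [c − 0.03, c + 0.03] s; the per-bin feature is the
per-channel mean amplitude (feature dimension = channel count). Averaging
within the bin rather than concatenating samples keeps the covariance
estimable with few observations at 128 channels and emphasizes the
low-frequency evoked component; it is exposed as a config choice.

Observations are pseudo-trials: disjoint random groups of 4 same-condition
epochs, averaged; leftovers smaller than a group are discarded, and the
grouping is redrawn on every resampling repeat. The classifier is a
shrinkage LDA with λ = 0.1 (pooled within-class covariance, denominator
n − 2, shrunk toward tr(Σ)/d · I; weights by direct linear solve — a
singular covariance with λ = 0 raises rather than pseudo-inverting).
Performance is the ROC area computed from ranks (Mann–Whitney form, ties at
half credit), with the decision values of all six stratified test folds
pooled into a single AUC per bin and repeat — pooling stabilizes the AUC
when test folds are small. Both conditions are subsampled without
replacement to ⌊0.8 · min(nA, nB)⌋ epochs per repeat (the literal reading
of equalizing to 80 % of the smaller count) and results averaged over 50
repeats. Whether subsampling is with or without replacement was an open
choice; without replacement avoids duplicate epochs inside a pseudo-trial.

The forward model of a fitted classifier is the Pearson correlation,
across training observations, between the discriminant component Xw and
each channel; zero-variance channels map to 0 with a warning. Forward
models are averaged over folds and repeats. For performance the per-bin
fits and forward models run through exactly vectorized batch versions of
the reference implementations (unit tests pin their equality to machine
precision).

Cross-classification trains one LDA per bin on all pseudo-trials of one
contrast and computes the test AUC on another contrast. A condition
appearing on both sides (the Illusion epochs in (Illusion vs Incongruent) →
(Illusion vs Real), or the illusory-state epochs in the within-trial
cross) is split 50/50 at the epoch level, disjointly between train and
test, fresh per repeat; both directions are run and averaged. Classes are
equalized to the smaller count; the pipeline passes the *same* dataset
object for a shared condition so the split is enforced structurally.

### Group inference

The group-level null is chance decoding. Per-participant effects are
AUC − 0.5 per bin; each of 5000 randomizations flips the sign of whole
participant time courses (preserving temporal autocorrelation under the
null). The cluster-forming threshold is the 99th percentile of all
randomized group means pooled over bins and randomizations — a one-sided
criterion, so only above-chance decoding can form clusters. Candidate
clusters are runs of ≥ 3 consecutive supra-threshold bins (adjacency is
temporal; the time course has no other dimension), their statistic the
summed chance-corrected group-mean AUC. Family-wise valid p-values come
from the distribution of each randomization's maximum cluster statistic,
with the add-one convention p = (1 + exceedances)/(1 + N) that guarantees
p > 0. Exactness is verified against full 2ⁿ enumeration at n = 10.

The between-participant correlation test computes, per bin, the Pearson r
between participants' AUC and a covariate (here the Illusion − Incongruent
skin-response difference). The first-level threshold is the parametric
two-sided p < 0.01 critical r at n − 2 degrees of freedom; clusters of
either sign are formed, the null shuffles the covariate's participant
assignment, and the max-|cluster statistic| distribution gives p-values.

Wilcoxon signed-rank tests drop zero differences, use exact enumeration of
all sign assignments for n ≤ 12 (two-sided p as twice the smaller tail,
capped at 1) and the normal approximation with tie-corrected variance and
continuity correction above; the reported Z is the signed normal
statistic. The rank-biserial effect size is (W₊ − W₋)/(W₊ + W₋).
Benjamini–Hochberg correction delegates to statsmodels and is checked
against a brute-force step-up oracle.

## Synthetic data generator

The generator emulates the design: five conditions (two Illusion
arrangements, two Incongruent controls, one Real-hand control) × 4 trials
× 180 events at 1 Hz; 128-channel EEG at 200 Hz; 100-Hz skin conductance.
Reduced sizes are used throughout the tests (typically 32 channels, 2
trials of 60 events, 12 participants) so the full pipeline runs end-to-end
on one CPU; all sizes are config fields.

* **Background EEG noise** — Gaussian, AR(1) along time (coefficient 0.95
  at 200 Hz, matching the 1/f-like concentration of EEG power at low
  frequencies) and spatially correlated through a row-normalized random
  mixing matrix I + 0.5·G/√d (equal channel variances, correlated
  channels); per-channel SD 10 μV.
* **Evoked response** — identical in every condition: two raised-cosine
  components (peak ~100 ms, width 100 ms, 4 μV; peak ~250 ms, width
  140 ms, 2.4 μV) with one random unit-norm topography per participant.
  Because it is condition-invariant it cancels in every contrast.
* **Condition effects** — an `EffectSpec` adds pattern × amplitude ×
  raised-cosine bump inside its window to the first condition of its
  contrast ("Illusion"/"Incongruent" expand to both hand positions).
  Patterns are unit-norm channel vectors: shared across participants,
  participant-specific, or constructed orthogonal to another spec's
  pattern (the device behind the cross-classification dissociation tests).
  In Illusion trials the effect is only added to events after the trial's
  illusion onset — the illusory state, not the condition label, carries
  the effect, which is what makes onset-based epoch selection and the
  pre/post contrast meaningful.
* **Onset latencies** — log-normal with configurable per-condition medians
  (defaults 42 s hand-next, 30 s hand-under) and log-SD σ = 0.55, clipped
  to [5 s, duration − 10 s]. Only medians and means are constrained by the
  design; the distributional form and per-trial spread are free choices
  (σ anchored to the reported mean/median ratios of ≈1.2).
* **Skin conductance** — 0.5–2 Hz band-limited Gaussian noise (SD
  0.05 μS on a 2 μS baseline) whose amplitude is multiplied by a
  per-condition factor inside a window relative to the (surrogate) onset.
  A multiplier of 1 gives a stationary trace whose SD ratio is ≈ 1 in
  expectation (slightly above, by the Jensen bias of a ratio at few
  effective degrees of freedom — the same bias real 3-s windows have).

What the generator does **not** emulate: volume-conduction-realistic
topographies, non-Gaussian or nonstationary noise, ocular/muscular
artifacts, drifting electrode impedances, or any coupling between EEG and
skin-conductance noise. Passing tests therefore demonstrate correctness of
the estimators and validity of the inference under a plausible
second-order-stationary model, not robustness to every pathology of real
recordings.

## Validation operating points

Chosen once, at the generator's study conditions:

* Type-I error: 200 zero-amplitude studies (12 participants, 32 channels,
  1000 randomizations, 2 decoding repeats) must keep the family-wise rate
  within 0.05 + 2 binomial SE.
* Effect recovery: amplitude 5.5 μV in [0.08, 0.30] s yields a true
  per-participant peak AUC ≈ 0.65 at these sizes (calibrated against the
  group-mean peak, which is unbiased — the per-participant *maximum* over
  bins overstates SNR through max-statistics noise bias); the detected
  cluster must overlap the window and the max-AUC bin must fall inside it
  (± half a bin) in ≥ 90 % of 50 studies.
* Forward-model recovery: amplitude 20 μV, 4 trials/condition, 5 repeats —
  mean |corr(topography, injected pattern)| ≥ 0.9. The ceiling is set by
  sampling noise of a correlation estimated from tens of pseudo-trials,
  not by bias; at lower SNR the estimator stays unbiased but noisier.
* Cross-classification: amplitude 8 μV; a pattern shared between the two
  hand-position contrasts must yield a significant cross-decoding cluster,
  orthogonal patterns must stay in the chance band with ≤ 1/20 null runs
  producing any cluster.
* SCR: a 2× SD step is recovered as a mean ratio within 10 % of 2 over
  ≥ 100 trials *through the full preprocessing* (the filter smears the
  step over ≈ 0.3 s of the 3-s windows, a bias well inside that band);
  an Illusion-only pre-onset multiplier of 1.5 at n = 20 must be detected
  by the BH-corrected Wilcoxon contrast in ≥ 80 % of studies.

## Numerical and degenerate-input choices

* Permutation p-values are never 0 (add-one convention); thresholds use
  `np.percentile` on the pooled randomized values.
* `fit_lda` raises on a singular covariance at λ = 0 instead of silently
  pseudo-inverting; batched solves raise identically.
* Bin width/step are snapped to the sample grid with a warning.
* Events whose epoch window leaves the recording are dropped with a logged
  warning; onset selection that removes every epoch warns and returns an
  empty set, which downstream stages reject explicitly.
* AUC tie handling is midrank (half credit), identical in the scalar and
  row-vectorized implementations.
* All randomness flows from explicit seeds; the pipeline's master seed
  spawns per-stage seeds via `numpy.random.SeedSequence`, so partial
  re-runs are reproducible.

## Known limitations

* The SD-ratio skin response is a deliberately simple statistic; it does
  not separate phasic from tonic electrodermal activity and inherits the
  ratio's small-sample bias (which cancels in condition contrasts).
* Cluster inference is one-dimensional along time; no channel-space
  clustering, TFCE or temporal-generalization matrices.
* The within-trial (pre vs post onset) contrast confounds the illusory
  state with time-in-trial in real data; the generator does not model
  slow adaptation, so this confound is not probed.
* BDF support writes fixed ±32768 μV physical range, 1-s records, and
  truncates to whole records.
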