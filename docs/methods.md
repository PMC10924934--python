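# Methods

## The task and its normative model

On every trial of the two-card game a player guesses whether the second of
two cards drawn without replacement from a ten-card deck (ace = 1) will be
higher or lower than the first, then sees card 1, sees card 2, and reports
whether they won. Correct guesses are worth ±10 points, correct reports ±5.
Because the deck is reshuffled between trials, each trial is an independent
draw and every latent quantity is an exact expectation over the deck:

* P₀ = P(win | guess) = 1/2 before card 1 (constant, excluded from decoding);
* EV = P(win | guess, card 1); for a "lower" guess EV = (c₁ − 1)/9;
* E.Risk_card1 = Var(EV) over the ten first cards = 11/108 (constant);
* RiPE_card1 = (EV − P₀)² − E.Risk_card1;
* E.Risk_card2 = Var(outcome | guess, card 1) = EV(1 − EV);
* RePE = outcome − EV;
* O.Risk = RePE² (observed risk);
* RiPE_card2 = O.Risk − E.Risk_card2.

`task_model` implements both closed forms and literal deck enumerations
(`enumerate_*`); the test suite requires them to agree to 1e-12 on all 20
(guess, card 1) states. Points never enter the model variables: the outcome
in RePE is the 0/1 win indicator.

Because RiPE_card1 is an affine function of its own observed risk
(P₀ and E.Risk_card1 are constants), orthogonalizing it against
(EV − P₀)² annihilates it exactly; the card-1 risk error therefore never
appears as a decodable quantity, and "RiPE" downstream always means
RiPE_card2.

## Synthetic cohorts

`synthetic_data` generates the entire study scaffold: 10 subjects, 1–2
sessions of 90 trials (16 sessions, 1440 trials by default), per-subject
electrode layouts with ROI labels, template-convention coordinates and a
gray/white tissue flag, and continuous 2 kHz raw signals. Behavior is i.i.d.
by construction — guesses carry no outcome dependence or stickiness, and the
report matches the truth with probability 0.915 (the default mirrors the
observed report accuracy the task is designed to elicit).

The raw signal model is deliberately simple, since it only needs to carry
the statistical structure the analysis chain consumes:

* per-contact AR(1) noise (φ = 0.95, unit variance) with Laplace
  innovations — a crude stand-in for the 1/f-like spectrum and transient,
  heavy-tailed character of field potentials. The non-Gaussianity is load-
  bearing: it makes the ICA denoising stage well-posed. With iid Gaussian
  channels the component basis is rotation-ambiguous, so arbitrary
  near-uniform directions get removed and their sources — which carry
  projections of every strong planted code — smear those codes across
  contacts, measurably coupling sites that were planted independently;
* a small number of shared components loading near-uniformly (±8%) on all
  contacts, emulating distal/reference noise — exactly the shape the
  KL-uniformity ICA criterion targets;
* 60 Hz line noise;
* event-locked encodings: a raised-cosine bump (default width 120 ms) at a
  configurable latency after a chosen trial event, scaled by the z-scored
  model variable and projected onto a spatial pattern across the ROI's
  contacts. Patterns are differential (per-contact coefficients of mixed
  sign, |w| ≥ 0.5) so bipolar referencing preserves rather than cancels
  them, and are drawn once per (encoding, subject) so sessions of one
  subject share their code. `pattern_group` lets two encodings share one
  pattern (a genuinely shared neural code); `disjoint_group` allocates
  contiguous, gap-separated contact blocks so no bipolar pair straddles two
  independent codes.

Amplitudes are in signal-s.d. per variable-s.d.; the default of 1.5 makes a
single well-loaded contact's event-window mean correlate with the encoded
variable at r > 0.5 — a strong but not saturated code at 60–90 trials.
Because RePE = OUT − EV and RiPE = O.Risk − E.Risk are intrinsically
correlated with their observed companions, the generator also exposes
`RePE_unique` and `RiPE_unique` (the residuals after orthogonalization),
used when a simulation requires codes that are independent *in substance*
and not merely planted on different contacts.

What the generator does **not** emulate: biophysical forward mixing,
interictal artifacts, nonstationarity across a session, cross-frequency
structure, or realistic 1/f exponents. Passing recovery tests therefore
demonstrate the correctness and calibration of the analysis chain, not its
performance on real recordings.

## Preprocessing

Order of operations per session: downsample 2 kHz → 500 Hz (polyphase,
anti-aliased) → 60 Hz FIR notch (801 taps, zero-phase) → 1 Hz Butterworth
high-pass (zero-phase) → ICA denoising → 250 Hz low-pass → bipolar
re-referencing → epoching. Downsampling precedes the notch for cost; 60 Hz
is far below the new Nyquist so nothing is lost.

ICA denoising runs twice: once globally over all of a subject's contacts
(D_kl threshold 0.2 nats) and once per electrode (0.05 nats). For each
component the absolute mixing weights over the K channels are normalized to
a distribution w and compared with uniform via D(w‖1/K) = Σ wᵢ log(K wᵢ);
D = 0 for exactly uniform loading and ln K for one-hot. Components *below*
threshold — near-uniform loading, the signature of distal noise or volume
conduction — are removed by subtracting their rank-one contribution. The
decomposition is scikit-learn FastICA, seeded, with the unmixing matrix
estimated on an evenly strided temporal subsample (≤ 40k samples) and then
applied to the full series. Thresholds are config-exposed: their meaning
depends on K, and the defaults are the ones appropriate for channel counts
in the tens.

Two honest limitations of this stage. First, ICA requires non-Gaussian
sources; on stretches of effectively Gaussian noise the component basis is
an arbitrary rotation, so near-uniform directions can be removed even
without a physical shared source — harmless (it is label-independent noise
surgery) but worth knowing. Second, when one strong uniform source coexists
with K focal sources the problem is overcomplete (K+1 sources in K
channels) and the estimated shared source carries a few percent
contamination from some focal source; its removal can dent that one
channel's variance noticeably even though aggregate focal variance is
preserved. Event-locked codes survive this comfortably (the recovery suite
is the end-to-end check).

Bipolar referencing differences adjacent contacts of each electrode; pairs
with *both* contacts in white matter are dropped; coordinates are
interpolated at pair midpoints. Epochs span −200..+500 ms around each of
the five trial events (guess response, card 1 on, card 1 off, card 2 on,
report response) on the 2 ms grid; the mean over [−200, 0) ms is
subtracted per epoch and channel. The decoding axis is 0..500 ms inclusive
— 251 timepoints — with the pre-event interval reserved for baseline.

## Feature preparation

Per subject and session, every contact × timepoint series is residualized
across epochs against a confound design containing: an intercept (removing
subject-mean activity — the step that makes cross-subject pooling sane),
indicator columns for card-1 onset, card-1 offset and card-2 onset,
mean-centered parametric regressors for every model variable *except* the
decode target, each aligned to its event (EV @ card-1 on; E.Risk @ card-1
off; OUT, RePE, RiPE, O.Risk @ card-2 on), and per-trial report accuracy
@ report. Two orthogonalization steps precede the design: RePE ⊥ OUT and
RiPE ⊥ O.Risk, so a variable's decodable variance is the part not
explained by its observed companion; O.Risk itself stays in the design when
RiPE is decoded. The same time-invariant design is applied at every
timepoint — the only choice consistent with per-timepoint decoding.
Residualization happens per session, before any cross-subject pooling. The
design can exclude *two* variables at once, which cross-variable
generalization requires (neither the train nor the test variable may be
regressed out of the shared feature space).

Decode targets are binarized around their mean into ±1 (exact zeros are
dropped); for RePE and RiPE the orthogonalized values are binarized, so the
labels describe the same unique variance the features retain.

The pseudo-population treats contacts pooled across subjects as one
population recorded simultaneously: each subject's trials are split into
stratified CV folds first, then fold-wise blocks are concatenated across
subjects, producing a block-structured matrix whose off-block entries are
exactly zero ("at the mean" for subjects that do not own the row). The
matrices are stored dense — at these sizes explicit zeros are cheaper than
sparse bookkeeping. Per (column, timepoint), normalization statistics are
computed on the owning subject's *training* rows only and applied to train
and test alike; zero-variance features scale to 0 with a warning.
Decoding rows are restricted to the variable's a-priori event (EV: card-1
on; E.Risk: card-1 off; OUT/RePE/RiPE: card-2 on).

## Decoding and inference

At every timepoint independently, an L2-regularized logistic regression
(inverse strength C = 1.0, unpenalized intercept, no hyperparameter search)
is fit on the pooled train rows and scored with ROC AUC on the held-out
rows; the decoding curve is the mean over 10 folds. The solver is a damped
Newton minimizer of the penalized logistic loss, vectorized over an
arbitrary batch of label vectors sharing one feature matrix; it matches
scikit-learn's coefficients to ~1e-7 at tight tolerance (asserted in
tests) and exists because permutation inference refits the same model under
hundreds of label shuffles per (fold, timepoint). AUC is computed from
midranks (Mann-Whitney form), batched the same way, and is invariant to
any strictly increasing transform of the decision scores.

Cluster inference: labels are permuted within subject (trials cannot move
across subjects), the whole decoding analysis is re-run per permutation
(1000 by default; 200 in the test profile), permuted curves are
thresholded at the per-timepoint 95th percentile θ_t, and each permutation
contributes its largest suprathreshold cluster mass (0 if none) to the
max-cluster null. An observed cluster — a maximal contiguous run with
AUC_t > θ_t — has mass Σ(AUC_t − θ_t), is significant at FWE < 0.05 iff
its mass exceeds the null's 95th percentile (C_thresh), and is reported
with p = 1 − (percentile rank of its mass in the null)/100. Mass as summed
*excess* is the reading consistent with printed cluster statistics of
order 1 over ~100 ms spans at AUCs a few points above threshold; summed
raw AUC is available behind `mass="sum_auc"`. Uncertainty on the curve
comes from resampling each fold's test rows with replacement (500
replicates), recomputing AUC, averaging across folds and taking 2.5/97.5
percentiles.

Cluster timing comparisons use the Mann-Whitney U between two clusters'
timepoint sets, with U counted for the later cluster (greater mean
latency) over the earlier, so complete separation gives U = n₁·n₂. The
p-value uses the two-sided normal approximation with continuity and tie
correction. FDR across ROIs is Benjamini-Hochberg with the family size
fixed at the full ROI set (11), so untested members still count toward the
correction.

Temporal/cross-variable generalization fits the classifier at each train
timepoint and applies it, without refitting or re-scaling, at every test
timepoint against the test variable's labels, within a 200–500 ms window by
default (config-switchable to the full epoch). The fold split and
normalization are those of the train variable; test labels are obtained by
relabeling the identical rows. The 2D permutation null applies one
within-subject row permutation jointly to both label vectors, preserving
their mutual dependence; suprathreshold cells (per-cell 95th/99th
percentile) are grouped by 4-connectivity and tested against the 2D
max-cluster null at FWE < 0.05.

Feature importance is leave-one-feature-out: the drop in mean CV AUC when
one contact's column is removed and the model refit. To compare two
variables' maps, each map is z-scored, averaged over a shared window, and
correlated across contacts (Pearson), with a two-sided p from permuting
contact assignment.

Any curve smoothing is for display only; statistics are always computed on
unsmoothed curves.

## Calibration and recovery studies

`validation.fwer_study` measures the empirical family-wise error rate: 200
signal-free datasets (4 subjects, 20 contacts, 60 trials of AR(1) noise
with real simulated-task labels), each run through fold assembly,
normalization, per-timepoint decoding and the 200-permutation cluster
procedure; the reported quantity is the fraction of datasets with any
significant cluster, to be compared with the nominal 0.05 plus two binomial
standard errors. The null datasets are generated directly at the epoch
level: the preprocessing chain is deterministic and label-independent, so
under the null it cannot alter the error rate, and synthesizing 200 raw
cohorts would add cost without information. The decoding grid uses 26
timepoints and 5 folds here — grid density and fold count do not enter the
FWER guarantee.

`validation.run_recovery_study` is the sensitivity counterpart, run on two
4-subject, 60-trial cohorts at the test profile (200 permutations, 10 ms
decoding grid). The *cascade cohort* carries each decodable variable
planted at a known (ROI, latency), including a 4-region outcome cascade at
staggered latencies (angular gyrus 30 ms → hippocampus 110 ms → amygdala
210 ms → vmPFC 250 ms). The *code-sharing cohort* carries an
anterior-insula pair sharing one spatial pattern (RePE at 250 ms, a weaker
RiPE copy at 450 ms) and an OFC pair on disjoint contact blocks (OUT, and
the OUT-orthogonalized RePE component). The code-sharing simulations live
in their own cohort because the denoising stage, however well-posed, can
only estimate shared sources imperfectly, and residual cross-contact
smearing grows with the number of strong codes in the cohort — the
(in)dependence claims should not hinge on that. Recovery means: a significant cluster overlapping the
planted kernel's support for each code; cascade peak latencies in planted
order; a significant train-early/test-late generalization cluster for the
shared pattern (and a larger early→late than late→early mass, since the
late copy is noisier); no such cluster and a near-zero feature-weight
correlation for the disjoint pair. For generalization overlap we use the
kernel's above-half-maximum window: classifiers trained where a code is
fading can pick up in-sample noise alignments that transfer weakly, an
overfitting pathway distinct from a shared code, so the claim is anchored
where the planted codes actually live.

## Numerical and design notes

* All randomness flows from explicit seeds through `numpy` Generators;
  identical configs produce byte-identical outputs.
* Rank-deficient confound designs (e.g. a session with all reports correct)
  are handled by pseudoinverse, equivalent to dropping dependent columns.
* Degenerate CV folds: a single-class train split is an error; a
  single-class test split skips the fold with a warning and the curve
  averages the rest.
* Exact-zero binarized targets are dropped from decoding rows; relabeling
  for generalization refuses targets that would change the row set.
* The epoch grid convention (timepoint t covers [t, t+2 ms), decoding axis
  0..500 ms inclusive) yields exactly 251 decoding timepoints; printed
  cluster bounds in the literature that fall on odd-millisecond grids
  cannot be represented here and are reconstructed on this grid.
* Desk-scale profiles (200 permutations, 100 bootstraps, strided decoding
  grids) change counts, never procedure; full-scale defaults are 1000/500
  on the 2 ms grid.
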