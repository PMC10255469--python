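# Methods

`vadeeg` implements an EEG emotion-recognition pipeline for software
usability testing.  A subject's multichannel EEG is band-decomposed,
event-related desynchronization/synchronization (ERD/ERS) features are
computed on adaptively selected electrodes, and three emotion dimensions —
valence, arousal, dominance (VAD) — are each decided by a pair of
one-vs-all recurrent networks fused through a fixed decision table.  A
session layer sizes a "first impression" window from a continuous
performance test (CPT) and links per-segment emotion labels to usability
factors.  This note records the model, the parameter choices, and what the
synthetic evaluation does and does not demonstrate.

## Signal model and preprocessing

Recordings are channels x samples matrices in microvolts with 10-20 system
labels.  Preprocessing applies, in order:

1. **High-pass filter** — 4th-order Butterworth, default cutoff 1 Hz,
   applied forward-backward (zero phase) so trial timing is preserved.
   The cutoff and order are configuration choices; only the presence of a
   high-pass stage is prescribed by the method.
2. **Common average reference (CAR)** — subtract the instantaneous mean
   across channels.  Drift removal happens first so channel DC offsets do
   not leak into the common average.
3. **FFT band extraction** — per segment: forward rFFT, zero every bin
   outside the band, inverse transform.  Bands default to clinical
   conventions: theta 4–8, alpha 8–13, beta 13–30, gamma 30–45 Hz.  Bins
   are retained on the half-open interval [f_lo, f_hi) so adjacent bands
   partition the spectrum; the four band outputs sum exactly to the
   4–45 Hz mask output.  Bin granularity is fs/n_samples of the segment.

Filtering is applied trial-wise (not on the continuous recording), matching
the per-fragment feature computation downstream.

## Fragmentation

Trials are augmented by overlapping windows: a trial of T seconds yields
`N = floor((T - W)/shift) + 1` fragments, `shift = (1 - O) * W`, with
window W = 12 s and overlap O = 0.5 by default.  Trailing partial windows
are discarded so fragments are equal-sized.  In samples, consecutive
fragments share exactly `round(O * W * fs)` samples.

## ERD/ERS features and adaptive channel selection

Band power of a fragment is the mean squared amplitude of its
band-limited signal (µV²); for a pure in-band sine of amplitude A this is
A²/2.  The ERD/ERS feature is the relative power change against a neutral
baseline:

    ERD/ERS = (A - R) / R

where A is the fragment's active band power and R the *reference average
power*: the mean band power over all reference (neutral) fragments of the
same subject, channel and band.  Values are dimensionless, bounded below
by -1, and scale-invariant.

Selection is per subject.  For each emotional state, band and channel, the
active fragments' powers are compared with the reference fragments' powers
by a two-sided Mann–Whitney rank-sum test; a (channel, band) pair is
selected if p < alpha (default 0.05, no multiplicity correction) for at
least one state.  The feature vector enumerates selected pairs in fixed
(band, channel) order, so its length is constant across fragments of a
subject but varies between subjects — the network input size adapts to the
subject's brain activity.

Two notes on this design:

* The rank-sum test is used rather than a signed-rank test of
  `active - mean(reference)` because the latter is miscalibrated: the
  reference mean's sampling error shifts all of a channel's tests
  coherently, inflating the null selection rate well above alpha whenever
  the reference set is not much larger than the active set.  The
  signed-rank variant remains available (`method='signed_rank'`).
* Because each pair is tested once per state with no correction, the
  selected set contains a predictable fraction of null pairs
  (≈ 1 - (1-alpha)^n_states of the null pairs).  This is intentional —
  selection feeds a classifier, where a moderate number of uninformative
  inputs is preferable to missing informative ones.

An alternative feature mode — per-band power differences between left-right
homologous electrode pairs (Fp1–Fp2, F3–F4, ...) — is provided but off by
default.

## Recurrent network and Levenberg–Marquardt training

One recurrent tanh layer (default 80 hidden units, one output):

    a_t = tanh(delay_scale * W_aa a_{t-1} + W_ax x_t + b_a)
    y_t = tanh(W_ya a_{t-1} + b_y)

The output reads the *previous* hidden state; `output_from='current'`
switches to the more common convention.  `delay_scale = 0.01` damps the
recurrence — the classifier is deliberately nearly static, because trials
(independent stimuli) carry no temporal dependence worth modelling.
Weights and biases initialize uniformly in [-0.5, +0.5].  A fragment's
feature vector is presented as the two-step sequence [x, 0], and the score
is the second output, tanh(W_ya tanh(W_ax x + b_a) + b_y).  Eighty stacked
recurrent layers would not be trainable by full-batch LM at this scale; a
single wide layer is the reading adopted, with the stack depth left as a
possible extension.

Training is full-batch damped least squares on the cost
X² = Σ((y_i - ŷ_i)/σ_i)², σ_i = 1 by default.  Each step solves

    (Jᵀ W J + λ I) h = Jᵀ W (y - ŷ)

and accepts p + h iff the cost strictly decreases (λ /= 10), otherwise
rejects and retries with λ *= 10.  Defaults: λ₀ = 3, adapt factor 10,
8 epochs (one fresh Jacobian per epoch, up to 12 damping retries each),
stopping tolerance 1e-10.  The Jacobian is exact, computed by real-time
recurrent learning: hidden-state sensitivities are propagated forward in
time block-wise per parameter matrix, and blocks whose sensitivity is
structurally zero (e.g. W_aa when only the first hidden state is ever
read) are skipped.  When observations are fewer than active parameters the
step is obtained in observation space through the push-through identity
`(JᵀJ + λI)⁻¹Jᵀr = Jᵀ(JJᵀ + λI)⁻¹r` — algebraically exact and much
cheaper for wide networks.

Numerical/termination choices: parameters are flattened in fixed order
(W_ax, W_aa, W_ya, b_a, b_y); a zero update vector leaves the state
untouched; an epoch in which no damping level yields strict improvement
terminates training normally with the best-so-far parameters (at a local
optimum no strictly improving step exists, so unbounded λ growth is a
normal stopping condition, not a failure); only a non-finite cost raises
`ConvergenceError`, which carries the step history.  Accepted-step costs
are monotone non-increasing by construction.

## Classification and fusion

Per dimension, two one-vs-all classifiers: the upper-level one targets
positive valence / active arousal / **low** dominance, the lower-level one
negative valence / passive arousal / high dominance.  (The inverted
dominance semantics are preserved from the source scheme on purpose;
flagging rather than "fixing" keeps decisions auditable.)  Training labels
are +1 for fragments whose true level matches the classifier's level and
-1 for everything else, including neutral fragments.  A fragment is
`target` iff the raw tanh output strictly exceeds the threshold (default
0; ties are conservative, falling to `outlier`).

The fused outcome per dimension:

| upper clf | lower clf | outcome |
|-----------|-----------|---------|
| target    | target    | error   |
| target    | outlier   | upper   |
| outlier   | target    | lower   |
| outlier   | outlier   | neutral |

Evaluation reports one-vs-rest accuracy/precision/recall/specificity/F1
per (dimension, level) — on both the fused decision and the raw stage-1
labels, since either convention is defensible — a per-dimension decision
accuracy (fraction of fragments whose outcome equals the true level;
`error` outcomes count against it but are never credited), and a 3x3
confusion matrix over {upper, neutral, lower} with errors in a separate
column, rows normalized to percentages.

## Synthetic subjects

Each trial is, per channel, one band-limited oscillation per band
(frequency uniform in the band, fresh phase per trial and channel — 
independent draws per channel prevent cancellation under CAR) plus white
Gaussian noise (1 µV), with optional 1/f background (off by default, so
power oracles stay exact).  Oscillation amplitudes are EEG-like: theta 8,
alpha 10, beta 6, gamma 4 µV.  Amplitudes carry log-normal trial-to-trial
jitter (sigma = 0.1, normalized so the expected squared gain is 1), giving
~20% band-power variability — the realistic low end for within-subject
EEG.  Without it, any systematic imperfection of the pipeline (CAR
mixing, spectral edge effects) is "statistically significant" at any
alpha, which no real recording exhibits.

Emotional states modulate power through an effect map: for a designated
(state, band, channel), the oscillation amplitude is scaled by
sqrt(1 + e), so the expected band-power ratio against the unscaled neutral
reference is exactly 1 + e and the ground-truth ERD/ERS is analytic.  The
default map assigns each (dimension, level) two homologous electrodes in
one band (e.g. valence-upper: F3/F4 alpha; arousal-upper: C3/C4 beta); a
corner state carries the union of its three levels' signatures — 12
designated pairs in total, 8 when restricted to two dimensions.

Generation is deterministic: every trial draws from a substream keyed by
(seed, trial counter), so subjects are bit-reproducible and trials could
be generated in any order.

What the synthetic data does *not* emulate: volume conduction and
inter-channel correlation, non-stationarity within trials, eye/muscle
artifacts, realistic 1/f-dominated spectra (unless enabled), and
inter-subject variability of effect topography.  Passing the synthetic
benchmark therefore demonstrates that the pipeline recovers planted
band-power structure through its own preprocessing, selection, feature and
training stages — not that comparable accuracy would be obtained on real
recordings.

## Benchmark study design

The packaged benchmark (`run_synthetic_benchmark`) uses one subject with
80 trials per corner state plus 96 neutral reference trials, 12-second
trials at 128 Hz on the 32-electrode montage, planted ratio 0.6, a 25%
per-state trial-level hold-out (fragments of one trial never straddle the
split), selection at alpha 0.05, and the default network/training
configuration.  Twelve-second trials make each trial a single fragment, so
the selection tests operate on independent samples; the trial counts give
the one-vs-all networks enough data that the 80-unit models generalize
(with ~a third as many trials they interpolate the training set and lose
3–5 accuracy points).  On this design, held-out per-dimension decision
accuracy is typically 90–96% and mean accuracy increases monotonically
with the planted ratio (≈40% at e=0.1, ≈72% at e=0.3, ≈93% at e=0.6 for
seed 1).

The teacher–student check trains a fresh 2-input/3-hidden student on the
final-timestep outputs of a random teacher of the same architecture over
30 six-step input sequences uniform in [-1, 1]; full-batch LM reaches
X² < 1e-4 within the 8-epoch budget.  Final-timestep targets keep the fit
near-interpolating (30 observations, 22 parameters); observing every
timestep creates long, ill-conditioned valleys that LM crawls through.

## Usability session layer

The CPT response time is the mean, over non-X stimuli, of the first
keypress latency before the next stimulus; omissions are excluded and
presses following an 'X' (commission errors) never enter the mean — their
effect on the estimate is an open question in the source scheme, and
exclusion is the conservative choice.  That mean sizes the
first-impression window.  In discrete mode every task window is split into
a first-impression segment plus remainder; in continuous mode a single
first-impression segment opens the first task.  The linking report maps
segment labels to usability factors: first-impression label, per-task
modal outcome per dimension (ties resolve to neutral), overall valence
proportions, and a satisfaction indicator (fraction of non-error segments
with upper valence; undefined, with a warning, if everything is an error).
Effectiveness and efficiency are reported descriptively (per-task outcome
tables); correlating them against task-success or resource logs requires
data the framework does not itself produce, so those remain integration
hooks.  Dominance is reported but mapped to no factor.

## Known limitations

* The EDF codec covers the subset this package writes (identical integer
  rates, 1-s records); the last record is zero-padded, so a read-back
  recording may be up to fs-1 samples longer.
* Full-batch LM with exact Jacobians is practical for the static operating
  mode and small sequence problems; long sequences with many observed
  timesteps would need truncated or stochastic training.
* The selection union over states inflates the feature count at the
  default alpha; a multiplicity-corrected variant is a one-line change but
  deliberately not the default.
* Single-subject models only; no cross-subject transfer of selections or
  classifiers.
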