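# vadeeg

EEG-based emotion recognition for software usability testing.

`vadeeg` is for researchers and UX engineers who want an objective,
physiological read-out of a user's emotional state while they work through
software tasks, instead of (or alongside) questionnaires.  It classifies
each moment of a multichannel EEG recording along the three dimensions of
the valence–arousal–dominance (VAD) model — pleasant/unpleasant,
excited/calm, in-control/controlled — and links those labels to the
usability factors of a testing session (first impression, per-task
emotion, overall satisfaction).

## Method

For a subject with trials grouped by emotional state and a set of neutral
baseline trials:

1. **Preprocess** — zero-phase high-pass (1 Hz), common average reference,
   and FFT band extraction into theta (4–8), alpha (8–13), beta (13–30)
   and gamma (30–45 Hz).
2. **Fragment** — each trial of length *T* is split into
   `N = ⌊(T−W)/shift⌋ + 1` overlapping windows, `shift = (1−O)·W`, with
   *W* = 12 s, *O* = 50 %.
3. **ERD/ERS features on adaptively selected electrodes** — band power of
   an active fragment, *A*, is compared to the neutral reference average
   power *R* of the same channel and band:

       ERD/ERS = (A − R) / R

   Channels are selected per subject: a (channel, band) pair enters the
   feature vector if its power distribution differs significantly from the
   neutral baseline (rank-sum test, α = 0.05) in at least one emotional
   state, so the feature dimension adapts to the individual's brain
   activity.
4. **Classify** — per dimension, two one-vs-all recurrent tanh networks
   (80 hidden units, weights initialized in [−0.5, 0.5], recurrence damped
   by a 0.01 delay factor) are trained with full-batch
   Levenberg–Marquardt (λ₀ = 3, ×/÷ 10 adaptation, 8 epochs) using exact
   Jacobians from real-time recurrent learning.  The two binary labels
   fuse into a four-way outcome per dimension:
   (target, target) → error, (target, outlier) → upper,
   (outlier, target) → lower, (outlier, outlier) → neutral.
5. **Link** — a continuous-performance-test (CPT) gives the subject's mean
   reaction time, which sizes the "first impression" window; session
   recordings are segmented (discrete or continuous mode) and per-segment
   VAD labels become a usability report.

A synthetic-EEG generator (32-channel 10–20 montage at 128 Hz, band
oscillations with planted emotion-dependent power effects, neutral
baselines, CPT/task event logs) makes every stage testable end to end
without external recordings; see `docs/methods.md` for the model and its
limits.

## Worked example

Run the full pipeline on one synthetic subject (planted power ratio 0.6,
80 trials per state, held-out 25 % of trials):

```
$ vadeeg run --seed 1
selected electrodes: 32 (channel, band) pairs
valence   decision accuracy:  95.65 %
arousal   decision accuracy:  91.85 %
dominance decision accuracy:  94.57 %

confusion (valence), % per actual-level row:
         upper  neutral  lower  error
upper    92.50     3.75    2.5   1.25
neutral   0.00   100.00    0.0   0.00
lower     1.25     1.25   97.5   0.00
```

Reading the numbers: selection kept 32 of the 128 possible
(channel, band) pairs — the 12 electrode pairs that genuinely carry the
planted effects plus the false positives expected at α = 0.05 across eight
states.  Decision accuracy is the fraction of held-out fragments whose
fused outcome (upper / lower / neutral) matches the trial's true level in
that dimension; each confusion row shows where fragments of one true level
went, in percent, with fragments that fired both one-vs-all classifiers
tallied in the separate `error` column.

The same flow in Python:

```python
from vadeeg import run_synthetic_benchmark

report, model = run_synthetic_benchmark(effect=0.6, seed=1)
print(report.decision_accuracy)
# {'valence': 95.65, 'arousal': 91.85, 'dominance': 94.57}
```

Other entry points: `vadeeg simulate` writes a synthetic subject to disk
(matrix + JSON sidecar per trial), `vadeeg io convert` converts between
EDF and the matrix dialect, and `vadeeg fragment` prints the window count
for a trial length.  Library modules mirror the pipeline: `io`,
`preprocessing`, `fragmentation`, `features`, `rnn`, `classifier`,
`synthetic`, `usability`, `pipeline`.

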