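# Methods

This note records the modelling choices behind `capscore`, the defaults
that matter, and what the synthetic benchmark does and does not show.

## Scoring model

The scorer follows the two-step structure that dominates CAP research:
first decide, for every one-second epoch, whether it belongs to an A phase
(activation) or the B background; then apply the Terzano scoring rules to
the phase sequence to obtain per-epoch CAP/non-CAP flags.  The two-step
route is preferred over direct CAP-cycle classification because it yields
both the phases and the cycles, which are separately useful clinically.

Assumptions inherited from the scoring rules: phases are valid when they
last 2–60 s; a cycle is a valid A run immediately followed by a valid B
run; a CAP sequence needs at least two consecutive cycles.  The scorer is
applied to the whole recording — REM periods are not masked out, so any
A-like activity in REM counts against specificity.  Movement artifacts are
deliberately retained in the signal because transient activity is
correlated with the microstructure events being detected.

### Phase classifiers

Three architectures are provided (presets named `*_table1`): an LSTM
(400 cells), a GRU (200 cells) and a two-block 1-D CNN.  The layers,
backpropagation and the Adam optimizer are implemented directly in NumPy;
`networks.reference` holds literal, unbatched single-step transcriptions
of the gate equations that the vectorized layers are tested against
(agreement to 1e-10 on random instances, plus finite-difference gradient
checks to 1e-6).

Two readings of "input (100 neurons)" exist for the recurrent models and
both are implemented:

* `sequence_mode="epochs"` (default): each epoch is one time step carrying
  a 100-dimensional vector; a training sequence is a window of
  `context_length` consecutive epochs of one recording, trained
  sequence-to-sequence.  This is the reading consistent with the temporal
  dependency of CAP *across* epochs, which is the stated reason for using
  recurrent networks at all.  At prediction time the recurrence runs over
  the full recording as a single sequence, so no epoch is left unlabelled.
* `sequence_mode="samples"`: the recurrence runs over the 100 samples
  within one epoch (sequence-to-one).  Kept as a config option; epochs are
  then classified independently.

The printed form of the LSTM cell-candidate nonlinearity is a sigmoid,
which is non-standard (a sigmoid candidate can never decrease the cell
state, since `I, P ≥ 0`).  The reference step follows the printed form
exactly; the trainable cell defaults to the conventional tanh candidate
(`candidate="tanh"`) with `candidate="sigmoid"` available to reproduce the
literal equations.  The convolution is cross-correlation (no kernel flip),
the deep-learning convention.

Training defaults, all exposed in `TrainingConfig`: Adam, learning rate
1e-3, batch 256, 30 passes, context 60 epochs, decision threshold 0.5,
2-class cross-entropy on the softmax output, no class re-weighting
(optional inverse-frequency weighting exists but is off: the reference
procedure used none, and the B-majority imbalance is a property of the
data being emulated).  Weight initialization is Glorot-uniform with a
forget-gate bias of 1.  Training is bit-reproducible for a fixed seed in
single-threaded NumPy; this is a documented contract and is tested.

### Preprocessing

Decimation to 100 Hz uses an order-8 Chebyshev type I lowpass with 0.05 dB
passband ripple and normalized cutoff 0.8/r, the standard decimation
filter, applied forward-only by default (a zero-phase option exists but
changes the standard behaviour and is off).  Non-integer factors (e.g.
512 Hz sources) are handled by rational resampling: zero-stuff by L,
filter with the same design at cutoff 0.8/max(L, M), keep every M-th
sample.  The filter is realized as second-order sections; the polynomial
transfer-function form loses precision badly at the small relative cutoffs
that large upsampling factors produce.

Normalization is a whole-recording z-score using the population (divide by
n) standard deviation, performed before epoching so that between-epoch
amplitude differences — the main class signal — survive.  Epoching drops a
trailing remainder shorter than one second.

The flatline rule scans non-overlapping 60-epoch blocks; a block whose
every sample stays within `amplitude_eps` of zero is flagged erroneous and
scanning restarts at the next block.  "Close to zero" is not quantified by
the rule itself; the default `amplitude_eps = 1e-3` (normalized units) is
a package choice, far below any physiological background after z-scoring.
Erroneous epochs are excluded from metric computation and break cycle
chains.

### Post-processing and the cycle FSM

Isolated-phase correction flips runs of duration ≤ 2 s flanked by valid
(≥ 2 s) opposite-phase runs.  Choices made where the rule is silent:
1-second runs count as isolated (they are further below the minimum valid
phase than 2-second runs; a strict `exactly_two` switch restores the
narrower reading); flanks need only the 2 s minimum, not the 60 s maximum;
boundary runs are never flipped; all flips are decided on the original run
decomposition and applied at once, so the result is order-independent and
no cascade occurs.

The cycle scorer enforces the two-cycle sequence minimum by default
(`min_cycles_per_sequence=2`); setting 1 reproduces the literal
"any valid cycle" reading.  A trailing valid A run closes no cycle.  Note
a consequence of binary labels: B time adjacent to a cycle's B phase
merges into one run, so a cycle's B phase extends until the next A phase
or until the run exceeds 60 s and invalidates the cycle — there is no way,
and no need, to split a B run into "cycle part" and "gap part".

The scorer is verified against a brute-force oracle (direct enumeration of
every alternating valid-run interval) exhaustively on all 2^16 length-16
sequences and on 10,000 random length-600 sequences.

### Evaluation

Metrics are computed per held-out subject and averaged across subjects
(not pooled counts), matching a protocol that reports the average over
leave-one-subject-out iterations; each fold is retrained `n_repeats` times
with distinct seeds and the subject's metrics are first averaged over
repeats.  The 95 % confidence interval is Student-t over the per-subject
means — the CI construction of the original reports is not stated, so this
choice is documented rather than claimed identical.  Undefined metrics
(zero denominators, including an infinite DOR at Spe = 1) are excluded
from averages with a logged warning.  AUC uses the Mann–Whitney rank form
with ties counted one half; for the binary cycle detector the flags
themselves are ranked, which reduces to (Sen+Spe)/2.

## Synthetic generator

`capsim` emulates the *statistics* of CAP, not EEG physiology:

* phase durations: uniform on [2, 2·mean − 2] s (defaults: A mean 8 s,
  in-sequence B mean 18.9 s, giving the 26.9 s population mean cycle);
* cycles per sequence: 2 + Poisson(3.6), mean 5.6, minimum 2;
* sequences are emitted as n cycles plus one terminal valid A run, then an
  inter-sequence B gap drawn from [65, 120] s.  The terminal A closes no
  cycle (the following B run exceeds 60 s), so the rule engine scores
  exactly n cycles per sequence and the stored cycle truth — defined as
  the scorer's output on the true labels — matches the generative intent;
* signal: unit-variance 1/f colored noise background; during A phases a
  band-limited burst (0.5–4 Hz plus a weaker 8–12 Hz component) scaled by
  the `snr` amplitude knob is added under a raised-cosine envelope.
  `snr=0` yields a null recording (A and B statistically identical);
  `snr=4`, the default, makes A epochs easily separable (RMS ratio > 2).

One master seed fans out to per-subject seeds through a fixed
`SeedSequence` split, so corpora regenerate byte-identically.

What passing the synthetic benchmark shows: the pipeline is internally
consistent — preprocessing preserves the class signal, the classifiers can
learn a planted epoch-level difference, the correction and the FSM recover
the planted cycle structure, and the evaluation harness measures it all
correctly.  What it does not show: performance on real sleep EEG, where
A phases differ spectrally rather than mainly in amplitude, artifacts and
arousals confound the classes, and REM periods contribute structured
false positives.  Real-data figures require the clinical corpus and
full-scale training.

## Problem sizes

The test suite runs desk-scale configurations chosen to exercise every
code path quickly: the end-to-end recovery check uses 6 synthetic subjects
of 10 minutes each at `snr=4` with a reduced LSTM (64 cells, context 30,
60 training passes, 2 repeats per fold) and a shuffled-label control;
smaller fixtures (2 subjects, 16–32 cells) back the unit tests.  Full-size
presets (400-cell LSTM, 50 repeats, 19 subjects) are exercised for
construction and shape only — training them end-to-end is a compute-scale
choice left to users with real data.

## Known limitations

* No A-phase subtype (A1/A2/A3) classification — out of scope by design.
* No sleep-stage gating: NREM/REM are not distinguished.
* The EDF writer is a minimal single-channel 16-bit encoder intended for
  fixtures and round trips, not a general-purpose exporter.
* The PhysioNet-style annotation reader is best-effort and untested
  against the live database.
* Recurrent training is plain BPTT over non-overlapping windows; trailing
  window remainders shorter than the context are dropped from training
  (prediction always covers every epoch).
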