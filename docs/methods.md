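# Methods

This note records the modelling assumptions, parameter choices, and known
limitations of the toolkit, in the order signal → preprocessing → classifier
→ paradigm → evaluation.

## Synthetic EEG generator

The generator emulates one oddball sub-trial: a flash schedule is rendered
into a continuous 30-channel recording at 1000 Hz in which every flash of
the *attended* button adds an ERP template, and additive noise covers every
sample. It is a pure function of its inputs and one integer seed.

**ERP template.** A Gaussian bump in time, `a·exp(−(t−ℓ)²/2s²)` with peak
latency `ℓ = 350 ms`, temporal sd `s = width/2 = 50 ms`, and peak amplitude
`a = 5 µV`, multiplied by a fixed spatial topography (length-30 weight
vector, maximum 1 at Pz, falling off anteriorly) — a textbook P300
morphology. A Gaussian was chosen because it is smooth and effectively
band-limited well inside the 0.1–20 Hz analysis band, so zero-phase
filtering barely distorts it; the template is truncated to the 600 ms
epoch support. The 30 channels are a canonical 10–20 montage for a
32-electrode cap minus the two earlobe references; the montage order is
fixed in `synth.CHANNELS`.

**Noise.** White Gaussian noise per channel-sample (default), plus an
optional 1/f-shaped component (`pink_gain`). No ocular/EMG artifact model
and no mains interference: a 50 Hz notch is an acquisition-hardware
property and the simulator injects nothing at 50 Hz, so no notch stage is
implemented (the band-pass would remove it anyway). Optional uniform ±J ms
latency jitter on the template onset supports robustness experiments
(default 0).

**What passing tests do and do not show.** The generator produces
perfectly time-locked, stationarity-respecting signals with homogeneous
noise; real EEG has latency jitter, amplitude habituation, artifacts, and
non-stationary background rhythms. Results on this substrate validate the
*pipeline* (shapes, alignment, averaging, decoding mechanics, closed-loop
bookkeeping) and relative comparisons between decoders under matched
conditions; they do not predict absolute accuracies on human EEG.

## Preprocessing

* Band-pass 0.1–20 Hz: 4th-order Butterworth applied forward–backward
  (`sosfiltfilt`), i.e. zero phase, so epoch onsets stay aligned; the
  effective magnitude response is the square of one pass.
* Epoch: 600 samples from flash onset, every 4th sample kept → 150×30
  time-by-channel matrix. Plain decimation is aliasing-safe because the
  signal is already low-passed at 20 Hz, far below the 125 Hz
  post-decimation Nyquist.
* No baseline correction: the 0.1 Hz high-pass serves that role (a config
  switch exists in the filtering band edges if needed).
* Per-button averaging over rounds 1..k; one averaged epoch per button.
* Balancing: positives are replicated until class counts match — whole
  copies first, any remainder cycling through positives in input order
  (deterministic); negatives are never modified.

## The variational CNN

**Posterior and objective.** Every convolutional and dense weight tensor
carries a diagonal Gaussian posterior `q(w)=N(µ, σ²)`, `σ = softplus(ρ)` so
the optimization over ρ is unconstrained. The per-minibatch loss is the
exact negative evidence lower bound

    L_batch = Σ_{i∈batch} CE(y_i, f_w(x_i)) + (1/n_batches)·KL(q ‖ p),

with one reparameterized weight draw per step (`mc_train = 1`) and prior
`p = N(0, prior_sd²)`. The cross-entropy is *summed* over the batch so the
per-epoch sum over batches estimates the dataset's full negative ELBO;
with a mean-CE convention the KL term would dominate by a factor of the
batch size. The KL is closed-form per element:
`log(p/σ) + (σ²+µ²)/(2p²) − ½`.

**Prior scale.** `prior_sd = 0.5` by default. A much tighter prior
(e.g. 0.1) shrinks the weight means below their own posterior sd, so
sampled weights are noise-dominated and training never leaves chance — the
0.5 default keeps the KL a regularizer rather than a straitjacket. It is a
config field; the small-sample advantage reported by
`compare_small_sample` is obtained at this default.

**Topology.** Input BN (a single statistic pair for the whole 150×30 map)
→ 10 spatial filters (1×30) + BN + ReLU → max-pool (2×1, stride 2) → 10
temporal filters (length 20, spanning all 10 spatial maps, stride 6) + BN
+ ReLU → flatten to 100 → dense 100→100 with a softmax activation → dense
100→2 → softmax. The temporal stride of 6 is the unique value for which
75 pooled samples and a length-20 kernel yield (75−20)/6+1 = 10 positions,
i.e. exactly 100 flattened features. The hidden softmax is kept as the
default (`hidden_activation="softmax"`); a ReLU variant is available
behind the same flag since a softmax squashes hidden activations to the
simplex and mainly rescales the learning-rate regime.

**Training.** Plain SGD on (µ, ρ) and the BN affine parameters, batch
size 85, default 50 epochs, no early stopping; Adam is available as a
config option. Learning rate 0.01 by default. Seeded shuffling and weight
draws make two equal-seed runs bit-identical. Batch-norm batch statistics
are used during training and frozen running estimates at evaluation.

**Prediction.** The P300 probability of an epoch is the mean over
`mc_test = 20` independent weight draws of the final softmax's positive
class; recognition takes the argmax over candidate buttons, ties to the
lowest index. Setting `stochastic=False` freezes σ at 0 and skips the KL,
giving the point-weight CNN baseline with identical topology.

## Paradigm

Timing constants: 100 ms flash, 40 ms ISI (140 ms onset asynchrony), 10
rounds per sub-trial, no gap between rounds, 2.5 s between sub-trials, 5 s
between trials. Regions are labelled 'A'–'Y' row-major over the 5×5 region
grid (so 'M' is the centre region); digits 1–9 run row-major within each
3×3 block. Schedules draw one seeded permutation per round, with a
deterministic swap when a round would open with the button that closed the
previous round (no immediate re-flash across the abutting boundary).

Sequence shortening: start from the 9 digits plus 'R'; drop digits whose
cells are occupied; if fewer than 6 buttons remain, re-add dropped digits
in ascending order until the length is 6. 'R' is a control button and is
never dropped.

Note on nominal timing: the first sub-trial alone is 250 × 0.14 s = 35 s
of stimulation, so a fixed "about 30 s per trial" figure sometimes quoted
for two-level P300 selections cannot be reproduced from these constants;
the toolkit reports durations computed from the constants only.

## Gomoku opponent

Rule cascade: play an immediate win, else block an immediate opponent win,
else maximize a pattern score over open/closed runs of 2–4 (open runs
dominate), with the opponent's patterns weighted 0.3 and a small centre
bias; ties break to the lowest (row, col). The low defensive weight makes
two copies of the heuristic reach a decisive result (~86 moves) instead of
blocking each other into a draw. Overlines count as wins; no opening
restrictions. Strength is deliberately modest — the opponent exists to
close the loop, not to play well.

## Evaluation designs and problem sizes

* Training session: 40 first-level items → 40 positive / 960 negative
  averaged epochs → balanced 960/960.
* Accuracy-vs-repeats: for each trial both sub-trials are simulated once;
  for every repeat count k the candidates are re-averaged over rounds 1..k
  and re-recognized, giving three curves (first, second, complete; the
  complete trial is correct iff both selections are).
* Closed-loop game: the simulated subject's move policy is the built-in
  engine; a wrong first-level recognition makes the subject attend 'R'
  next (regret mechanic); recognized 'R' or a selection landing on an
  occupied cell counts as an invalid trial and places no stone. Accuracy =
  valid / total trials; times are nominal (from the timing constants).
* Small-sample comparison: both networks trained per seed on a half-size
  (20-item) training session and scored on first-sub-trial recognition.

**Operating point.** The default noise sd is 65 µV (white), calibrated
once so that, with the 5 µV ERP and the full 40-item training session,
complete-trial accuracy at 10 repeats lands in the 0.85–0.95 band
(measured 0.85–0.90 over seeds). A per-subject SNR cannot be taken from
human data here, so this operating point is a fixed property of the study
conditions, not a tuning knob.

**Reduced sizes.** The test suite and examples run the same designs at
reduced sizes (10–20 training items, 2–8 evaluation trials, 10–25 training
epochs, 4–10 Monte-Carlo draws) chosen so the full suite completes in
minutes on one CPU; the structural quantities (counts, shapes, sequence
lengths) are size-exact regardless, and the stochastic properties are
asserted with seed-averaged, tolerance-based checks.

## Numerical choices and degenerate inputs

* σ positivity via softplus; σ is initialized at 0.05, µ at
  N(0, 1/√fan_in); BN γ=1, β=0.
* Finite-difference validation of all hand-written gradients (absolute
  tolerance 2e-5 against central differences).
* Datasets smaller than one batch fall back to a single batch with a
  warning; a class with zero samples, an epoch window beyond the recording,
  non-finite data, and an empty candidate list raise errors.
* Recognition ties (identical probabilities) resolve to the lowest
  candidate index; `learning_rate = 0` is legal and leaves parameters
  unchanged (BN running statistics still accumulate).

## Known limitations

* No artifact model, no subject-variability model beyond config-exposed
  amplitude/latency/jitter, no transfer across simulated subjects.
* The Bayesian layer set excludes the BN affine parameters (treated as
  deterministic, standard practice).
* EDF export is not implemented (delimited-text matrix + TSV events are
  the writers; EDF reading is available via the optional mne dependency).
* The opponent is a 1-ply heuristic; game outcomes say nothing about
  Gomoku strength.
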