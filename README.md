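# p300gomoku

A toolkit for studying a P300 brain–computer-interface (BCI) board game in
simulation: synthetic oddball EEG, the standard event-related-potential
(ERP) preprocessing chain, a **Bayesian convolutional neural network** for
single-epoch P300 detection, a two-level stimulation paradigm with dynamic
sequence shortening, a Gomoku (five-in-a-row) engine, and a closed-loop
simulated-subject harness.

It is aimed at BCI researchers who want a fully seeded, end-to-end testbed
for P300 decoding ideas — every stage from stimulus schedule to placed
game stone is reproducible from integer seeds, and the "subject" is a
generative model whose signal-to-noise ratio you control.

## The decoding problem

In an oddball paradigm, buttons flash one at a time; the one the user
attends (rare among many) evokes a P300 — a central-parietal positive
deflection ~300–500 ms after the flash. Selecting 1 of N buttons reduces
to classifying, for each button, whether its flash-locked EEG epoch
contains a P300, then taking the argmax.

A move on the 15×15 board is selected in two sub-trials: first one of 25
region buttons (the board is partitioned into 25 labelled 3×3 regions),
then one of the 9 position digits or a regret button `R`. Each sub-trial
flashes every button once per round for 10 rounds (100 ms flash, 40 ms
inter-stimulus interval). The second-level sequence is *shortened* by
dropping digits whose cells are already occupied, clamped to a minimum of
6 buttons.

Preprocessing follows standard ERP practice: zero-phase 0.1–20 Hz
band-pass, a 600 ms epoch after each flash, ×4 decimation to a 150×30
time-by-channel matrix, per-button averaging over rounds, and replication
of the rare target class to balance training data.

## The classifier

Each convolutional/dense weight carries a diagonal Gaussian variational
posterior `q(w) = N(μ, σ²)` with `σ = softplus(ρ)`. A forward pass draws
`w = μ + ε·σ` (reparameterization trick) and training minimizes the
negative evidence lower bound per minibatch

```
L = Σ_batch CE(y, f_w(x)) + (1/n_batches) · KL(q ‖ N(0, s₀²))
```

by stochastic gradient descent on `(μ, ρ)` (Bayes by Backprop). Prediction
averages the P300 probability over `T` Monte-Carlo weight draws. Forcing
`σ = 0` yields a plain point-estimate CNN with identical topology — the
built-in baseline for small-sample comparisons.

Topology for a 150×30 epoch: input batch-norm → 10 spatial filters (1×30)
+ BN + ReLU → max-pool (2×1, stride 2) → 10 temporal filters (length 20,
full depth, stride 6) + BN + ReLU → flatten (100) → dense 100→100 with
softmax → dense 100→2 → softmax. All forward/backward passes are
hand-written NumPy, validated against finite differences and an
independently coded plain forward pass in the test suite.

## Worked example

```bash
python examples/02_train_and_evaluate.py
```

trains on a reduced simulated session (20 items at the calibrated
moderate SNR) and prints:

```
balanced training set: 480 P300 / 480 non-P300 averaged epochs
negative ELBO per batch: 1972.1 -> 1675.3 over 25 epochs
 repeats  first_subtrial  second_subtrial  complete_trial
       1           0.000            0.250           0.000
       2           0.250            0.250           0.125
       5           0.750            0.875           0.625
      10           0.875            0.875           0.750
```

Accuracy rises with the number of averaged rounds ("repeats"): averaging k
rounds shrinks the noise by √k while the time-locked P300 template stays
put. The complete trial is correct only when both sub-trial selections
are, so its curve lies below both. The other examples demonstrate the
synthetic generator (`01`), dynamic sequence shortening (`03`), and a full
closed-loop game (`04`).

A thin CLI wraps the same functions:

```bash
p300gomoku train --seed 1 --out scratch/model
p300gomoku exp1 --seed 2 --model scratch/model --out scratch/curves.csv
```

## Layout

- `src/p300gomoku/synth.py` — seeded synthetic oddball EEG (ERP template,
  noise model, session renderer; TSV/EDF I/O)
- `src/p300gomoku/preprocess.py` — filtering, epoching, averaging,
  class balancing
- `src/p300gomoku/bnn.py` — the variational CNN: sampling, closed-form KL,
  ELBO training, Monte-Carlo prediction, argmax recognition
- `src/p300gomoku/paradigm.py` — region map, flash schedules, sequence
  shortening, trial state machine, nominal timing
- `src/p300gomoku/gomoku.py` — rules, win detection, rule-based opponent
- `src/p300gomoku/session.py` — training sessions, accuracy-vs-repeats
  evaluation, closed-loop games, small-sample comparison
- `docs/methods.md` — modelling assumptions, parameter choices, and
  limitations
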