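"""Train the Bayesian CNN on a simulated training session and score it.

Runs a reduced-size study (20 training items instead of 40, 8 evaluation
trials instead of 20) at the calibrated moderate signal-to-noise ratio,
then reports recognition accuracy as a function of the number of averaged
stimulation rounds — the accuracy-vs-repeats curve that characterizes any
P300 speller-style interface.
"""

from p300gomoku import SessionConfig, TrainConfig
from p300gomoku.session import (
    run_experiment1, run_training_session, train_model,
)

cfg = SessionConfig(
    n_training_trials=20,
    n_exp1_trials=8,
    mc_test=10,
    train=TrainConfig(n_epochs=25),
)

dataset = run_training_session(cfg, seed=5)
print(f"balanced training set: {dataset.n_positive} P300 / "
      f"{dataset.n_negative} non-P300 averaged epochs")

model, trace = train_model(dataset, cfg, seed=5)
print(f"negative ELBO per batch: {trace[0]:.1f} -> {trace[-1]:.1f} "
      f"over {len(trace)} epochs")

result = run_experiment1(model, cfg, seed=6, repeats=[1, 2, 5, 10])
print(result.to_frame().to_string(index=False))
print("complete-trial accuracy is the product-like intersection of both "
      "sub-trials being correct; it rises with the number of averaged rounds.")
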