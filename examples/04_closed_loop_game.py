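"""A full closed-loop game with a noiseless simulated subject.

The subject's move policy is the built-in rule-based engine; every intended
coordinate is communicated through the two-level paradigm, decoded by a
Bayesian CNN trained on a small noiseless session, and placed on the board;
the computer opponent replies.  With no EEG noise every trial decodes
correctly, so the game statistics are exact.
"""

from p300gomoku import SessionConfig, TrainConfig
from p300gomoku.session import (
    run_experiment2, run_training_session, train_model,
)

cfg = SessionConfig(
    n_training_trials=8,
    noise_sd_uV=0.0,   # noiseless: recognition is error-free
    mc_test=4,
    train=TrainConfig(n_epochs=10),
)

dataset = run_training_session(cfg, seed=1)
model, _ = train_model(dataset, cfg, seed=1)

result = run_experiment2(model, cfg, seed=2)
print(f"trials: {result.trials}, valid: {result.valid_trials}, "
      f"accuracy: {result.accuracy:.3f}")
print(f"game result: {result.game_status.value} after "
      f"{len(result.history)} stones")
print(f"nominal session time: {result.total_time_s / 60:.1f} min "
      f"({result.time_per_trial_s:.1f} s per trial)")
for entry in result.log[:3]:
    print(entry)
print("... each log line records one trial: the intended coordinate, both "
      "recognized selections, and the outcome.")
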