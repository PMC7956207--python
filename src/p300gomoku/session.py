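"""Closed-loop orchestration: training-data collection, accuracy-vs-repeats
evaluation, and full simulated game sessions.

A "simulated subject" attends the button the task demands on every sub-trial
(perfect attention); its EEG is rendered by `synth`, preprocessed by
`preprocess`, and decoded by the Bayesian CNN.  Three evaluation designs are
provided:

* a training session: 40 first-level sub-trials with known targets, averaged
  per button and balanced into a classifier training set;
* experiment I: system-prompted target selection, scored per repeat count
  for the first sub-trial, the second sub-trial, and the complete trial
  (complete is correct iff both sub-trials are);
* experiment II: the full game loop, where recognition places stones,
  a wrong region selection is resolved by the regret button, and the
  rule-based opponent replies, with accuracy = valid / total trials;
* a small-sample comparison of the variational network against the
  point-weight CNN baseline on half-size training sets.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from . import gomoku, paradigm
from .bnn import BayesianCNN, TrainConfig, recognize, train
from .preprocess import (
    LabeledDataset, average_by_button, balance, bandpass, extract_epochs,
)
from .synth import ErpTemplate, NoiseModel, make_erp_template, simulate_session

#: Background-noise sd (microvolts) giving a moderate-SNR operating point:
#: with the default 5 uV ERP, 10-round averaging puts complete-trial
#: recognition accuracy in the 0.85-0.95 band.  Calibrated once; see
#: docs/methods.md.
DEFAULT_NOISE_SD_UV = 65.0


@dataclasses.dataclass
class SessionConfig:
    """All knobs of a simulated study, with the study-design defaults."""

    n_training_trials: int = 40
    n_exp1_trials: int = 20
    rounds: int = paradigm.N_ROUNDS
    erp_latency_ms: float = 350.0
    erp_width_ms: float = 100.0
    erp_amplitude_uV: float = 5.0
    noise_sd_uV: float = DEFAULT_NOISE_SD_UV
    pink_gain: float = 0.0
    jitter_ms: float = 0.0
    mc_test: int = 20
    max_game_trials: int = 60
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if min(self.n_training_trials, self.n_exp1_trials, self.rounds) < 1:
            raise ValueError("all counts must be >= 1")

    def erp(self) -> ErpTemplate:
        return make_erp_template(
            latency_ms=self.erp_latency_ms,
            width_ms=self.erp_width_ms,
            amplitude_uV=self.erp_amplitude_uV,
        )

    def noise(self) -> NoiseModel:
        return NoiseModel(white_sd_uV=self.noise_sd_uV,
                          pink_gain=self.pink_gain)


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2 ** 31, size=n)


def _averaged_candidates(
    schedule: paradigm.FlashSchedule,
    session,
    k_rounds: int,
) -> np.ndarray:
    """Preprocess one simulated sub-trial into per-button averaged epochs,
    ordered like ``schedule.buttons``; returns an (n_buttons, 150, 30) array."""
    filtered = bandpass(session.recording)
    epochs = extract_epochs(filtered, session.events)
    averaged = {
        ep.button: ep for ep in average_by_button(epochs, k_rounds=k_rounds)
    }
    return np.stack([averaged[b].matrix for b in schedule.buttons])


def run_subtrial(
    schedule: paradigm.FlashSchedule,
    attended: str,
    cfg: SessionConfig,
    seed: int,
):
    """Simulate one sub-trial's EEG for the attending subject."""
    return simulate_session(
        schedule, attended, cfg.erp(), cfg.noise(), seed=seed,
        jitter_ms=cfg.jitter_ms,
    )


# --------------------------------------------------------------------- #
# training session

def collect_training_data(cfg: SessionConfig, seed: int) -> LabeledDataset:
    """Simulate the training session and return the *unbalanced* dataset.

    First-level paradigm only: each of the ``n_training_trials`` items is one
    25-button sub-trial with a known attended region, averaged per button
    over all rounds, labelled target vs non-target (so 1 positive and 24
    negative averaged epochs per item).
    """
    rng = np.random.default_rng(seed)
    X, y = [], []
    for _trial in range(cfg.n_training_trials):
        attended = paradigm.REGION_LABELS[rng.integers(25)]
        sched = paradigm.first_level_sequence(
            seed=int(rng.integers(2 ** 31)), rounds=cfg.rounds
        )
        sess = run_subtrial(sched, attended, cfg, seed=int(rng.integers(2 ** 31)))
        filtered = bandpass(sess.recording)
        averaged = average_by_button(
            extract_epochs(filtered, sess.events), k_rounds=cfg.rounds
        )
        for ep in averaged:
            X.append(ep.matrix)
            y.append(1 if ep.button == attended else 0)
    return LabeledDataset(X=np.array(X), y=np.array(y))


def run_training_session(cfg: SessionConfig, seed: int) -> LabeledDataset:
    """Collect training data and balance the classes by replication."""
    return balance(collect_training_data(cfg, seed))


def train_model(
    dataset: LabeledDataset,
    cfg: SessionConfig,
    seed: int,
    stochastic: bool = True,
) -> tuple[BayesianCNN, list[float]]:
    """Train a fresh network (variational, or the sigma = 0 baseline)."""
    train_cfg = dataclasses.replace(cfg.train, seed=seed)
    model = BayesianCNN(
        prior_sd=train_cfg.prior_sd, stochastic=stochastic, seed=seed
    )
    trace = train(model, dataset.X, dataset.y, train_cfg)
    return model, trace


# --------------------------------------------------------------------- #
# experiment I

@dataclasses.dataclass
class Exp1Result:
    """Accuracy-vs-repeats curves: index k = repeats used (1..rounds)."""

    repeats: np.ndarray
    first_subtrial: np.ndarray
    second_subtrial: np.ndarray
    complete_trial: np.ndarray
    n_trials: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "repeats": self.repeats,
            "first_subtrial": self.first_subtrial,
            "second_subtrial": self.second_subtrial,
            "complete_trial": self.complete_trial,
        })


def run_experiment1(
    model: BayesianCNN,
    cfg: SessionConfig,
    seed: int,
    repeats: list[int] | None = None,
) -> Exp1Result:
    """System-prompted target selection scored at every repeat count.

    Each trial prompts a random board coordinate; the subject attends its
    region in the first sub-trial and its digit in the second (second-level
    sequence built for the true region on an empty board).  For each repeat
    count k the candidates are averaged over rounds 1..k and recognized; the
    complete trial is correct iff both sub-trials are.
    """
    ks = list(repeats) if repeats is not None else list(range(1, cfg.rounds + 1))
    rng = np.random.default_rng(seed)
    rm = paradigm.build_region_map()
    board = gomoku.Board()  # experiment I uses an empty board
    hits1 = np.zeros(len(ks))
    hits2 = np.zeros(len(ks))
    hits_complete = np.zeros(len(ks))
    for _trial in range(cfg.n_exp1_trials):
        target = (int(rng.integers(15)), int(rng.integers(15)))
        region, digit = rm.from_coordinate(*target)
        sched1 = paradigm.first_level_sequence(
            seed=int(rng.integers(2 ** 31)), rounds=cfg.rounds
        )
        sess1 = run_subtrial(sched1, region, cfg, seed=int(rng.integers(2 ** 31)))
        sched2 = paradigm.gi_ss_sequence(
            region, board, seed=int(rng.integers(2 ** 31)), rounds=cfg.rounds
        )
        sess2 = run_subtrial(sched2, str(digit), cfg,
                             seed=int(rng.integers(2 ** 31)))
        mc_rng = np.random.default_rng(int(rng.integers(2 ** 31)))
        for i, k in enumerate(ks):
            cand1 = _averaged_candidates(sched1, sess1, k)
            cand2 = _averaged_candidates(sched2, sess2, k)
            pick1 = sched1.buttons[
                recognize(model, cand1, T=cfg.mc_test, rng=mc_rng)
            ]
            pick2 = sched2.buttons[
                recognize(model, cand2, T=cfg.mc_test, rng=mc_rng)
            ]
            ok1, ok2 = pick1 == region, pick2 == str(digit)
            hits1[i] += ok1
            hits2[i] += ok2
            hits_complete[i] += ok1 and ok2
    n = cfg.n_exp1_trials
    return Exp1Result(
        repeats=np.array(ks),
        first_subtrial=hits1 / n,
        second_subtrial=hits2 / n,
        complete_trial=hits_complete / n,
        n_trials=n,
    )


# --------------------------------------------------------------------- #
# experiment II

@dataclasses.dataclass
class Exp2Result:
    """Game-session statistics (accuracy = valid trials / total trials)."""

    trials: int
    valid_trials: int
    accuracy: float
    total_time_s: float
    time_per_trial_s: float
    game_status: gomoku.Status
    history: list[tuple[int, int, int]]
    log: list[dict]

    def write_log(self, path) -> None:
        with open(path, "w") as fh:
            for entry in self.log:
                fh.write(json.dumps(entry) + "\n")


def run_experiment2(
    model: BayesianCNN,
    cfg: SessionConfig,
    seed: int,
    subject_color: int = gomoku.BLACK,
) -> Exp2Result:
    """Full closed-loop game: recognition drives the board.

    The simulated subject plays ``subject_color`` using the rule-based
    engine as its move policy; the computer opponent plays the other colour.
    A wrong first-level recognition makes the subject attend 'R' in the
    second sub-trial (the regret mechanic); a recognized 'R', or a selection
    landing on an occupied cell, records an invalid trial and no stone is
    placed.  Times are nominal, from the paradigm's timing constants.
    """
    rng = np.random.default_rng(seed)
    rm = paradigm.build_region_map()
    board = gomoku.Board()
    opp_color = gomoku.WHITE if subject_color == gomoku.BLACK else gomoku.BLACK
    status = gomoku.Status.ONGOING
    log: list[dict] = []
    trials = valid_trials = 0
    total_time = 0.0

    if subject_color == gomoku.WHITE:
        move = gomoku.ai_move(board, seed=int(rng.integers(2 ** 31)))
        board = gomoku.apply_move(board, move, opp_color)
        status = gomoku.check_win(board, move).status

    while status is gomoku.Status.ONGOING and trials < cfg.max_game_trials:
        intended = gomoku.ai_move(board, seed=int(rng.integers(2 ** 31)))
        region, digit = rm.from_coordinate(*intended)

        sched1 = paradigm.first_level_sequence(
            seed=int(rng.integers(2 ** 31)), rounds=cfg.rounds
        )
        sess1 = run_subtrial(sched1, region, cfg, seed=int(rng.integers(2 ** 31)))
        mc_rng = np.random.default_rng(int(rng.integers(2 ** 31)))
        cand1 = _averaged_candidates(sched1, sess1, cfg.rounds)
        rec_region = sched1.buttons[
            recognize(model, cand1, T=cfg.mc_test, rng=mc_rng)
        ]

        sched2 = paradigm.gi_ss_sequence(
            rec_region, board, seed=int(rng.integers(2 ** 31)), rounds=cfg.rounds
        )
        attended2 = str(digit) if rec_region == region else paradigm.REGRET_BUTTON
        sess2 = run_subtrial(sched2, attended2, cfg,
                             seed=int(rng.integers(2 ** 31)))
        cand2 = _averaged_candidates(sched2, sess2, cfg.rounds)
        rec2 = sched2.buttons[
            recognize(model, cand2, T=cfg.mc_test, rng=mc_rng)
        ]

        trials += 1
        total_time += paradigm.nominal_trial_seconds((sched1, sched2))
        entry = {
            "trial": trials, "intended": list(intended),
            "attended_region": region, "recognized_region": rec_region,
            "attended_level2": attended2, "recognized_level2": rec2,
        }
        if rec2 == paradigm.REGRET_BUTTON:
            entry["outcome"] = "invalid-regret"
            log.append(entry)
            continue
        coord = paradigm.map_selection(rec_region, int(rec2))
        if not board.is_empty(*coord):
            entry["outcome"] = "invalid-occupied"
            log.append(entry)
            continue
        valid_trials += 1
        board = gomoku.apply_move(board, coord, subject_color)
        status = gomoku.check_win(board, coord).status
        entry["outcome"] = "placed"
        entry["coordinate"] = list(coord)
        entry["status"] = status.value
        if status is gomoku.Status.ONGOING:
            move = gomoku.ai_move(board, seed=int(rng.integers(2 ** 31)))
            board = gomoku.apply_move(board, move, opp_color)
            status = gomoku.check_win(board, move).status
            entry["opponent_move"] = list(move)
            entry["status"] = status.value
        log.append(entry)

    return Exp2Result(
        trials=trials,
        valid_trials=valid_trials,
        accuracy=valid_trials / trials if trials else 0.0,
        total_time_s=total_time,
        time_per_trial_s=total_time / trials if trials else 0.0,
        game_status=status,
        history=list(board.history),
        log=log,
    )


# --------------------------------------------------------------------- #
# small-sample comparison

def evaluate_first_subtrial(
    model: BayesianCNN,
    cfg: SessionConfig,
    seed: int,
    n_trials: int,
    repeats: list[int] | None = None,
) -> np.ndarray:
    """First-sub-trial recognition accuracy per repeat count."""
    ks = list(repeats) if repeats is not None else list(range(1, cfg.rounds + 1))
    rng = np.random.default_rng(seed)
    hits = np.zeros(len(ks))
    for _trial in range(n_trials):
        attended = paradigm.REGION_LABELS[rng.integers(25)]
        sched = paradigm.first_level_sequence(
            seed=int(rng.integers(2 ** 31)), rounds=cfg.rounds
        )
        sess = run_subtrial(sched, attended, cfg, seed=int(rng.integers(2 ** 31)))
        mc_rng = np.random.default_rng(int(rng.integers(2 ** 31)))
        for i, k in enumerate(ks):
            cand = _averaged_candidates(sched, sess, k)
            pick = sched.buttons[recognize(model, cand, T=cfg.mc_test, rng=mc_rng)]
            hits[i] += pick == attended
    return hits / n_trials


def compare_small_sample(
    cfg: SessionConfig,
    seeds: list[int],
    n_eval_trials: int = 12,
    repeats: list[int] | None = None,
) -> pd.DataFrame:
    """Variational vs point-weight CNN on half-size training sets.

    For every seed, both networks are trained on a training session of
    ``n_training_trials // 2`` items and scored on first-sub-trial
    recognition per repeat count; the table reports mean and sd across
    seeds, one row per repeat count.
    """
    ks = list(repeats) if repeats is not None else list(range(1, cfg.rounds + 1))
    half_cfg = dataclasses.replace(
        cfg, n_training_trials=max(cfg.n_training_trials // 2, 1)
    )
    acc = {"bayes": [], "point": []}
    for seed in seeds:
        dataset = run_training_session(half_cfg, seed=seed)
        eval_seed = int(np.random.default_rng(seed + 1).integers(2 ** 31))
        for name, stochastic in (("bayes", True), ("point", False)):
            model, _ = train_model(dataset, half_cfg, seed=seed,
                                   stochastic=stochastic)
            acc[name].append(
                evaluate_first_subtrial(model, half_cfg, seed=eval_seed,
                                        n_trials=n_eval_trials, repeats=ks)
            )
    bayes = np.array(acc["bayes"])
    point = np.array(acc["point"])
    return pd.DataFrame({
        "repeats": ks,
        "bayes_mean": bayes.mean(axis=0),
        "bayes_sd": bayes.std(axis=0, ddof=1) if len(seeds) > 1 else 0.0,
        "point_mean": point.mean(axis=0),
        "point_sd": point.std(axis=0, ddof=1) if len(seeds) > 1 else 0.0,
    })
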