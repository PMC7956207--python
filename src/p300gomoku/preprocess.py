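"""EEG preprocessing: band-pass filtering, epoching, averaging, balancing.

The chain mirrors standard P300 practice: zero-phase 0.1-20 Hz band-pass on
the continuous signal, a 600 ms epoch after each flash, x4 decimation to a
150 x 30 time-by-channel matrix, per-button averaging over stimulation
rounds, and replication of the rare target class so the classifier trains on
balanced data.
"""

from __future__ import annotations

import dataclasses
import json
from collections import OrderedDict
from typing import Sequence

import numpy as np
from scipy import signal

#: Epoch window after flash onset, in ms, and the decimation factor.
EPOCH_MS = 600
DECIM = 4
#: Epoch matrix shape: 150 time samples (600 ms at 1000 Hz / 4) x 30 channels.
N_T = 150
N_ELEC = 30


@dataclasses.dataclass
class EEGRecording:
    """Continuous multi-channel EEG: ``data[channel, sample]`` in microvolts."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"data shape {self.data.shape} inconsistent with "
                f"{len(self.channel_labels)} channel labels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclasses.dataclass(frozen=True)
class FlashEvent:
    """One button intensification: where it starts and what was flashed."""

    onset_sample: int
    button: str
    level: int = 1
    round: int = 1
    is_target: bool | None = None


@dataclasses.dataclass(frozen=True)
class Epoch:
    """A 150 x 30 time-by-channel matrix fed to the classifier."""

    matrix: np.ndarray
    button: str
    round: int = 1
    is_target: bool | None = None

    def __post_init__(self) -> None:
        if self.matrix.shape != (N_T, N_ELEC):
            raise ValueError(
                f"epoch matrix must be {(N_T, N_ELEC)}, got {self.matrix.shape}"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("epoch contains non-finite values")


@dataclasses.dataclass
class LabeledDataset:
    """Classifier-ready epochs: ``X[i]`` is 150 x 30, ``y[i]`` is 1 for P300."""

    X: np.ndarray  # (n, N_T, N_ELEC)
    y: np.ndarray  # (n,) in {0, 1}

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 3 or self.X.shape[1:] != (N_T, N_ELEC):
            raise ValueError(f"X must be (n, {N_T}, {N_ELEC}), got {self.X.shape}")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("labels must align one-to-one with epochs")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.y == 1))

    @property
    def n_negative(self) -> int:
        return int(np.sum(self.y == 0))


def bandpass(
    recording: EEGRecording, low_hz: float = 0.1, high_hz: float = 20.0,
    order: int = 4,
) -> EEGRecording:
    """Zero-phase Butterworth band-pass, applied forward-backward.

    Zero-phase filtering (``sosfiltfilt``) keeps epoch onsets aligned with the
    unfiltered event latencies; the effective magnitude response is the square
    of a single pass of the order-``order`` design.
    """
    nyq = recording.fs / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"invalid band edges ({low_hz}, {high_hz}) for fs={recording.fs}"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=recording.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, recording.data, axis=1)
    return EEGRecording(data=filtered, fs=recording.fs,
                        channel_labels=list(recording.channel_labels))


def extract_epoch(recording: EEGRecording, event: FlashEvent) -> Epoch:
    """Cut the 600 ms window after a flash and decimate by 4 -> 150 x 30.

    Plain decimation (keep every 4th sample) is aliasing-safe here because the
    recording is already low-passed at 20 Hz, far below the post-decimation
    Nyquist of 125 Hz.
    """
    n_win = int(round(EPOCH_MS * recording.fs / 1000.0))
    start = event.onset_sample
    if start < 0 or start + n_win > recording.n_samples:
        raise IndexError(
            f"epoch window [{start}, {start + n_win}) exceeds recording "
            f"bounds [0, {recording.n_samples})"
        )
    window = recording.data[:, start : start + n_win : DECIM]
    return Epoch(matrix=window.T.copy(), button=event.button,
                 round=event.round, is_target=event.is_target)


def extract_epochs(
    recording: EEGRecording, events: Sequence[FlashEvent]
) -> list[Epoch]:
    """Epoch every event of a (filtered) recording."""
    return [extract_epoch(recording, ev) for ev in events]


def average_by_button(
    epochs: Sequence[Epoch], k_rounds: int = 10
) -> list[Epoch]:
    """Element-wise mean per button over its flashes in rounds 1..k_rounds.

    Superimposing and averaging the matrices of the same flashed button
    raises the ERP above the background noise; one averaged epoch is returned
    per distinct button, in first-appearance order.
    """
    if not epochs:
        raise ValueError("no epochs to average")
    if k_rounds < 1:
        raise ValueError(f"k_rounds must be >= 1, got {k_rounds}")
    groups: OrderedDict[str, list[Epoch]] = OrderedDict()
    for ep in epochs:
        groups.setdefault(ep.button, []).append(ep)
    out = []
    for button, group in groups.items():
        selected = [ep for ep in group if ep.round <= k_rounds]
        if not selected:
            raise ValueError(
                f"button {button!r} has no flashes in rounds 1..{k_rounds}"
            )
        mean = np.mean([ep.matrix for ep in selected], axis=0)
        is_target = selected[0].is_target
        out.append(Epoch(matrix=mean, button=button, round=k_rounds,
                         is_target=is_target))
    return out


def balance(dataset: LabeledDataset) -> LabeledDataset:
    """Replicate the positive (P300) class until class counts are equal.

    Whole copies first; a non-integer remainder is filled by cycling through
    the positives in input order, which keeps the operation deterministic.
    Negatives are never touched.  Copies are appended after the original
    epochs, originals first.
    """
    n_pos, n_neg = dataset.n_positive, dataset.n_negative
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"both classes must be present (got {n_pos} positive, "
            f"{n_neg} negative)"
        )
    if n_pos == n_neg:
        return dataset
    if n_pos > n_neg:
        raise ValueError("more positives than negatives; nothing to replicate")
    pos_idx = np.flatnonzero(dataset.y == 1)
    n_extra = n_neg - n_pos
    extra = np.concatenate([
        np.tile(pos_idx, n_extra // n_pos),
        pos_idx[: n_extra % n_pos],
    ]).astype(int)
    X = np.concatenate([dataset.X, dataset.X[extra]], axis=0)
    y = np.concatenate([dataset.y, dataset.y[extra]], axis=0)
    return LabeledDataset(X=X, y=y)


def save_dataset(path_prefix: str, dataset: LabeledDataset,
                 meta: dict | None = None) -> None:
    """Write a dataset as ``<prefix>.npz`` plus a ``<prefix>.json`` sidecar."""
    np.savez(path_prefix + ".npz", X=dataset.X, y=dataset.y)
    sidecar = {
        "n_epochs": len(dataset),
        "shape": list(dataset.X.shape),
        "n_positive": dataset.n_positive,
        "n_negative": dataset.n_negative,
    }
    if meta:
        sidecar.update(meta)
    with open(path_prefix + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_dataset(path_prefix: str) -> LabeledDataset:
    arr = np.load(path_prefix + ".npz")
    return LabeledDataset(X=arr["X"], y=arr["y"])
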