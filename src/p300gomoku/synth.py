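"""Synthetic oddball EEG sessions with controllable P300 morphology and noise.

Stands in for the amplifier/electrode-cap stage of a real recording: given a
flash schedule and an attended button, it renders a continuous 30-channel
recording in which every flash of the attended button is followed by an
event-related potential (ERP) template, and every sample carries additive
noise.  All randomness flows through a single integer seed, so a session is a
pure function of its inputs.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .preprocess import EEGRecording, FlashEvent

#: Acquisition sampling rate in Hz.
FS = 1000

#: The 30 recorded channels: a canonical 10-20 montage for a 32-electrode cap
#: with the two earlobe references (A1, A2) excluded.
CHANNELS = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC3", "FCz", "FC4", "FT8",
    "T7", "C3", "Cz", "C4", "T8",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
)

N_CHANNELS = len(CHANNELS)

#: Template support: the ERP waveform is identically zero outside
#: [0, TEMPLATE_MS] milliseconds after flash onset.
TEMPLATE_MS = 600

# Relative P300 scalp weights: a central-parietal positivity peaking at Pz.
_TOPO_WEIGHTS = {
    "Pz": 1.0, "CPz": 0.92, "Cz": 0.78, "P3": 0.75, "P4": 0.75,
    "CP3": 0.72, "CP4": 0.72, "POz": 0.9, "FCz": 0.5, "C3": 0.45,
    "C4": 0.45, "P7": 0.35, "P8": 0.35, "Oz": 0.4, "O1": 0.3, "O2": 0.3,
    "Fz": 0.3, "F3": 0.2, "F4": 0.2,
}
_TOPO_DEFAULT = 0.12


def default_topography() -> np.ndarray:
    """Per-channel ERP weights (length 30, max 1.0, peak at Pz)."""
    return np.array([_TOPO_WEIGHTS.get(ch, _TOPO_DEFAULT) for ch in CHANNELS])


@dataclasses.dataclass(frozen=True)
class ErpTemplate:
    """A sampled ERP waveform: ``waveform[t, c]`` in microvolts at 1000 Hz.

    The waveform is a Gaussian bump peaking ``latency_ms`` after flash onset
    with standard deviation ``width_ms / 2`` in time, scaled per channel by
    ``topography`` (so the spatial peak carries ``amplitude_uV`` exactly).
    A Gaussian is smooth and effectively band-limited well inside the
    0.1-20 Hz analysis band, so zero-phase filtering barely distorts it.
    """

    latency_ms: float
    width_ms: float
    amplitude_uV: float
    topography: np.ndarray
    waveform: np.ndarray  # (TEMPLATE_MS, N_CHANNELS)

    @property
    def n_samples(self) -> int:
        return self.waveform.shape[0]


def make_erp_template(
    latency_ms: float = 350.0,
    width_ms: float = 100.0,
    amplitude_uV: float = 5.0,
    topography: np.ndarray | None = None,
) -> ErpTemplate:
    """Build a sampled Gaussian ERP bump.

    Parameters
    ----------
    latency_ms : peak time after flash onset (P300 conventionally ~300-500 ms).
    width_ms : temporal spread; the Gaussian sd is ``width_ms / 2``.
    amplitude_uV : peak amplitude on the maximally weighted channel.
    topography : per-channel weights, length 30; defaults to a
        central-parietal map peaking at Pz.
    """
    if width_ms <= 0:
        raise ValueError(f"width_ms must be positive, got {width_ms}")
    if topography is None:
        topography = default_topography()
    topography = np.asarray(topography, dtype=float)
    if topography.shape != (N_CHANNELS,):
        raise ValueError(
            f"topography must have length {N_CHANNELS}, got {topography.shape}"
        )
    if not np.all(np.isfinite(topography)):
        raise ValueError("topography must be finite")
    t = np.arange(TEMPLATE_MS, dtype=float)  # ms grid at 1000 Hz
    sd = width_ms / 2.0
    bump = amplitude_uV * np.exp(-0.5 * ((t - latency_ms) / sd) ** 2)
    waveform = bump[:, None] * topography[None, :]
    return ErpTemplate(latency_ms, width_ms, amplitude_uV, topography, waveform)


@dataclasses.dataclass(frozen=True)
class NoiseModel:
    """Additive background noise: white Gaussian plus optional 1/f.

    ``white_sd_uV`` is the sd of i.i.d. Gaussian noise per sample;
    ``pink_gain`` scales a spectrally shaped (amplitude ~ 1/sqrt(f))
    component, 0 disables it.
    """

    white_sd_uV: float = 10.0
    pink_gain: float = 0.0

    def __post_init__(self) -> None:
        if self.white_sd_uV < 0 or self.pink_gain < 0:
            raise ValueError("noise amplitudes must be non-negative")

    def sample(self, shape: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
        noise = np.zeros(shape)
        if self.white_sd_uV > 0:
            noise += rng.normal(0.0, self.white_sd_uV, shape)
        if self.pink_gain > 0:
            noise += self.pink_gain * _pink_noise(shape, rng)
        return noise


def _pink_noise(shape: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-shaped noise along the last axis."""
    n = shape[-1]
    white = rng.normal(size=shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / FS)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    pink = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = pink.std()
    return pink / sd if sd > 0 else pink


@dataclasses.dataclass(frozen=True)
class SimSession:
    """One simulated sub-trial: a recording, its flash events, and the truth."""

    recording: EEGRecording
    events: list[FlashEvent]
    attended: str
    seed: int


def simulate_session(
    schedule,
    attended: str,
    erp: ErpTemplate,
    noise: NoiseModel,
    seed: int,
    jitter_ms: float = 0.0,
    pad_ms: float = 100.0,
) -> SimSession:
    """Render a flash schedule into a continuous 30-channel recording.

    The ERP template is added at (only) the flashes of ``attended``; noise is
    added everywhere.  ``jitter_ms`` applies an optional uniform +/-J ms shift
    to each template onset (default 0).  Identical arguments and seed give a
    bit-identical recording.

    Parameters
    ----------
    schedule : a `paradigm.FlashSchedule` (or any object with ``flashes``
        yielding (onset_ms, button, round) and attributes ``level``,
        ``buttons``).
    attended : the button the simulated subject attends; must be in the
        schedule's button set unless the schedule is empty.
    """
    flashes = list(schedule.flashes)
    if flashes and attended not in schedule.buttons:
        raise ValueError(f"attended button {attended!r} not in schedule")
    onsets_ms = [f[0] for f in flashes]
    if onsets_ms != sorted(set(onsets_ms)):
        raise ValueError("schedule onsets must be strictly increasing")

    last_ms = onsets_ms[-1] if onsets_ms else 0.0
    n_samples = int(round((last_ms + TEMPLATE_MS + pad_ms) * FS / 1000.0))
    rng = np.random.default_rng(seed)
    data = noise.sample((N_CHANNELS, n_samples), rng)

    events: list[FlashEvent] = []
    for onset_ms, button, rnd in flashes:
        onset = int(round(onset_ms * FS / 1000.0))
        is_target = button == attended
        if is_target:
            start = onset
            if jitter_ms > 0:
                start += int(round(rng.uniform(-jitter_ms, jitter_ms)))
                start = max(0, min(start, n_samples - erp.n_samples))
            data[:, start : start + erp.n_samples] += erp.waveform.T
        events.append(
            FlashEvent(
                onset_sample=onset,
                button=button,
                level=schedule.level,
                round=rnd,
                is_target=is_target,
            )
        )

    rec = EEGRecording(data=data, fs=FS, channel_labels=list(CHANNELS))
    return SimSession(recording=rec, events=events, attended=attended, seed=seed)


def write_recording_txt(path, recording: EEGRecording) -> None:
    """Write a recording as a TSV matrix, channels as columns, header row."""
    header = "\t".join(recording.channel_labels)
    np.savetxt(path, recording.data.T, fmt="%.6f", delimiter="\t",
               header=header, comments="")


def read_recording_txt(path, fs: float = FS) -> EEGRecording:
    with open(path) as fh:
        labels = fh.readline().strip().split("\t")
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    return EEGRecording(data=np.atleast_2d(data).T, fs=fs, channel_labels=labels)


def read_recording_edf(path) -> EEGRecording:
    """Read a recording from EDF (requires the optional ``mne`` dependency)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return EEGRecording(
        data=raw.get_data() * 1e6,  # volts -> microvolts
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
    )


def write_events_tsv(path, events: Sequence[FlashEvent], fs: float = FS) -> None:
    """Write flash events as TSV: onset_ms, level, button, round, is_target."""
    with open(path, "w") as fh:
        fh.write("onset_ms\tlevel\tbutton\tround\tis_target\n")
        for ev in events:
            fh.write(
                f"{ev.onset_sample * 1000.0 / fs:.3f}\t{ev.level}\t"
                f"{ev.button}\t{ev.round}\t{int(bool(ev.is_target))}\n"
            )


def read_events_tsv(path, fs: float = FS) -> list[FlashEvent]:
    events = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            row = line.rstrip("\n").split("\t")
            events.append(
                FlashEvent(
                    onset_sample=int(round(float(row[idx["onset_ms"]]) * fs / 1000.0)),
                    button=row[idx["button"]],
                    level=int(row[idx["level"]]),
                    round=int(row[idx["round"]]),
                    is_target=bool(int(row[idx["is_target"]])),
                )
            )
    return events
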