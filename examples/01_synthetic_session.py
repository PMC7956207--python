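"""Simulate one oddball sub-trial and preprocess it into classifier epochs.

Builds the 25-button first-level flash schedule (10 rounds, 100 ms flashes,
40 ms ISI), renders a 30-channel EEG recording in which the attended button
'M' evokes a P300-like bump at 350 ms, then band-passes, epochs, and
averages per button.
"""

import numpy as np

from p300gomoku import (
    NoiseModel, average_by_button, bandpass, extract_epochs,
    first_level_sequence, make_erp_template, simulate_session,
)

schedule = first_level_sequence(seed=7)
erp = make_erp_template(latency_ms=350, width_ms=100, amplitude_uV=5.0)
noise = NoiseModel(white_sd_uV=65.0)
session = simulate_session(schedule, attended="M", erp=erp, noise=noise,
                           seed=7)

print(f"flashes: {schedule.n_flashes} (25 buttons x 10 rounds)")
print(f"recording: {session.recording.data.shape[0]} channels x "
      f"{session.recording.n_samples} samples at {session.recording.fs} Hz")

filtered = bandpass(session.recording)          # 0.1-20 Hz, zero phase
epochs = extract_epochs(filtered, session.events)
averaged = average_by_button(epochs, k_rounds=10)

target = next(ep for ep in averaged if ep.button == "M")
others = [ep for ep in averaged if ep.button != "M"]
print(f"epoch matrix: {epochs[0].matrix.shape} (600 ms window, x4 decimation)")
print(f"averaged epochs: {len(averaged)} (one per button)")

# at this (deliberately hard) noise level the raw traces are still noisy;
# what separates the attended button is the time-locked template shape
template = erp.waveform[::4, :].ravel()


def corr(ep):
    return np.corrcoef(ep.matrix.ravel(), template)[0, 1]


print(f"correlation with the clean template, target 'M': {corr(target):.3f}")
print(f"mean correlation, non-targets: "
      f"{np.mean([corr(ep) for ep in others]):.3f}")
print("10-round averaging leaves the attended button's average correlated "
      "with the evoked-response template while non-targets stay near zero.")
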