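"""Amplitude SNR spectrum of a simulated trial.

SNR at a frequency is its amplitude over the mean amplitude of the
neighbouring FFT bins, with other tagged/harmonic/IM bins excluded from
the neighbourhood.  Frequency tagging shows up as sharp SNR peaks at the
fundamentals, their harmonics, and — when the tagged signals interact
nonlinearly — at the intermodulation frequencies.
"""

import numpy as np

from hftmspc import simulate_trial
from hftmspc.pipeline import default_study_params
from hftmspc.spectral import (
    amplitude_snr,
    enumerate_ims,
    protected_frequencies,
    trial_fft_window,
)
from hftmspc.stimulus_model import build_exp1_schedule

schedule = build_exp1_schedule("FHHFFH", task="PV", n_cycles=21, violation_index=17)
# constant latency (no jitter) so the 15 Hz peak is not smeared into sidebands
params = default_study_params("stim_locked", gain=0.5, jitter_sd=0.0)  # noise RMS 1.1 uV
ds = simulate_trial(schedule, params, rng_seed=0)

segment, n_data, bw = trial_fft_window(ds.recording.data, fs=500.0, mode="exp1")
freqs = np.fft.rfftfreq(segment.shape[1], 1 / 500.0)
amps = (2.0 * np.abs(np.fft.rfft(segment, axis=1)) / n_data).mean(axis=0)
protected = protected_frequencies(1.2, 15.0, nyquist=250.0)

print(f"window: {segment.shape[1] / 500.0:.0f} s (half-bandwidth {bw} Hz)")
targets = [("SWIFT f1", 1.2), ("harmonic 2f1", 2.4), ("SSVEP f2", 15.0)]
targets += [(f"IM {c.n1:+d}f1{c.n2:+d}f2", c.freq) for c in enumerate_ims(1.2, 15.0, 2)]
for name, f in targets:
    snr = amplitude_snr(freqs, amps, f, n_side=8, protected=protected)
    print(f"  {name:14s} {f:6.2f} Hz   SNR = {snr.value:5.1f}  ({snr.n_neighbours} neighbours)")
# SNR >> 1 at the tagged frequencies and their intermodulation components;
# an SNR near 1 would mean the bin is indistinguishable from background.
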