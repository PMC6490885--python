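"""Epoching, exact-bin Fourier decomposition and amplitude SNR.

Frequency tagging places every frequency of interest — the two
fundamentals f1 (SWIFT) and f2 (SSVEP), their harmonics, and the
intermodulation (IM) components n1*f1 + n2*f2 — on exact FFT bins of a
suitably chosen analysis window.  All spectral estimates here therefore
use a rectangular window: tapering would only smear tagged energy across
bins.  Off-bin frequency requests are an error, never interpolated.

Amplitudes use the single-sided convention ``2*|X(f)|/N`` so a pure
cosine of amplitude A reads out as A; for zero-padded windows N is the
number of real data samples, which keeps the physical amplitude scale.
Phases are referenced to the segment start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import EEGRecording
from .stimulus_model import TrialSchedule

__all__ = [
    "IMComponent",
    "Epochs",
    "TrialTooShortError",
    "ExactBinError",
    "enumerate_ims",
    "epoch_for_mspc",
    "cycle_grid_samples",
    "trial_fft_window",
    "fft_coeffs",
    "spectral_table",
    "amplitude_snr",
]

_FREQ_TOL = 1e-9


class TrialTooShortError(ValueError):
    """Trial has too little data for the requested spectral window."""


class ExactBinError(ValueError):
    """A requested frequency does not fall on an exact FFT bin."""


@dataclass(frozen=True)
class IMComponent:
    """An intermodulation component ``n1*f1 + n2*f2`` with non-zero weights."""

    n1: int
    n2: int
    f1: float
    f2: float

    def __post_init__(self) -> None:
        if self.n1 == 0 or self.n2 == 0:
            raise ValueError("IM weights must be non-zero (harmonics are not IMs)")

    @property
    def freq(self) -> float:
        return self.n1 * self.f1 + self.n2 * self.f2

    @property
    def order(self) -> int:
        return abs(self.n1) + abs(self.n2)

    @property
    def weights(self) -> tuple[int, int]:
        return (self.n1, self.n2)


def enumerate_ims(
    f1: float,
    f2: float,
    max_order: int = 2,
    return_collisions: bool = False,
):
    """All IM components with 2 <= |n1|+|n2| <= max_order and positive frequency.

    Components are deduplicated by frequency with the lowest order
    retained.  Coincidences — two distinct weight pairs of the same
    (retained) order landing on one frequency — are reported via
    ``return_collisions`` rather than silently dropped.
    """
    if f1 <= 0 or f2 <= 0:
        raise ValueError("fundamental frequencies must be positive")
    if abs(f1 - f2) < _FREQ_TOL:
        raise ValueError("fundamental frequencies must differ")
    if max_order < 2:
        raise ValueError("max_order must be >= 2")

    by_freq: dict[int, IMComponent] = {}
    collisions: list[tuple[IMComponent, IMComponent]] = []
    rng_n = range(-max_order, max_order + 1)
    for n1 in rng_n:
        if n1 == 0:
            continue
        for n2 in rng_n:
            if n2 == 0:
                continue
            comp = IMComponent(n1, n2, f1, f2)
            if not 2 <= comp.order <= max_order:
                continue
            if comp.freq <= _FREQ_TOL:
                continue
            key = round(comp.freq / _FREQ_TOL)
            held = by_freq.get(key)
            if held is None or comp.order < held.order:
                by_freq[key] = comp
            elif comp.order == held.order and comp.weights != held.weights:
                collisions.append((held, comp))
    out = sorted(by_freq.values(), key=lambda c: c.freq)
    if return_collisions:
        return out, collisions
    return out


@dataclass(frozen=True)
class Epochs:
    """Sliding within-trial analysis epochs.

    ``data`` has shape (n_epochs, n_channels, epoch_samples);
    ``start_times`` are the epoch onsets in trial time (seconds), which is
    the time reference of each epoch's FFT phases.
    """

    data: np.ndarray
    fs: float
    start_times: np.ndarray
    epoch_len: float
    channel_labels: list[str]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


def cycle_grid_samples(schedule: TrialSchedule, fs: float, n_samples: int,
                       swift_freq: float | None = None) -> list[tuple[int, int]]:
    """Sample ranges of the SWIFT cycles of one stream (default: slowest)."""
    if swift_freq is None:
        swift_freq = schedule.swift_freqs[0]
    grid = []
    for c in schedule.stream(swift_freq):
        a = int(round(c.onset * fs))
        b = int(round((c.onset + 1.0 / c.swift_freq) * fs))
        if a < n_samples:
            grid.append((a, min(b, n_samples)))
    return grid


def epoch_for_mspc(
    recording: EEGRecording,
    schedule: TrialSchedule,
    epoch_len: float,
    step: float = 1.0,
    analysis_freqs: list[float] | None = None,
) -> Epochs:
    """Cut overlapping epochs for phase-coherence analysis.

    The first SWIFT cycle is excluded (onset transients); epochs of
    ``epoch_len`` seconds then start every ``step`` seconds.  Every
    analysis frequency must complete an integer number of cycles per
    epoch (the exact-bin condition); offenders are reported together.
    """
    if analysis_freqs:
        bad = [f for f in analysis_freqs if abs(f * epoch_len - round(f * epoch_len)) > _FREQ_TOL]
        if bad:
            raise ExactBinError(
                f"epoch length {epoch_len} s puts frequencies {bad} Hz off the FFT bin grid"
            )
    fs = recording.fs
    # drop the first SWIFT cycle; with several streams, the fastest one
    # defines the discarded interval
    t0 = 1.0 / max(schedule.swift_freqs)
    start0 = int(round(t0 * fs))
    epoch_samples = int(round(epoch_len * fs))
    step_samples = int(round(step * fs))
    n_avail = recording.n_samples - start0
    if n_avail < epoch_samples:
        raise TrialTooShortError(
            f"{n_avail / fs:.2f} s available after dropping the first SWIFT cycle; "
            f"need {epoch_len} s"
        )
    n_epochs = (n_avail - epoch_samples) // step_samples + 1
    starts = start0 + step_samples * np.arange(n_epochs)
    data = np.stack([recording.data[:, s:s + epoch_samples] for s in starts])
    return Epochs(
        data=data,
        fs=fs,
        start_times=starts / fs,
        epoch_len=epoch_len,
        channel_labels=list(recording.channel_labels),
    )


def trial_fft_window(
    data: np.ndarray,
    fs: float = 500.0,
    mode: str = "exp1",
) -> tuple[np.ndarray, int, float]:
    """Select and (for short/variable trials) zero-pad the whole-trial FFT window.

    Returns ``(segment, n_data, bin_width)`` where ``n_data`` is the number
    of real (non-padded) samples and ``bin_width`` the resulting FFT bin
    spacing (the half-bandwidth).

    ``mode='exp1'`` (variable-length trials): more than 17 s of data is
    zero-padded to 20 s (0.05 Hz bins); 10-17 s keeps the first 10 s
    (0.1 Hz bins); under 10 s is refused.  ``mode='exp2'`` (fixed 31.5 s
    trials): the fixed 3-28 s window, 25 s = 12,500 samples at 500 Hz
    (0.04 Hz bins).
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n = data.shape[1]
    dur = n / fs
    if mode == "exp1":
        if dur > 17.0:
            n_pad = int(round(20.0 * fs))
            if n > n_pad:
                raise ValueError("more than 20 s of data in a variable-length trial")
            seg = np.pad(data, ((0, 0), (0, n_pad - n)))
            return seg, n, 1.0 / 20.0
        if dur >= 10.0:
            n10 = int(round(10.0 * fs))
            return data[:, :n10], n10, 1.0 / 10.0
        raise TrialTooShortError(f"only {dur:.2f} s of data (< 10 s)")
    if mode == "exp2":
        a = int(round(3.0 * fs))
        b = int(round(28.0 * fs))
        if n < b:
            raise TrialTooShortError(f"{dur:.2f} s of data; the 3-28 s window needs 28 s")
        return data[:, a:b], b - a, 1.0 / 25.0
    raise ValueError(f"unknown mode {mode!r}")


def fft_coeffs(
    segment: np.ndarray,
    freqs: list[float],
    fs: float,
    n_data: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude and phase at exact-bin frequencies (rectangular window).

    ``segment`` is (..., n_samples); returns ``(amplitude, phase)`` arrays
    of shape (..., n_freqs).  Amplitude is ``2*|X(f)|/n_data``; phase is
    ``arg X(f)`` in (-pi, pi], referenced to the segment start.
    """
    segment = np.asarray(segment, dtype=float)
    n = segment.shape[-1]
    if n_data is None:
        n_data = n
    idx = []
    for f in freqs:
        k = f * n / fs
        if abs(k - round(k)) > 1e-6:
            raise ExactBinError(f"{f} Hz is not an exact bin of a {n}-sample window at {fs} Hz")
        k = int(round(k))
        if not 0 <= k <= n // 2:
            raise ValueError(f"{f} Hz outside the spectrum")
        idx.append(k)
    X = np.fft.rfft(segment, axis=-1)[..., idx]
    return 2.0 * np.abs(X) / n_data, np.angle(X)


def spectral_table(epochs: Epochs, freqs: list[float]) -> pd.DataFrame:
    """Long-format per-epoch spectral estimates at the requested frequencies."""
    amp, ph = fft_coeffs(epochs.data, freqs, epochs.fs)
    k, c, f = np.meshgrid(
        np.arange(epochs.n_epochs), np.arange(epochs.n_channels), np.arange(len(freqs)),
        indexing="ij",
    )
    return pd.DataFrame(
        {
            "epoch": k.ravel(),
            "channel": np.asarray(epochs.channel_labels)[c.ravel()],
            "freq": np.asarray(freqs)[f.ravel()],
            "amplitude": amp.ravel(),
            "phase": ph.ravel(),
        }
    )


@dataclass(frozen=True)
class SNRResult:
    value: float
    n_neighbours: int
    flagged: bool  # no usable neighbours, or zero neighbour mean


def amplitude_snr(
    freqs: np.ndarray,
    amplitudes: np.ndarray,
    f: float,
    n_side: int,
    protected: tuple[float, ...] = (),
) -> SNRResult:
    """Amplitude SNR: amplitude at ``f`` over the mean of its neighbours.

    ``freqs``/``amplitudes`` describe the full (regularly spaced) amplitude
    spectrum.  ``n_side`` bins on each side of ``f`` enter the mean; any
    neighbour within half a bin of a protected frequency (harmonics, other
    IMs) is removed from the calculation.  An empty neighbour set or a zero
    neighbour mean is flagged, never silent.
    """
    freqs = np.asarray(freqs, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    df = np.median(np.diff(freqs))
    k = int(round((f - freqs[0]) / df))
    if not 0 <= k < len(freqs) or abs(freqs[k] - f) > 1e-6:
        raise ExactBinError(f"{f} Hz is not a bin of the supplied spectrum")
    neighbours = [k + d for d in range(-n_side, n_side + 1) if d != 0]
    neighbours = [j for j in neighbours if 0 <= j < len(freqs)]
    neighbours = [
        j for j in neighbours
        if not any(abs(freqs[j] - p) < df / 2 for p in protected)
    ]
    if not neighbours:
        return SNRResult(value=np.nan, n_neighbours=0, flagged=True)
    denom = amplitudes[neighbours].mean()
    if denom == 0:
        return SNRResult(value=np.inf, n_neighbours=len(neighbours), flagged=True)
    return SNRResult(value=amplitudes[k] / denom, n_neighbours=len(neighbours), flagged=False)


def protected_frequencies(
    f1: float,
    f2: float,
    nyquist: float,
    im_max_order: int = 4,
) -> tuple[float, ...]:
    """Harmonics of both fundamentals up to Nyquist plus IMs up to order 4,
    the default exclusion set for SNR neighbour means."""
    out = set()
    for f in (f1, f2):
        h = f
        while h <= nyquist:
            out.add(round(h, 9))
            h += f
    for comp in enumerate_ims(f1, f2, max_order=im_max_order):
        if comp.freq <= nyquist:
            out.add(round(comp.freq, 9))
    return tuple(sorted(out))
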