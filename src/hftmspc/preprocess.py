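"""Preprocessing and data-quality rules for multichannel EEG.

The pipeline standardises recordings (resample to 500 Hz, zero-phase
0.3 Hz high-pass, average reference) and applies per-sample noise
criteria, cycle/channel/trial/participant exclusion rules and bad-channel
interpolation.  Thresholds follow common practice for steady-state
paradigms: a sample is noisy if its absolute voltage exceeds 80 uV, if it
jumps more than 30 uV from the previous sample, or if it lies more than
5 SD from the channel's trial mean; a SWIFT cycle is noisy if more than
2% of its samples are noisy; a channel is bad if more than 10% of its
cycles are noisy; a trial is excluded if more than 10% of channels are
bad; a participant is excluded with more than 20% bad trials or more than
30% behaviourally invalid trials.

Interpolation of bad channels uses inverse-distance weighting over the
nearest good electrodes.  Line-noise removal is available as an optional
notch filter and is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal

__all__ = [
    "EEGRecording",
    "NoiseReport",
    "TrialQC",
    "ExclusionReport",
    "standardize",
    "notch_line_noise",
    "flag_noise",
    "interpolate_bad_channels",
    "apply_exclusions",
]

AMP_THRESHOLD_UV = 80.0
JUMP_THRESHOLD_UV = 30.0
SD_THRESHOLD = 5.0
NOISY_CYCLE_FRACTION = 0.02
BAD_CHANNEL_CYCLE_FRACTION = 0.10
BAD_TRIAL_CHANNEL_FRACTION = 0.10
EXCLUDE_PARTICIPANT_TRIAL_FRACTION = 0.20
COUNT_TOLERANCE = 3
EXCLUDE_PARTICIPANT_INVALID_FRACTION = 0.30


@dataclass
class EEGRecording:
    """Channels x samples voltage matrix (uV) with sampling metadata."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    channel_positions: np.ndarray | None = None  # (n_channels, 3), unit sphere
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel row is required")
        if self.channel_positions is not None:
            self.channel_positions = np.asarray(self.channel_positions, dtype=float)
            if self.channel_positions.shape != (self.data.shape[0], 3):
                raise ValueError("channel_positions must be (n_channels, 3)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "EEGRecording":
        return EEGRecording(
            data=self.data.copy(),
            fs=self.fs,
            channel_labels=list(self.channel_labels),
            channel_positions=None if self.channel_positions is None else self.channel_positions.copy(),
            events=list(self.events),
        )


@dataclass
class NoiseReport:
    """Outcome of the per-sample/cycle/channel noise criteria."""

    noisy_sample_mask: np.ndarray  # (n_channels, n_samples) bool
    noisy_cycles: np.ndarray  # (n_channels, n_cycles) bool
    noisy_cycle_fraction: np.ndarray  # (n_channels,)
    bad_channels: list[str]
    channel_labels: list[str]

    @property
    def n_bad_channels(self) -> int:
        return len(self.bad_channels)


def standardize(
    recording: EEGRecording,
    target_fs: float = 500.0,
    highpass_hz: float = 0.3,
    order: int = 4,
) -> EEGRecording:
    """Resample to 500 Hz, zero-phase high-pass at 0.3 Hz, average reference.

    The high-pass is a 4th-order Butterworth applied forward-backward.
    Recordings below the target rate are refused rather than upsampled.
    """
    if recording.fs < target_fs:
        raise ValueError(
            f"recording sampled at {recording.fs} Hz; refusing to upsample to {target_fs} Hz"
        )
    data = recording.data
    events = list(recording.events)
    fs = recording.fs
    if fs != target_fs:
        frac = Fraction(target_fs / fs).limit_denominator(10000)
        data = signal.resample_poly(data, frac.numerator, frac.denominator, axis=1)
        events = [(int(round(s * target_fs / fs)), lab) for s, lab in events]
        fs = target_fs
    sos = signal.butter(order, highpass_hz, btype="highpass", fs=fs, output="sos")
    # a 0.3 Hz high-pass settles over tens of seconds; pad far beyond the
    # sosfiltfilt default so edge transients decay below numerical noise
    padlen = min(data.shape[1] - 1, int(round(30.0 * fs)))
    data = signal.sosfiltfilt(sos, data, axis=1, padlen=padlen)
    data = data - data.mean(axis=0, keepdims=True)
    if np.isnan(data).any():
        raise ValueError("preprocessing produced NaNs")
    return EEGRecording(
        data=data,
        fs=fs,
        channel_labels=list(recording.channel_labels),
        channel_positions=recording.channel_positions,
        events=events,
    )


def notch_line_noise(recording: EEGRecording, line_hz: float = 50.0, q: float = 35.0,
                     harmonics: int = 2) -> EEGRecording:
    """Optional zero-phase notch at the mains frequency and its harmonics.

    Off the default path: synthetic recordings carry no mains component,
    and on real data a dedicated sinusoid-regression tool may be preferred.
    """
    out = recording.copy()
    for h in range(1, harmonics + 1):
        b, a = signal.iirnotch(line_hz * h, q, fs=recording.fs)
        out.data = signal.filtfilt(b, a, out.data, axis=1)
    return out


def flag_noise(
    recording: EEGRecording,
    cycle_grid: list[tuple[int, int]],
    amp_threshold: float = AMP_THRESHOLD_UV,
    jump_threshold: float = JUMP_THRESHOLD_UV,
    sd_threshold: float = SD_THRESHOLD,
    noisy_cycle_fraction: float = NOISY_CYCLE_FRACTION,
    bad_channel_cycle_fraction: float = BAD_CHANNEL_CYCLE_FRACTION,
) -> NoiseReport:
    """Flag noisy samples, cycles and channels.

    ``cycle_grid`` lists half-open sample ranges ``(start, stop)``
    partitioning the trial into SWIFT cycles.  A sample is noisy if any of
    the three criteria fires in its channel (|x| > 80 uV; |jump from the
    previous sample| > 30 uV; |x - channel mean| > 5 channel SD, both
    computed over the whole trial).  A cycle is noisy if strictly more than
    2% of its samples are noisy; a channel is bad if noisy in strictly more
    than 10% of cycles.
    """
    if not cycle_grid:
        raise ValueError("cycle grid is empty")
    x = recording.data
    mask = np.abs(x) > amp_threshold
    mask[:, 1:] |= np.abs(np.diff(x, axis=1)) > jump_threshold
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    mask |= np.abs(x - mean) > sd_threshold * sd

    n_cycles = len(cycle_grid)
    noisy_cycles = np.zeros((recording.n_channels, n_cycles), dtype=bool)
    for j, (a, b) in enumerate(cycle_grid):
        if not 0 <= a < b <= recording.n_samples:
            raise ValueError(f"cycle ({a}, {b}) outside the recording")
        frac = mask[:, a:b].mean(axis=1)
        noisy_cycles[:, j] = frac > noisy_cycle_fraction

    cycle_fraction = noisy_cycles.mean(axis=1)
    bad = cycle_fraction > bad_channel_cycle_fraction
    return NoiseReport(
        noisy_sample_mask=mask,
        noisy_cycles=noisy_cycles,
        noisy_cycle_fraction=cycle_fraction,
        bad_channels=[lab for lab, b in zip(recording.channel_labels, bad) if b],
        channel_labels=list(recording.channel_labels),
    )


def interpolate_bad_channels(
    recording: EEGRecording,
    bad: list[str],
    k: int = 4,
) -> EEGRecording:
    """Replace bad channels by the inverse-distance-weighted mean of the
    ``k`` nearest good channels (by electrode position)."""
    if not bad:
        return recording.copy()
    if recording.channel_positions is None:
        raise ValueError("channel positions are required for interpolation")
    unknown = [lab for lab in bad if lab not in recording.channel_labels]
    if unknown:
        raise ValueError(f"unknown channels: {unknown}")
    bad_idx = [recording.channel_labels.index(lab) for lab in bad]
    good_idx = [i for i in range(recording.n_channels) if i not in set(bad_idx)]
    if len(bad_idx) > recording.n_channels / 2:
        raise ValueError("more than half the channels are bad; refusing to interpolate")
    out = recording.copy()
    pos = recording.channel_positions
    for bi in bad_idx:
        d = np.linalg.norm(pos[good_idx] - pos[bi], axis=1)
        nearest = np.argsort(d)[: min(k, len(good_idx))]
        dn = d[nearest]
        if np.any(dn == 0):
            w = (dn == 0).astype(float)
        else:
            w = 1.0 / dn
        w /= w.sum()
        src = np.asarray(good_idx)[nearest]
        out.data[bi] = w @ recording.data[src]
    return out


@dataclass(frozen=True)
class TrialQC:
    """Per-trial quality and behaviour summary feeding the exclusion rules.

    Behaviour is described by whichever fields apply: expectation-paradigm
    trials carry ``pressed``/``press_time``/``target_time`` (a valid
    response is a press at or after target appearance); counting-paradigm
    trials carry ``reported_count``/``true_count`` (valid within +/-3).
    Trials with no behavioural fields are treated as valid.
    """

    participant: str
    trial_id: str
    n_channels: int
    n_bad_channels: int
    pressed: bool | None = None
    press_time: float | None = None
    target_time: float | None = None
    reported_count: int | None = None
    true_count: int | None = None


@dataclass
class ExclusionReport:
    bad_trials: list[str]
    invalid_response_trials: list[str]
    excluded_participants: dict[str, str]  # participant -> reason


def _response_valid(t: TrialQC) -> bool:
    if t.reported_count is not None and t.true_count is not None:
        return abs(t.reported_count - t.true_count) <= COUNT_TOLERANCE
    if t.pressed is not None:
        if not t.pressed:
            return False
        if t.press_time is not None and t.target_time is not None:
            return t.press_time >= t.target_time
        return True
    return True


def apply_exclusions(trials: list[TrialQC]) -> ExclusionReport:
    """Apply the trial- and participant-level exclusion rules.

    A trial is bad if strictly more than 10% of its channels are bad.  A
    participant is excluded with strictly more than 20% bad trials, or with
    strictly more than 30% behaviourally invalid trials.
    """
    bad_trials = [t.trial_id for t in trials if t.n_bad_channels > BAD_TRIAL_CHANNEL_FRACTION * t.n_channels]
    invalid = [t.trial_id for t in trials if not _response_valid(t)]
    participants = sorted({t.participant for t in trials})
    excluded: dict[str, str] = {}
    bad_set, invalid_set = set(bad_trials), set(invalid)
    for p in participants:
        own = [t for t in trials if t.participant == p]
        n = len(own)
        n_bad = sum(1 for t in own if t.trial_id in bad_set)
        n_invalid = sum(1 for t in own if t.trial_id in invalid_set)
        if n_bad > EXCLUDE_PARTICIPANT_TRIAL_FRACTION * n:
            excluded[p] = f"bad EEG in {n_bad}/{n} trials"
        elif n_invalid > EXCLUDE_PARTICIPANT_INVALID_FRACTION * n:
            excluded[p] = f"invalid responses in {n_invalid}/{n} trials"
    return ExclusionReport(
        bad_trials=bad_trials,
        invalid_response_trials=invalid,
        excluded_participants=excluded,
    )
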