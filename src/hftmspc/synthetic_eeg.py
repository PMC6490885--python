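"""Synthetic multichannel EEG with ground-truthed nonlinear integration.

The generator emulates the statistical structure that the frequency-
tagging analysis assumes, via a two-level cascade:

* a SWIFT drive ``s1`` (cosine at the cycle frequency plus harmonics,
  phase-locked to the stimulus) and an SSVEP drive ``s2`` (cosine at the
  contrast-modulation frequency);
* a *stimulus-locked* ("low-level") interaction ``g_low * s1 * s2``
  evaluated at a fixed latency ``tau_low`` — its intermodulation phase is
  rigidly tied to the stimulus phases;
* *response-level* drives ``r1, r2``: the same drives delayed by
  ``tau_low + delta_e``, where ``delta_e ~ N(0, tau_jitter_sd^2)`` is a
  response latency resampled once per analysis-epoch-length block — the
  minimal mechanism by which stimulus- and response-referenced phase
  coherence dissociate;
* a *response-locked* ("high-level") interaction ``g_high * r1 * r2``;
* the measured fundamentals are emitted from the response level, so the
  response-referenced coherence sees the jittered phases;
* independent 1/f^alpha background noise per channel.

With ``tau_jitter_sd = 0`` every delay is constant and the two coherence
variants agree exactly; with jitter, a stimulus-locked interaction keeps
the stimulus-referenced variant high while the jittered fundamentals
destroy the response-referenced one, and a response-locked interaction
does the reverse (its IM phase jitters coherently with the fundamentals).

Artifacts (voltage spikes, steps, drifts) can be injected at known
positions to exercise the rejection rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import EEGRecording
from .stimulus_model import TrialSchedule, stimulus_phase

__all__ = [
    "CascadeParams",
    "SyntheticDataset",
    "simulate_trial",
    "inject_artifacts",
    "pink_noise",
    "DEFAULT_CHANNELS",
]

def _unit(p: tuple[float, float, float]) -> tuple[float, float, float]:
    v = np.asarray(p, dtype=float)
    v = v / np.linalg.norm(v)
    return tuple(v)


#: default synthetic montage: the 17-electrode posterior set (occipital,
#: parieto-occipital, parietal) with approximate unit-sphere positions
#: (x right, y front, z up)
DEFAULT_CHANNELS: dict[str, tuple[float, float, float]] = {
    "Oz": _unit((0.00, -1.00, 0.05)),
    "O1": _unit((-0.31, -0.95, 0.05)),
    "O2": _unit((0.31, -0.95, 0.05)),
    "POz": _unit((0.00, -0.88, 0.48)),
    "PO3": _unit((-0.34, -0.85, 0.40)),
    "PO4": _unit((0.34, -0.85, 0.40)),
    "PO7": _unit((-0.59, -0.78, 0.20)),
    "PO8": _unit((0.59, -0.78, 0.20)),
    "Pz": _unit((0.00, -0.66, 0.75)),
    "P1": _unit((-0.26, -0.65, 0.70)),
    "P2": _unit((0.26, -0.65, 0.70)),
    "P3": _unit((-0.50, -0.62, 0.60)),
    "P4": _unit((0.50, -0.62, 0.60)),
    "P5": _unit((-0.67, -0.59, 0.45)),
    "P6": _unit((0.67, -0.59, 0.45)),
    "P7": _unit((-0.81, -0.55, 0.20)),
    "P8": _unit((0.81, -0.55, 0.20)),
}


@dataclass(frozen=True)
class CascadeParams:
    """Parameters of the two-level interaction cascade.

    Amplitudes and gains are in uV; latencies in seconds.  ``channel_gains``
    optionally maps each source ("fund_low", "fund_high", "im_low",
    "im_high", i.e. SSVEP fundamental, SWIFT fundamental, stimulus-locked
    IM, response-locked IM) to a per-channel gain vector; by default every
    channel receives every source with gain 1.
    """

    amp_f1: float = 1.0          # SWIFT-response fundamental amplitude
    amp_f2: float = 1.0          # SSVEP fundamental amplitude
    n_harmonics: int = 2         # harmonics of the SWIFT drive
    harmonic_decay: float = 0.5  # amplitude ratio between successive harmonics
    g_low: float = 0.0           # stimulus-locked interaction gain
    g_high: float = 0.0          # response-locked interaction gain
    tau_low: float = 0.08        # fixed transmission latency (s)
    tau_jitter_sd: float = 0.0   # SD of the per-block response latency (s)
    jitter_block_s: float = 5.0  # latency resampling block (the analysis epoch length)
    jitter_block_offset_s: float = 0.0  # start of the first block (align to epoch grid)
    noise_alpha: float = 1.0     # 1/f^alpha exponent
    noise_level: float = 0.0     # background noise RMS (uV)
    fs: float = 500.0
    channels: tuple[str, ...] = tuple(DEFAULT_CHANNELS)
    channel_gains: dict | None = None

    def __post_init__(self) -> None:
        if self.noise_level < 0:
            raise ValueError("noise level must be >= 0")
        if self.tau_jitter_sd < 0:
            raise ValueError("latency jitter SD must be >= 0")
        if min(self.amp_f1, self.amp_f2, self.g_low, self.g_high) < 0:
            raise ValueError("amplitudes and gains must be >= 0")
        if self.fs <= 0 or self.jitter_block_s <= 0 or self.n_harmonics < 1:
            raise ValueError("fs, jitter_block_s and n_harmonics must be positive")

    def gains(self, source: str) -> np.ndarray:
        n = len(self.channels)
        if self.channel_gains and source in self.channel_gains:
            g = np.asarray(self.channel_gains[source], dtype=float)
            if g.shape != (n,):
                raise ValueError(f"gain vector for {source!r} must have length {n}")
            return g
        return np.ones(n)


@dataclass
class SyntheticDataset:
    """A simulated recording with its schedule and ground-truth labels."""

    recording: EEGRecording
    schedule: TrialSchedule
    truth: dict
    params: CascadeParams

    def __post_init__(self) -> None:
        for ch, s, _kind in self.truth.get("artifacts", []):
            if not (0 <= ch < self.recording.n_channels and 0 <= s < self.recording.n_samples):
                raise ValueError(f"artifact position ({ch}, {s}) outside the recording")


def pink_noise(
    n: int,
    rng: np.random.Generator,
    alpha: float = 1.0,
    rms: float = 1.0,
    size: int | None = None,
) -> np.ndarray:
    """Zero-mean 1/f^alpha noise of the requested RMS (independent rows)."""
    shape = (size, n) if size is not None else (n,)
    white = rng.standard_normal(shape)
    X = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-alpha / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(X * scale, n=n, axis=-1)
    x -= x.mean(axis=-1, keepdims=True)
    cur = x.std(axis=-1, keepdims=True)
    cur[cur == 0] = 1.0
    return x / cur * rms


def _check_fs(params: CascadeParams, schedule: TrialSchedule) -> None:
    f_max = max(
        schedule.ssvep_freq + params.n_harmonics * max(schedule.swift_freqs),
        2 * schedule.ssvep_freq,
    )
    if params.fs <= 2 * f_max:
        raise ValueError(f"fs = {params.fs} Hz cannot represent components up to {f_max} Hz")


def simulate_trial(
    schedule: TrialSchedule,
    params: CascadeParams,
    rng_seed: int | np.random.Generator = 0,
) -> SyntheticDataset:
    """Simulate one trial of the interaction cascade on a trial schedule.

    Every SWIFT stream in the schedule contributes its own drive and its
    own interactions with the SSVEP drive.  Sources sum per channel
    (weighted by the per-source channel gains) with independent 1/f
    noise.  Identical seeds give bit-identical recordings.
    """
    _check_fs(params, schedule)
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    fs = params.fs
    n = int(round(schedule.duration * fs))
    t = np.arange(n) / fs

    # block-constant response latency: tau_low + delta, delta resampled
    # every jitter block (one analysis epoch length)
    n_blocks = int(np.ceil(schedule.duration / params.jitter_block_s)) + 1
    delta = rng.normal(0.0, params.tau_jitter_sd, size=n_blocks) if params.tau_jitter_sd > 0 else np.zeros(n_blocks)
    block_of_t = np.clip(
        np.floor((t - params.jitter_block_offset_s) / params.jitter_block_s).astype(int) + 1,
        0, n_blocks - 1,
    )
    t_resp = t - params.tau_low - delta[block_of_t]
    t_low = t - params.tau_low

    def swift_drive(freq: float, times: np.ndarray) -> np.ndarray:
        ph = stimulus_phase(schedule, freq, times)
        out = np.zeros_like(times)
        for h in range(1, params.n_harmonics + 1):
            out += params.harmonic_decay ** (h - 1) * np.cos(h * ph)
        return out

    ssvep_low = np.cos(stimulus_phase(schedule, schedule.ssvep_freq, t_low))
    ssvep_resp = np.cos(stimulus_phase(schedule, schedule.ssvep_freq, t_resp))

    fund_high = np.zeros(n)   # SWIFT fundamentals (response level)
    im_low = np.zeros(n)
    im_high = np.zeros(n)
    for f_swift in schedule.swift_freqs:
        s1_low = swift_drive(f_swift, t_low)
        s1_resp = swift_drive(f_swift, t_resp)
        fund_high += params.amp_f1 * s1_resp
        im_low += params.g_low * s1_low * ssvep_low
        im_high += params.g_high * s1_resp * ssvep_resp

    sources = {
        "fund_high": fund_high,
        "fund_low": params.amp_f2 * ssvep_resp,  # SSVEP fundamental, emitted at response level
        "im_low": im_low,
        "im_high": im_high,
    }
    data = np.zeros((len(params.channels), n))
    for name, src in sources.items():
        data += params.gains(name)[:, None] * src[None, :]
    if params.noise_level > 0:
        data += pink_noise(n, rng, params.noise_alpha, params.noise_level, size=len(params.channels))

    labels = []
    g_im_low = params.g_low * params.gains("im_low")
    g_im_high = params.g_high * params.gains("im_high")
    for lo, hi in zip(g_im_low, g_im_high):
        if lo == 0 and hi == 0:
            labels.append("none")
        else:
            labels.append("stim_locked" if lo >= hi else "response_locked")

    positions = np.array([DEFAULT_CHANNELS.get(ch, (0.0, 0.0, 1.0)) for ch in params.channels])
    recording = EEGRecording(
        data=data,
        fs=fs,
        channel_labels=list(params.channels),
        channel_positions=positions,
        events=[(0, "trial_start")],
    )
    truth = {"mechanism": labels, "latency_jitter": delta, "artifacts": []}
    return SyntheticDataset(recording=recording, schedule=schedule, truth=truth, params=params)


def inject_artifacts(
    recording: EEGRecording,
    spec: list[tuple[int, int, str]],
) -> EEGRecording:
    """Inject artifacts at (channel, sample, kind) positions.

    ``spike80`` sets one sample to +85 uV (beyond the +/-80 uV amplitude
    criterion); ``jump30`` adds a 35 uV step from the sample onward (one
    adjacent-sample difference beyond the 30 uV jump criterion); ``drift``
    adds a linear ramp from the sample to the end of the recording rising
    to 6 channel-SDs (crossing the 5 SD criterion).
    """
    out = recording.copy()
    for ch, s, kind in spec:
        if not (0 <= ch < out.n_channels and 0 <= s < out.n_samples):
            raise IndexError(f"artifact position ({ch}, {s}) outside the recording")
        if kind == "spike80":
            out.data[ch, s] = 85.0
        elif kind == "jump30":
            out.data[ch, s:] += 35.0
        elif kind == "drift":
            sd = recording.data[ch].std()
            ramp = np.linspace(0.0, 6.0 * max(sd, 1.0), out.n_samples - s)
            out.data[ch, s:] += ramp
        else:
            raise ValueError(f"unknown artifact kind {kind!r}")
    return out
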