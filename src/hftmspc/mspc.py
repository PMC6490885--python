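"""Multispectral phase coherence (MSPC) and the phase-locking value.

For an output frequency ``f_sum = sum_r n_r * f_r`` generated by a
nonlinear interaction of input frequencies ``f_r`` with integer weights
``n_r``, the MSPC over K epochs is

    Psi = | (1/K) * sum_k exp(i * (sum_r n_r*phi_I,k(f_r) - phi_O,k(f_sum))) |

i.e. the across-epoch coherence of the difference between the weighted
input phases and the output (intermodulation) phase.  It lies in [0, 1]
and is invariant to any phase offset that is constant across epochs —
in particular to constant neural transmission delays.

Two variants differ only in where the input phases come from:

* ``mspc_stim`` — input phases of the *stimulus* modulations (the SSVEP
  contrast cosine and the SWIFT cycle phase), evaluated at each epoch's
  start time.  Sensitive to interactions locked to the stimulus, i.e.
  occurring early, before variable processing delays accumulate.
* ``mspc_res`` — input phases of the recorded *response* at the
  fundamental frequencies, taken from the same channel's FFT in the same
  epoch.  Sensitive to interactions locked to the (possibly
  latency-jittered) neural responses, i.e. occurring at higher levels.

With constant delays the two are identical; they dissociate exactly when
the response latency varies across epochs.

Everything is computed within-channel: one value per channel, IM
component and variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import Epochs, fft_coeffs
from .stimulus_model import TrialSchedule, stimulus_phase

__all__ = [
    "MSPCSpec",
    "MSPCResult",
    "NullCalibration",
    "mspc",
    "plv",
    "mspc_stim",
    "mspc_res",
    "null_calibrate",
    "rayleigh_null_mean",
]


@dataclass(frozen=True)
class MSPCSpec:
    """Input frequencies, integer weights and variant of one MSPC estimate.

    The generalized form supports any input set — e.g. second harmonics
    ``{2*f1, 2*f2}`` with weights (1, 1), or a second-order IM treated as
    a single input with weight 2 — not only the two fundamentals.
    """

    input_freqs: tuple[float, ...]
    weights: tuple[int, ...]
    variant: str = "stim"  # stim | res

    def __post_init__(self) -> None:
        if len(self.input_freqs) != len(self.weights):
            raise ValueError("one weight per input frequency is required")
        if any(w == 0 for w in self.weights):
            raise ValueError("weights must be non-zero integers")
        if self.variant not in {"stim", "res"}:
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def output_freq(self) -> float:
        return float(sum(n * f for n, f in zip(self.weights, self.input_freqs)))


@dataclass(frozen=True)
class MSPCResult:
    channel: str
    spec: MSPCSpec
    value: float
    K: int
    null_mean: float
    p_null: float
    degenerate: bool = False  # K == 1: the statistic is 1 by construction


def mspc(input_phases, output_phases, weights) -> float:
    """The coherence statistic itself, from per-epoch phases.

    ``input_phases`` is (K, R) — one phase per input frequency per epoch;
    ``output_phases`` is (K,); ``weights`` is (R,) signed integers.
    """
    inp = np.asarray(input_phases, dtype=float)
    out = np.asarray(output_phases, dtype=float)
    w = np.asarray(weights, dtype=float)
    if inp.ndim != 2 or out.ndim != 1 or inp.shape[0] != out.shape[0]:
        raise ValueError("input_phases must be (K, R) and output_phases (K,)")
    if inp.shape[1] != w.shape[0]:
        raise ValueError("phase vectors and weights must have equal length")
    if inp.shape[0] < 1:
        raise ValueError("at least one epoch is required")
    if np.isnan(inp).any() or np.isnan(out).any():
        raise ValueError("NaN phases")
    return float(np.abs(np.exp(1j * (inp @ w - out)).mean()))


def plv(phase_pairs) -> float:
    """Phase-locking value of a per-epoch phase difference.

    Accepts (K, 2) phase pairs (the difference ``a - b`` is taken) or a
    (K,) vector of phase differences.
    """
    p = np.asarray(phase_pairs, dtype=float)
    if p.ndim == 2 and p.shape[1] == 2:
        p = p[:, 0] - p[:, 1]
    if p.ndim != 1 or p.shape[0] < 1:
        raise ValueError("expected (K, 2) phase pairs or (K,) differences")
    if np.isnan(p).any():
        raise ValueError("NaN phases")
    return float(np.abs(np.exp(1j * p).mean()))


def rayleigh_null_mean(K: int) -> float:
    """Expected coherence of K independent uniform phases: sqrt(pi)/(2*sqrt(K))."""
    return float(np.sqrt(np.pi) / (2.0 * np.sqrt(K)))


def _finalize(channel: str, spec: MSPCSpec, value: float, K: int) -> MSPCResult:
    # Rayleigh-test tail probability for the observed coherence
    p = float(np.exp(-K * value**2)) if K > 1 else 1.0
    return MSPCResult(
        channel=channel,
        spec=spec,
        value=value,
        K=K,
        null_mean=rayleigh_null_mean(K),
        p_null=p,
        degenerate=K == 1,
    )


def _output_phases(epochs: Epochs, freq: float) -> np.ndarray:
    _, ph = fft_coeffs(epochs.data, [freq], epochs.fs)
    return ph[..., 0]  # (K, C)


def mspc_stim(epochs: Epochs, schedule: TrialSchedule, spec: MSPCSpec) -> list[MSPCResult]:
    """Stimulus-referenced MSPC, one result per channel.

    Input phases come from the stimulus phase references evaluated at each
    epoch's start; the output phase is the channel's FFT phase at the IM
    frequency within that epoch (also referenced to the epoch start).
    """
    inp = np.column_stack(
        [stimulus_phase(schedule, f, epochs.start_times) for f in spec.input_freqs]
    )  # (K, R)
    out = _output_phases(epochs, spec.output_freq)  # (K, C)
    return [
        _finalize(lab, spec, mspc(inp, out[:, c], spec.weights), epochs.n_epochs)
        for c, lab in enumerate(epochs.channel_labels)
    ]


def mspc_res(epochs: Epochs, spec: MSPCSpec) -> list[MSPCResult]:
    """Response-referenced MSPC, one result per channel.

    Input phases are the same channel's FFT phases at the input
    frequencies, epoch by epoch; everything else as in ``mspc_stim``.
    """
    _, ph_in = fft_coeffs(epochs.data, list(spec.input_freqs), epochs.fs)  # (K, C, R)
    out = _output_phases(epochs, spec.output_freq)  # (K, C)
    return [
        _finalize(lab, spec, mspc(ph_in[:, c, :], out[:, c], spec.weights), epochs.n_epochs)
        for c, lab in enumerate(epochs.channel_labels)
    ]


@dataclass(frozen=True)
class NullCalibration:
    null_mean: float
    threshold_95: float
    rayleigh_mean: float
    K: int
    n_perm: int
    low_n_perm: bool  # warning flag: n_perm < 100


def null_calibrate(
    K: int,
    n_perm: int = 1000,
    rng_seed: int | np.random.Generator = 0,
    input_phases: np.ndarray | None = None,
    output_phases: np.ndarray | None = None,
    weights=None,
) -> NullCalibration:
    """Empirical null of the coherence under independent input/output phases.

    With only ``K`` given, the null is Monte-Carlo: K uniform phases per
    draw.  Given observed ``input_phases``/``output_phases``/``weights``,
    the null is a permutation null that shuffles the epoch pairing between
    the input-phase vectors and the output phases, preserving each
    margin's own structure (including overlap-induced dependence).
    Returns the empirical mean and 95th percentile, alongside the
    closed-form Rayleigh-walk mean sqrt(pi)/(2*sqrt(K)).
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    vals = np.empty(n_perm)
    if input_phases is not None:
        inp = np.asarray(input_phases, dtype=float)
        out = np.asarray(output_phases, dtype=float)
        w = np.asarray(weights, dtype=float)
        combo = inp @ w
        for i in range(n_perm):
            vals[i] = np.abs(np.exp(1j * (combo - rng.permutation(out))).mean())
    else:
        phases = rng.uniform(-np.pi, np.pi, size=(n_perm, K))
        vals = np.abs(np.exp(1j * phases).mean(axis=1))
    return NullCalibration(
        null_mean=float(vals.mean()),
        threshold_95=float(np.quantile(vals, 0.95)),
        rayleigh_mean=rayleigh_null_mean(K),
        K=K,
        n_perm=n_perm,
        low_n_perm=n_perm < 100,
    )
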