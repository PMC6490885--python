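"""End-to-end conveniences: trial-level MSPC tables and simulated studies.

These functions wire the modules together the way an analysis would:
simulate (or accept) a recording, cut sliding epochs, compute both MSPC
variants for the second-order IM components of every SWIFT stream, and
stack the per-channel values into long-format tables ready for the
group-level models.

The simulated "study" reproduces the two study designs on ground-truthed
data: an expectation-style design in which the condition modulates the
stimulus-locked interaction gain, and an attention-style design in which
it modulates the response-locked gain under latency jitter.  Defaults are
chosen so a single trial carries a realistic tagged-fundamental SNR of
about 5 and clearly separable coherence values.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .group_stats import LRTResult, ROIDefinition, lrt_contrast, roi_aggregate
from .mspc import MSPCSpec, mspc_res, mspc_stim
from .preprocess import EEGRecording
from .spectral import Epochs, epoch_for_mspc
from .stimulus_model import TrialSchedule, build_exp1_schedule
from .synthetic_eeg import CascadeParams, simulate_trial

__all__ = [
    "epoch_grid_offset",
    "second_order_specs",
    "trial_mspc_table",
    "default_study_params",
    "simulate_study",
    "study_contrast",
    "STUDY_GAIN_HIGH",
    "STUDY_GAIN_LOW",
    "STUDY_NOISE_LEVEL",
    "STUDY_JITTER_SD",
]

#: interaction gain (uV) in the condition that enhances integration
STUDY_GAIN_HIGH = 0.5
#: interaction gain (uV) in the condition that does not
STUDY_GAIN_LOW = 0.2
#: background 1/f noise RMS (uV) giving tagged-fundamental SNR ~ 5
STUDY_NOISE_LEVEL = 1.1
#: response-latency jitter SD (s); latency variability across epochs
STUDY_JITTER_SD = 0.08


def second_order_specs(f1: float, f2: float, variant: str) -> list[MSPCSpec]:
    """The two second-order IM specs (f2 - f1 and f2 + f1) on one stream."""
    return [
        MSPCSpec(input_freqs=(f1, f2), weights=(-1, 1), variant=variant),
        MSPCSpec(input_freqs=(f1, f2), weights=(1, 1), variant=variant),
    ]


def trial_mspc_table(
    recording: EEGRecording,
    schedule: TrialSchedule,
    epoch_len: float = 5.0,
    step: float = 1.0,
    variants: tuple[str, ...] = ("stim", "res"),
) -> pd.DataFrame:
    """Both MSPC variants at the second-order IMs of every SWIFT stream.

    Returns a long-format table (channel, variant, n1, n2, freq, value, K,
    null_mean, p_null), one row per channel x IM x variant.
    """
    f2 = schedule.ssvep_freq
    all_specs = [
        spec
        for f1 in schedule.swift_freqs
        for variant in variants
        for spec in second_order_specs(f1, f2, variant)
    ]
    freqs = sorted({f for s in all_specs for f in (*s.input_freqs, s.output_freq)})
    epochs = epoch_for_mspc(recording, schedule, epoch_len, step, analysis_freqs=freqs)
    rows = []
    for spec in all_specs:
        results = (
            mspc_stim(epochs, schedule, spec) if spec.variant == "stim" else mspc_res(epochs, spec)
        )
        for r in results:
            rows.append(
                {
                    "channel": r.channel,
                    "variant": spec.variant,
                    "n1": spec.weights[0],
                    "n2": spec.weights[1],
                    "swift_freq": spec.input_freqs[0],
                    "freq": spec.output_freq,
                    "value": r.value,
                    "K": r.K,
                    "null_mean": r.null_mean,
                    "p_null": r.p_null,
                }
            )
    return pd.DataFrame(rows)


def epoch_grid_offset(schedule: TrialSchedule, fs: float = 500.0) -> float:
    """Start time of the first analysis epoch (first SWIFT cycle dropped,
    rounded to the sample grid) — used to align the generator's latency
    blocks with the analysis epochs."""
    return round((1.0 / max(schedule.swift_freqs)) * fs) / fs


def default_study_params(
    mechanism: str,
    gain: float,
    channels: tuple[str, ...] | None = None,
    noise_level: float = STUDY_NOISE_LEVEL,
    jitter_sd: float = STUDY_JITTER_SD,
    epoch_len: float = 5.0,
    jitter_block_offset_s: float = 0.0,
) -> CascadeParams:
    """Cascade parameters for one condition of a simulated study.

    ``mechanism`` is ``"stim_locked"`` (the interaction happens at a fixed
    latency, phase-locked to the stimulus) or ``"response_locked"`` (it
    happens between the latency-jittered responses).  Latency blocks are
    one analysis epoch long; pass ``jitter_block_offset_s`` (see
    :func:`epoch_grid_offset`) so each non-overlapping epoch sees a single
    latency draw.
    """
    if mechanism not in {"stim_locked", "response_locked"}:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    kwargs = dict(
        amp_f1=1.0,
        amp_f2=1.0,
        noise_level=noise_level,
        tau_jitter_sd=jitter_sd,
        jitter_block_s=epoch_len,
        jitter_block_offset_s=jitter_block_offset_s,
    )
    if channels is not None:
        kwargs["channels"] = channels
    if mechanism == "stim_locked":
        kwargs.update(g_low=gain, g_high=0.0)
    else:
        kwargs.update(g_low=0.0, g_high=gain)
    return CascadeParams(**kwargs)


def _default_schedule(n_cycles: int = 126) -> TrialSchedule:
    # 105-s expectation-style trial: 1.2 Hz SWIFT, 15 Hz SSVEP; long enough
    # for 20 non-overlapping 5-s epochs after dropping the first cycle
    return build_exp1_schedule("FHHFFH", task="PV", n_cycles=n_cycles, violation_index=17)


def simulate_study(
    kind: str,
    n_participants: int = 15,
    rng_seed: int | np.random.Generator = 0,
    schedule: TrialSchedule | None = None,
    channels: tuple[str, ...] | None = None,
    epoch_len: float = 5.0,
    step: float = 5.0,
    gain_high: float = STUDY_GAIN_HIGH,
    gain_low: float = STUDY_GAIN_LOW,
    noise_level: float = STUDY_NOISE_LEVEL,
    jitter_sd: float = STUDY_JITTER_SD,
    participant_sd: float = 0.1,
) -> pd.DataFrame:
    """Simulate one two-condition study with per-participant variability.

    ``kind='expectation'``: the condition (1 = expected) modulates the
    stimulus-locked gain; ``kind='attention'``: the condition (1 =
    attended) modulates the response-locked gain.  Each participant
    contributes one trial per condition; per-participant multiplicative
    gain factors (lognormal-ish, SD ``participant_sd``) induce the random-
    intercept structure the mixed models assume.

    Returns a long table (participant, condition, channel, variant, freq,
    value) of second-order-IM MSPC values.
    """
    mechanism = {"expectation": "stim_locked", "attention": "response_locked"}.get(kind)
    if mechanism is None:
        raise ValueError(f"kind must be 'expectation' or 'attention', got {kind!r}")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    if schedule is None:
        schedule = _default_schedule()
    offset = epoch_grid_offset(schedule)
    frames = []
    for p in range(n_participants):
        factor = float(np.exp(rng.normal(0.0, participant_sd)))
        for condition, gain in ((1, gain_high), (0, gain_low)):
            params = default_study_params(
                mechanism, gain * factor, channels, noise_level, jitter_sd, epoch_len,
                jitter_block_offset_s=offset,
            )
            ds = simulate_trial(schedule, params, rng)
            tab = trial_mspc_table(ds.recording, ds.schedule, epoch_len, step)
            tab["participant"] = f"P{p:02d}"
            tab["condition"] = condition
            frames.append(tab[["participant", "condition", "channel", "variant", "freq", "value"]])
    return pd.concat(frames, ignore_index=True)


def study_contrast(
    table: pd.DataFrame,
    variant: str,
    roi: ROIDefinition | None = None,
) -> LRTResult:
    """Mixed-model condition contrast of one MSPC variant in a study table.

    Values are averaged over the two second-order IM components per
    channel (restricted to ``roi`` when given), then the condition effect
    is tested by a likelihood-ratio test of a mixed model with a random
    intercept and a random condition slope per participant.  The random
    slope is essential: within a trial all channels share the same
    response-latency draws, so channel rows are strongly correlated at
    the trial level, and a random-intercept-only model would be badly
    anti-conservative.
    """
    sub = table[table["variant"] == variant].drop(columns=["variant"])
    im_pair = tuple(sorted(sub["freq"].unique()))
    if roi is not None:
        agg = roi_aggregate(sub, roi, im_pair)
    else:
        keys = [c for c in sub.columns if c not in {"value", "freq"}]
        agg = sub.groupby(keys, as_index=False, observed=True)["value"].mean()
    return lrt_contrast(agg, ["condition"], "condition", re_formula="~condition")
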