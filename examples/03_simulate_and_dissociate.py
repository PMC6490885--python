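"""The core dissociation: where in the cascade does the interaction live?

Two synthetic trials with identical spectra but different mechanisms:
in one, the SWIFT x SSVEP interaction is locked to the stimulus (a
fixed-latency, "low-level" interaction); in the other it happens between
latency-jittered neural responses ("high-level").  Stimulus-referenced
coherence (MSPCstim) flags the first; response-referenced coherence
(MSPCres) flags the second.
"""

from hftmspc import simulate_trial, trial_mspc_table
from hftmspc.pipeline import _default_schedule, default_study_params, epoch_grid_offset

schedule = _default_schedule()  # 105 s, SWIFT 1.2 Hz, SSVEP 15 Hz
offset = epoch_grid_offset(schedule)

for mechanism in ("stim_locked", "response_locked"):
    params = default_study_params(mechanism, gain=0.5, jitter_block_offset_s=offset)
    ds = simulate_trial(schedule, params, rng_seed=0)
    table = trial_mspc_table(ds.recording, schedule, epoch_len=5.0, step=5.0)
    means = table.groupby("variant")["value"].mean()
    print(f"{mechanism:16s}  MSPCstim = {means['stim']:.3f}   MSPCres = {means['res']:.3f}")
# Both trials show the same intermodulation peaks at 13.8 and 16.2 Hz;
# only the phase-coherence variants reveal which level generated them:
# the stimulus-locked trial is MSPCstim-dominant, the jittered
# response-level trial is MSPCres-dominant (chance floor ~ 0.2 at K = 20).
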