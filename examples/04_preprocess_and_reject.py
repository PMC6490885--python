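"""Artifact injection, noise flagging and the exclusion rules.

A sample is noisy if |x| > 80 uV, if it jumps > 30 uV from the previous
sample, or if it strays > 5 SD from the channel's trial mean; > 2% noisy
samples condemn a cycle, > 10% noisy cycles condemn a channel, > 10% bad
channels condemn the trial.
"""

from hftmspc import (
    TrialQC,
    apply_exclusions,
    flag_noise,
    inject_artifacts,
    simulate_trial,
    standardize,
)
from hftmspc.pipeline import _default_schedule, default_study_params
from hftmspc.spectral import cycle_grid_samples

schedule = _default_schedule(36)  # 30 s at 1.2 Hz -> 36 cycles
params = default_study_params("stim_locked", 0.5)
rec = simulate_trial(schedule, params, rng_seed=0).recording
rec = standardize(rec)

# ruin one channel with repeated spikes, brush another with a single jump
spikes = [(3, s, "spike80") for s in range(1000, 15000, 80)]
dirty = inject_artifacts(rec, spikes + [(0, 7000, "jump30")])

grid = cycle_grid_samples(schedule, rec.fs, rec.n_samples)
report = flag_noise(dirty, grid)
print(f"cycles: {len(grid)}; noisy-cycle fraction per channel:")
for lab, frac in zip(report.channel_labels, report.noisy_cycle_fraction):
    mark = " <- bad (>10% of cycles noisy)" if lab in report.bad_channels else ""
    print(f"  {lab:4s} {frac:5.1%}{mark}")

trials = [
    TrialQC("S01", "t1", n_channels=17, n_bad_channels=len(report.bad_channels)),
    TrialQC("S01", "t2", n_channels=17, n_bad_channels=0,
            reported_count=22, true_count=19),   # within the +/-3 tolerance
    TrialQC("S01", "t3", n_channels=17, n_bad_channels=0,
            reported_count=26, true_count=19),   # off by 7 -> invalid
    TrialQC("S01", "t4", n_channels=17, n_bad_channels=0,
            reported_count=20, true_count=20),
]
exc = apply_exclusions(trials)
print(f"bad trials: {exc.bad_trials}; invalid responses: {exc.invalid_response_trials}")
print(f"excluded participants: {exc.excluded_participants or 'none'}")
# One spiked channel is flagged bad; the single jump elsewhere is far too
# brief to condemn a cycle.  One miscount beyond +/-3 invalidates a trial,
# but one invalid trial in four (25%) stays under the 30% exclusion rule.
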