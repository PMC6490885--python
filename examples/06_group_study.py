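"""A simulated two-condition study with mixed-model contrasts.

Fifteen simulated participants each contribute one trial per condition.
In the expectation-style study the condition modulates the
stimulus-locked interaction gain; the group-level likelihood-ratio
contrast should therefore be significant for MSPCstim and flat for
MSPCres — the signature that the modulation acts at a low, stimulus-
locked level of the cascade.
"""

import warnings

from hftmspc import simulate_study, study_contrast
from hftmspc.synthetic_eeg import DEFAULT_CHANNELS

warnings.filterwarnings("ignore", module="statsmodels")

channels = tuple(list(DEFAULT_CHANNELS)[:8])
table = simulate_study("expectation", n_participants=15, rng_seed=0, channels=channels)

cond_means = table.groupby(["variant", "condition"])["value"].mean().unstack()
print("mean coherence by condition (0 = unexpected, 1 = expected):")
print(cond_means.round(3))

for variant in ("stim", "res"):
    lrt = study_contrast(table, variant)
    verdict = "significant" if lrt.p < 0.05 else "not significant"
    print(f"MSPC{variant:4s}: chi2({lrt.df}) = {lrt.chi2:6.2f}, p = {lrt.p:.2e}  -> {verdict}")
# Expectation raises MSPCstim (the interaction is stimulus-locked) while
# MSPCres stays at its chance floor in both conditions: the contrast is
# carried entirely by the stimulus-referenced variant.
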