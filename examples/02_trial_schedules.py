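"""Trial schedules of the two paradigms, plus the central-cross control.

The expectation paradigm shows one face/house stream at 1.2 Hz under a
15 Hz contrast modulation; a memorised pattern makes upcoming images
predictable (PV task) or not (IR task) with identical stimuli.  The
attention paradigm superimposes a face stream and a house stream at 0.8
and 1 Hz under 12 Hz contrast modulation, and attention is directed by
asking which stream to count.
"""

import numpy as np

from hftmspc import build_cross_schedule, build_exp1_schedule, build_exp2_schedule

pv = build_exp1_schedule("FHHFFH", task="PV", n_cycles=24, violation_index=17)
ir = build_exp1_schedule("FHHFFH", task="IR", n_cycles=24, violation_index=17)
short = {"face": "F", "house": "H"}
print("pattern FHHFFH, violated at the 18th image:")
print("  series:", "".join(short[c] for c in pv.categories))
print(f"  target index: {pv.target_index} (0-based); PV/IR series identical: "
      f"{pv.categories == ir.categories}")

exp2 = build_exp2_schedule(f_a=0.8, f_b=1.0, presence=0.78, rng_seed=4)
print(f"\ndual-frequency trial ({exp2.duration} s, SSVEP {exp2.ssvep_freq} Hz):")
for f, cat in ((0.8, "face"), (1.0, "house")):
    n = len(exp2.stream(f))
    print(f"  {cat} stream at {f} Hz: {n} cycles, {exp2.image_count(cat)} images "
          f"(rest are matched noise cycles)")

cross = build_cross_schedule(duration=31.5, rng_seed=5)
gaps = np.diff([0.0] + [e.time for e in cross])
print(f"\ncentral-cross control: {len(cross)} events, "
      f"{sum(e.is_target for e in cross)} conjunction targets, "
      f"intervals {gaps.min()*1e3:.0f}-{gaps.max()*1e3:.0f} ms")
# The images counted per stream stay within 17-26; cross events are
# jittered (850-1,000 ms) precisely so they do NOT frequency-tag.
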