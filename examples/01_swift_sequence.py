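"""Build a cyclic SWIFT sequence and verify its conservation properties.

A SWIFT sequence scrambles an image in the wavelet domain by rotating each
local 3-vector of detail coefficients along a circular path of constant
norm: contours are destroyed, local low-level statistics (contrast,
spatial frequency, luminance) are preserved, and the intact image appears
exactly once per cycle.
"""

import numpy as np

from hftmspc import make_noise_sequence, swift_scramble

# a smooth synthetic "photograph"
rng = np.random.default_rng(0)
x = rng.random((64, 64))
X = np.fft.fft2(x)
f = np.fft.fftfreq(64)
X *= np.exp(-((f[None, :] ** 2 + f[:, None] ** 2) / (2 * 0.08**2)))
img = np.fft.ifft2(X).real
img = (img - img.min()) / (img.max() - img.min())

seq = swift_scramble(img, n_frames=30, levels=6, rng_seed=1)
noise = make_noise_sequence(seq, rng_seed=2)

peak_err = np.max(np.abs(seq.frames[seq.peak_index] - img))
mean_drift = np.max(np.abs(seq.frames.mean(axis=(1, 2)) - img.mean()))
corr = np.corrcoef(seq.frames[seq.anchor_index].ravel(), img.ravel())[0, 1]

print(f"frames: {seq.n_frames}, peak at {seq.peak_index}, anchor at {seq.anchor_index}")
print(f"peak-frame reconstruction error: {peak_err:.2e}")
print(f"max mean-intensity drift across frames: {mean_drift:.2e}")
print(f"anchor-frame correlation with the original: {corr:+.3f}")
print(f"noise sequence frames: {noise.n_frames} (scramble of the anchor frame)")
# The peak frame IS the image (error ~1e-13); every frame keeps the image's
# mean intensity; the anchor frame used to seed the noise sequence carries
# no recognisable structure (low/negative correlation with the original).
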