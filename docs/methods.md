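# Methods

## Stimulus model

A SWIFT sequence is built by decomposing a grayscale image with a
discrete Meyer wavelet at 6 levels and, at every detail location and
scale, rotating the 3-vector of (horizontal, vertical, diagonal)
coefficients along a circular path through two random vectors of the same
norm. Because every point of the path lies on the sphere of the original
vector's norm, local energy — and hence contrast, luminance and spatial
frequency content — is conserved at every frame, while contour phase
structure is destroyed everywhere except at path angle 0, where the
original image reappears. The approximation band is never touched, so
frame mean intensity is conserved exactly.

The wavelet itself is a frequency-sampled discrete Meyer filter (256
taps by default) supplied to PyWavelets as a custom filter bank. The
sampled frequency response satisfies the quadrature-mirror condition
exactly at the DFT sample points, giving perfect reconstruction to
~1e-13 under periodized convolution; the widely shipped 62-tap Meyer
truncation reconstructs only to ~1e-3, which is far too coarse for a
scheme whose guarantees are phrased as exact coefficient-norm
conservation. Images whose sides are not multiples of 2^levels are
padded symmetrically and cropped after the inverse transform.

Noise sequences re-scramble the *anchor* frame — the frame at path angle
π, the geometrically most distant scramble from the peak. Path distance
is used rather than an image-similarity criterion because it is
deterministic and parameter-free; the anchor typically correlates
*negatively* with the original (the detail vectors are near-antipodal),
so "most distant" bounds are checked on correlation magnitudes.

Phase conventions are fixed once: the SSVEP contrast cosine
c(t) = lo + (hi−lo)(1+cos 2πf2 t)/2 peaks at trial onset (bounds
0.30–1.00 of original contrast), and the SWIFT phase is 0 (mod 2π) at
peak-frame times, with the peak at the middle of each cycle. The
coherence statistic is invariant to constant offsets, so the choice is
arbitrary but must match the FFT referencing (below). Schedules carry
variant-set metadata (three scramble variants per image, swapped at the
peak for same-image transitions and at the anchor otherwise); frame
rendering honours it. Default frame rate 120 Hz.

With two independent streams (0.8 and 1 Hz) each stream has
floor(duration·f) cycles, of which a `presence` fraction (70–85%) shows
the image and the rest its matched noise sequence; at the 31.5-s default
duration the counted-image total spans 17–26. The central-cross control
draws inter-event intervals uniformly from 850–1,000 ms — jittered
precisely so it does not frequency-tag.

## Synthetic EEG

The generator is a two-level cascade, the minimal mechanism that makes
the two coherence variants dissociate:

* drives: s1(t) = Σ_h d^(h−1) cos(h·φ1(t)) (SWIFT, 2 harmonics, decay
  d = 0.5 — the recognition response is non-sinusoidal), s2(t) = cos φ2(t)
  (SSVEP); amplitudes 1 μV;
* a stimulus-locked interaction g_low·s1·s2 at fixed latency τ = 80 ms;
* response drives r1, r2 = the same drives delayed by τ + δ_e, with
  δ_e ~ N(0, σ²) redrawn once per analysis-epoch-length block
  (σ = 80 ms in the study conditions);
* a response-locked interaction g_high·r1·r2;
* the measured fundamentals are emitted from the response level, so
  MSPCres references the jittered phases;
* independent 1/f^α noise per channel (α = 1), no spatial correlation —
  spatial realism is a non-goal.

Block-constant jitter is used rather than continuous drift because MSPC
extracts one phase per epoch: an epoch-constant latency is the smallest
perturbation that shifts all of an epoch's phases coherently. The blocks
are aligned to the analysis epoch grid and the study analyses use
non-overlapping 5-s epochs (step = epoch length) on 105-s trials,
giving K = 20 epochs per trial after the first SWIFT cycle is dropped.
With the 1-s sliding step appropriate for real recordings, overlapping
epochs share most of their samples and latency blocks, which leaves only
~n_blocks effective degrees of freedom and inflates the no-coupling
coherence floor to ~0.5; the aligned non-overlapping grid restores K
independent phases, which is what both the closed-form Rayleigh null and
the permutation null describe. The 1-s step remains the default of
`epoch_for_mspc` for real data.

Noise RMS 1.1 μV was calibrated so the SWIFT fundamental's amplitude SNR
is ≈ 5 under the 20-s analysis window. Under 1/f noise the 15 Hz SSVEP
fundamental then sits higher (~12); note that latency jitter itself
spreads the measured 15 Hz peak into ±1/block-length sidebands, capping
its apparent SNR near 2.6 regardless of the noise level — a property of
the jitter mechanism, not of the background.

What passing tests show — and what they do not: the generator reproduces
the *statistical structure the analysis assumes* (exact-bin tagged
components, epoch-coherent phases, 1/f background, injectable artifacts).
It does not model volume conduction, electrode forward fields, ocular or
myogenic artifact morphology, or spatially correlated noise, so
ground-truth recovery here demonstrates correctness of the estimator
chain, not performance on real recordings.

## Preprocessing

Resample to 500 Hz (polyphase), high-pass at 0.3 Hz with a 4th-order
zero-phase Butterworth, convert to average reference. The filter's
reflection padding is extended to 30 s because a 0.3 Hz IIR settles over
tens of seconds; with the default padding, endpoint transients leak ~1e-3
into the interior and standardisation would not be idempotent. The ±5 SD
noise criterion is computed on the signal as passed in (i.e. after
standardisation in the default pipeline); the ordering is ambiguous in
common practice, so it is the caller's choice. Noise rules: |x| > 80 μV,
adjacent-sample jump > 30 μV, |x − mean| > 5 SD (all strict); > 2% noisy
samples condemns a cycle, > 10% noisy cycles a channel, > 10% bad
channels a trial, > 20% bad trials a participant, as does > 30%
behaviourally invalid trials (count off by more than ±3, or a press
missing/before the target). Bad channels are replaced by
inverse-distance-weighted means of the 4 nearest good electrodes —
interpolation is incidental to the claims here and a spline's
order/regularisation would be additional unconstrained parameters. A
zero-phase notch (50 Hz + harmonic) is available behind a flag; the
synthetic data carry no mains component.

## Spectral analysis

All analysis frequencies must fall on exact FFT bins (an error, never
interpolation), so a rectangular window is used throughout — tapering
would only leak tagged energy into neighbours. Amplitudes are
2|X(f)|/N with N the number of real (non-padded) samples; phases are
referenced to the segment start. Whole-trial windows: > 17 s of data is
zero-padded to 20 s (0.05 Hz bins), 10–17 s keeps the first 10 s (0.1 Hz
bins), and the fixed-length design uses the 3–28 s window (25 s,
12,500 samples, 0.04 Hz bins). Phases from padded spectra are not used
for coherence (MSPC works on unpadded within-trial epochs); padded
spectra feed amplitude SNR only. SNR divides the amplitude at f by the
mean over ±n_side neighbouring bins (4 per side at 0.1 Hz bins up to 8
per side at 0.04 Hz), excluding any bin occupied by a harmonic or an IM
up to order 4.

## MSPC

Ψ = |K⁻¹ Σ_k exp(i(Σ_r n_r φ_I,k(f_r) − φ_O,k(f_Σ)))|. Each epoch's FFT
phase is referenced to that epoch's own start, and the stimulus phase is
evaluated at the same instant; with the conventions above, an entrained
zero-latency response has identical stimulus and FFT phases, which makes
the two variants directly comparable. Everything is within-channel.
K = 1 yields Ψ = 1 identically and is flagged degenerate. The
independence null has mean √π/(2√K) (Rayleigh walk); `null_calibrate`
also provides a Monte-Carlo/permutation null that shuffles the epoch
pairing between input-phase vectors and output phases, preserving each
margin's own structure. Generalized input sets (second harmonics
{2f1, 2f2}, or an IM treated as a single weighted input) are expressed
through `MSPCSpec` rather than special-cased code.

## Group statistics

Values are averaged over the two second-order IMs within the fixed
17-electrode posterior ROI (Oz/O1/O2, POz/PO3/PO4/PO7/PO8, Pz/P1–P8),
keeping channel as a factor. Contrasts are likelihood-ratio tests
between maximum-likelihood mixed-model fits (statsmodels MixedLM;
chi2 = 2Δll, df = number of dropped fixed-effect parameters; optimizer
fallback lbfgs → bfgs → powell; non-convergence raises, boundary fits
are flagged). The simulated-study contrast uses a random intercept plus
a random condition slope per participant: all channels within a trial
share the same latency draws, so channel rows are correlated at trial
level and a random-intercept-only model is badly anti-conservative
(observed false-positive rate near 1 on the "null" variant; ~0.03–0.05
with the slope). An all-zero dropped design column short-circuits to
chi2 = 0. The interaction analysis takes graded expectation (≥ 3 ordered
levels) × binary attention, tests the interaction by LRT, then the two
posthocs: expectation within attended, and attention within the
"expected" half of a median split (values strictly above the median of
the distinct levels; four levels split {1,2} vs {3,4}), plus
per-condition expectation slopes. A participant-level sign-flip
permutation contrast (default 10,000 flips) is provided because
coherence values near the [0, 1] boundary can destabilise mixed models
at small n.

## Problem sizes

Simulated studies use 15 participants × 2 conditions × 1 trial (105 s,
8 posterior channels); dissociation margins use 50 single-trial seeds;
LRT calibration uses 500 simulated tables (15 participants × 2
conditions × 4 channels); the coherence null uses 10,000 Monte-Carlo
draws at K = 100. These sizes make the full test suite and the
acceptance script each run in minutes on one CPU while leaving the
acceptance margins (≥ 0.3 coherence difference; ≥ 80% pattern recovery;
type-I 0.05 ± 0.02) comfortably wide.

## Known limitations

Frame rendering of full trials (variant alternation, blending, contrast
modulation) is provided as composable operations, not a real-time
presentation engine. The mne-based readers for BrainVision/EDF are thin
and untested against real recorder quirks. The LRT's χ² reference is
asymptotic; at very small n the permutation contrast is the safer tool.
Open policy choices without defaults: the image-repetition task's
repetition count (3 vs 4) is a caller parameter; source-photograph
luminance normalisation is out of scope (synthetic images are used).
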