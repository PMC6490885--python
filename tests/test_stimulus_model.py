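"""Stimulus construction: SWIFT scrambling, schedules, phase references."""

import inspect

import numpy as np
import pytest
import pywt

from hftmspc._meyer import meyer_wavelet
from hftmspc.stimulus_model import (
    DimensionError,
    ImageGrid,
    alpha_blend,
    build_cross_schedule,
    build_exp1_schedule,
    build_exp2_schedule,
    contrast_modulate,
    make_noise_sequence,
    stimulus_phase,
    swift_scramble,
)


class TestSwiftScramble:
    def test_peak_frame_reconstructs_source(self, smooth_image):
        seq = swift_scramble(smooth_image, n_frames=12, rng_seed=0)
        assert np.max(np.abs(seq.frames[seq.peak_index] - smooth_image)) < 1e-6

    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_coefficient_vector_norms_conserved(self, smooth_image):
        # oracle: re-run the forward transform on a scrambled frame and
        # compare every (H, V, D) coefficient-vector norm with the source's
        seq = swift_scramble(smooth_image, n_frames=12, rng_seed=1)
        wav = meyer_wavelet(256)
        ref = pywt.wavedec2(smooth_image, wav, mode="periodization", level=6)
        for k in (0, 3, 7):
            got = pywt.wavedec2(seq.frames[k], wav, mode="periodization", level=6)
            for lvl in range(1, 7):
                n_ref = np.linalg.norm(np.stack(ref[lvl]), axis=0)
                n_got = np.linalg.norm(np.stack(got[lvl]), axis=0)
                assert np.max(np.abs(n_got - n_ref)) < 1e-9 * max(1.0, n_ref.max())

    def test_mean_intensity_preserved(self, smooth_image):
        seq = swift_scramble(smooth_image, n_frames=10, rng_seed=2)
        means = seq.frames.mean(axis=(1, 2))
        assert np.all(np.abs(means - smooth_image.mean()) <= 0.02 * smooth_image.mean())

    def test_default_depth_is_six_levels(self):
        assert inspect.signature(swift_scramble).parameters["levels"].default == 6

    def test_deterministic_under_seed(self, smooth_image):
        a = swift_scramble(smooth_image, n_frames=8, rng_seed=7)
        b = swift_scramble(smooth_image, n_frames=8, rng_seed=7)
        assert np.array_equal(a.frames, b.frames)

    def test_rejects_bad_inputs(self, smooth_image):
        with pytest.raises(ValueError):
            swift_scramble(smooth_image, n_frames=12, levels=0)
        with pytest.raises(ValueError):
            swift_scramble(smooth_image, n_frames=2)
        with pytest.raises(DimensionError):
            swift_scramble(np.zeros((16, 16)), n_frames=12, levels=6)

    def test_padding_handles_non_power_of_two(self, smooth_image):
        img = smooth_image[:60, :50]
        seq = swift_scramble(img, n_frames=6, levels=4, rng_seed=3)
        assert seq.frames.shape == (6, 60, 50)
        assert np.max(np.abs(seq.frames[seq.peak_index] - img)) < 1e-6


class TestNoiseSequence:
    def test_noise_peak_is_the_anchor_frame(self, smooth_image):
        seq = swift_scramble(smooth_image, n_frames=10, rng_seed=0)
        noise = make_noise_sequence(seq, rng_seed=1)
        assert np.max(np.abs(noise.frames[noise.peak_index] - seq.frames[seq.anchor_index])) < 1e-6

    def test_noise_never_reconstructs_the_image(self, smooth_image):
        seq = swift_scramble(smooth_image, n_frames=10, rng_seed=0)
        noise = make_noise_sequence(seq, rng_seed=1)

        def corr(a, b):
            return np.corrcoef(a.ravel(), b.ravel())[0, 1]

        # the anchor (path angle pi) is anti-correlated with the source, so
        # the bound is on magnitudes: no noise frame resembles the original
        # more than the anchor does
        anchor_corr = abs(corr(seq.frames[seq.anchor_index], smooth_image))
        for frame in noise.frames:
            assert abs(corr(frame, smooth_image)) < anchor_corr + 0.05

    def test_noise_mean_matches_source(self, smooth_image):
        seq = swift_scramble(smooth_image, n_frames=10, rng_seed=0)
        noise = make_noise_sequence(seq, rng_seed=1)
        src_mean = seq.frames[seq.anchor_index].mean()
        assert np.all(np.abs(noise.frames.mean(axis=(1, 2)) - src_mean) <= 0.02 * abs(src_mean))


class TestBlendAndContrast:
    def test_blend_identities(self):
        x = np.random.default_rng(0).random((4, 8, 8))
        assert np.allclose(alpha_blend(x, x), x)
        assert np.allclose(alpha_blend(np.zeros((2, 4, 4)), np.ones((2, 4, 4))), 0.5)
        with pytest.raises(ValueError):
            alpha_blend(np.zeros((2, 4, 4)), np.zeros((3, 4, 4)))

    def test_unit_bounds_are_identity(self):
        x = np.random.default_rng(1).random((8, 16, 16))
        out = contrast_modulate(x, ssvep_freq=15.0, frame_rate=120.0, bounds=(1.0, 1.0))
        assert np.allclose(out, x)

    def test_trough_scale_equals_lower_bound(self):
        # at t = 1/(2 f) the modulation reaches exactly lo; with f = 15 Hz
        # and 120 fps that is frame 4
        x = np.random.default_rng(2).random((8, 16, 16))
        out = contrast_modulate(x, ssvep_freq=15.0, frame_rate=120.0, bounds=(0.30, 1.00))
        k = 4
        mean = x[k].mean()
        assert np.allclose(out[k] - mean, 0.30 * (x[k] - mean), atol=1e-12)

    def test_default_bounds_span_70_percent(self):
        sig = inspect.signature(contrast_modulate)
        lo, hi = sig.parameters["bounds"].default
        assert (lo, hi) == (0.30, 1.00)

    def test_aliasing_refused(self):
        with pytest.raises(ValueError):
            contrast_modulate(np.zeros((4, 8, 8)), ssvep_freq=70.0, frame_rate=120.0)


class TestExp1Schedule:
    def test_worked_example_target_is_18th_image(self):
        # pattern F,H,H,F,F,H repeating; the violated 18th image (index 17)
        # flips H -> F, creating the first three-in-a-row repetition
        sch = build_exp1_schedule("FHHFFH", "PV", n_cycles=24, violation_index=17)
        assert sch.target_index == 17
        cats = sch.categories
        assert cats[15:18] == ["face", "face", "face"]
        # no earlier run of length 3
        runs = [cats[i] == cats[i + 1] == cats[i + 2] for i in range(15)]
        assert not any(runs)

    def test_pv_and_ir_share_the_category_series(self):
        pv = build_exp1_schedule("FHHFFH", "PV", n_cycles=24, violation_index=17)
        ir = build_exp1_schedule("FHHFFH", "IR", n_cycles=24, violation_index=17)
        assert pv.categories == ir.categories

    def test_cycle_grid(self):
        sch = build_exp1_schedule("FHHFFH", "PV", n_cycles=24, violation_index=17)
        onsets = [c.onset for c in sch.cycles]
        assert np.allclose(np.diff(onsets), 1 / 1.2)
        assert sch.duration == pytest.approx(20.0)

    def test_rejects_degenerate_patterns(self):
        with pytest.raises(ValueError):
            build_exp1_schedule("F", "IR", n_cycles=24, violation_index=17)
        with pytest.raises(ValueError):
            build_exp1_schedule("FHHFFH", "PV", n_cycles=24, violation_index=5)


class TestExp2Schedule:
    def test_counted_images_at_the_bounds(self):
        # 31.5 s at 1.0 Hz -> 31 cycles; presence 0.85 -> floor(26.35) = 26
        sch = build_exp2_schedule(f_a=0.8, f_b=1.0, presence=0.85, rng_seed=0)
        assert sch.image_count("house") == 26
        # 0.8 Hz -> 25 cycles; presence 0.70 -> floor(17.5) = 17
        sch = build_exp2_schedule(f_a=0.8, f_b=1.0, presence=0.70, rng_seed=0)
        assert sch.image_count("face") == 17

    @pytest.mark.parametrize("presence", [0.70, 0.775, 0.85])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_counted_images_within_17_to_26(self, presence, seed):
        sch = build_exp2_schedule(presence=presence, rng_seed=seed)
        for cat in ("face", "house"):
            assert 17 <= sch.image_count(cat) <= 26

    def test_full_presence_means_no_noise_cycles(self):
        sch = build_exp2_schedule(presence=1.0, rng_seed=0)
        assert not [c for c in sch.cycles if c.category.startswith("noise")]

    def test_streams_span_the_trial_independently(self):
        sch = build_exp2_schedule(rng_seed=3)
        for f, n in ((0.8, 25), (1.0, 31)):
            stream = sch.stream(f)
            assert len(stream) == n
            assert stream[-1].onset + 1 / f <= sch.duration + 1e-6

    def test_presence_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            build_exp2_schedule(presence=1.2)


class TestCrossSchedule:
    def test_intervals_within_bounds(self):
        events = build_cross_schedule(duration=60.0, rng_seed=0)
        times = np.array([e.time for e in events])
        gaps = np.diff(np.concatenate([[0.0], times]))
        assert np.all((gaps >= 0.850) & (gaps <= 1.000))

    def test_mean_interval_near_925_ms(self):
        events = build_cross_schedule(duration=1000.0, rng_seed=1)
        times = np.array([e.time for e in events])
        assert abs(np.diff(times).mean() - 0.925) < 0.01

    def test_zero_duration_gives_no_events(self):
        assert build_cross_schedule(duration=0.0, rng_seed=0) == []

    def test_conjunction_targets(self):
        events = build_cross_schedule(duration=200.0, rng_seed=2)
        for e in events:
            assert e.is_target == ((e.height, e.colour) in {("up", "red"), ("down", "green")})
        assert any(e.is_target for e in events)


class TestStimulusPhase:
    def test_swift_phase_zero_at_peaks(self, exp1_schedule):
        f = 1.2
        peaks = np.array([c.onset + 0.5 / f for c in exp1_schedule.cycles])
        ph = stimulus_phase(exp1_schedule, f, peaks)
        assert np.allclose(np.mod(ph + np.pi, 2 * np.pi) - np.pi, 0.0, atol=1e-9)

    def test_phase_advances_2pi_per_cycle(self, exp1_schedule):
        for f in (1.2, 15.0):
            t = np.array([2.0, 2.0 + 1 / f])
            ph = stimulus_phase(exp1_schedule, f, t)
            assert ph[1] - ph[0] == pytest.approx(2 * np.pi)

    def test_unknown_frequency_rejected(self, exp1_schedule):
        with pytest.raises(ValueError):
            stimulus_phase(exp1_schedule, 7.7, [0.0])

    def test_fft_of_peak_impulse_train_matches(self, exp1_schedule):
        # render an impulse at every peak frame over an integer number of
        # cycles; the FFT phase at the SWIFT frequency, referenced to the
        # segment start, must equal the analytic stimulus phase there
        fs, f = 600.0, 1.2  # 600 Hz puts every peak time on the sample grid
        t0, dur = 5.0, 10.0  # 12 cycles
        n = int(dur * fs)
        x = np.zeros(n)
        for c in exp1_schedule.cycles:
            tp = c.onset + 0.5 / f
            k = int(round((tp - t0) * fs))
            if 0 <= k < n:
                x[k] = 1.0
        X = np.fft.rfft(x)
        k_bin = int(round(f * dur))
        got = np.angle(X[k_bin])
        want = stimulus_phase(exp1_schedule, f, t0)
        err = np.angle(np.exp(1j * (got - want)))
        assert abs(err) < 1e-3
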