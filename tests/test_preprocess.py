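"""Preprocessing: standardisation, noise flagging, interpolation, exclusions."""

import numpy as np
import pytest

from hftmspc.preprocess import (
    EEGRecording,
    TrialQC,
    apply_exclusions,
    flag_noise,
    interpolate_bad_channels,
    standardize,
)
from hftmspc.synthetic_eeg import inject_artifacts


def _rec(data, fs=500.0, positions=None):
    labels = [f"C{i}" for i in range(data.shape[0])]
    return EEGRecording(data=data, fs=fs, channel_labels=labels, channel_positions=positions)


class TestStandardize:
    def test_offset_removed_and_average_referenced(self):
        # constant-offset channels: the high-pass removes the offsets and
        # after re-referencing every column sums to zero
        data = np.tile(np.array([[10.0], [-3.0], [0.0], [7.0]]), (1, 5000))
        out = standardize(_rec(data))
        assert np.max(np.abs(out.data.mean(axis=1))) < 1e-6
        assert np.max(np.abs(out.data.sum(axis=0))) < 1e-9

    def test_filter_response(self):
        # 0.05 Hz attenuated by >= 20 dB, 15 Hz by <= 0.5 dB (zero-phase
        # 4th-order Butterworth high-pass at 0.3 Hz); antisymmetric channel
        # pair so the average reference leaves the signal untouched
        fs, dur = 500.0, 120.0
        t = np.arange(int(dur * fs)) / fs
        for f, check in ((0.05, lambda g: g < 0.1), (15.0, lambda g: g > 0.944)):
            x = np.sin(2 * np.pi * f * t)
            out = standardize(_rec(np.vstack([x, -x])))
            mid = slice(int(20 * fs), int(100 * fs))  # avoid filter edges
            gain = out.data[0, mid].std() / x[mid].std()
            assert check(gain), (f, gain)

    def test_resamples_1000_to_500(self):
        t = np.arange(10000) / 1000.0
        x = np.sin(2 * np.pi * 15.0 * t)[None, :]
        out = standardize(_rec(np.vstack([x, -x]), fs=1000.0))
        assert out.fs == 500.0
        assert out.data.shape[1] == 5000

    def test_refuses_to_upsample(self):
        with pytest.raises(ValueError):
            standardize(_rec(np.zeros((2, 1000)), fs=250.0))

    def test_idempotent_within_tolerance(self):
        # passband content with odd symmetry at both endpoints (so the
        # zero-phase filter's reflection padding is the exact continuation
        # and no slow edge transient arises): a second pass is a no-op
        fs, n = 500.0, 30001
        t = np.arange(n) / fs
        x = np.vstack([
            np.sin(2 * np.pi * 15 * t) + 0.5 * np.sin(2 * np.pi * 5 * t),
            np.sin(2 * np.pi * 12 * t),
        ])
        once = standardize(_rec(x))
        twice = standardize(once)
        assert np.max(np.abs(twice.data - once.data)) < 1e-9


class TestFlagNoise:
    grid = [(i * 417, (i + 1) * 417) for i in range(12)]

    def test_clean_recording_has_no_flags(self):
        rep = flag_noise(_rec(np.zeros((3, 5004))), self.grid)
        assert not rep.noisy_sample_mask.any()
        assert not rep.bad_channels

    def test_single_spike_does_not_condemn_a_cycle(self):
        # 1 noisy sample out of 417 (0.24%) stays under the 2% cycle rule
        rng = np.random.default_rng(1)
        data = rng.normal(0, 1.0, (2, 5004))
        rec = inject_artifacts(_rec(data), [(0, 100, "spike80")])
        rep = flag_noise(rec, self.grid)
        assert rep.noisy_sample_mask[0, 100]
        assert not rep.noisy_cycles[0, 0]

    def test_ten_spikes_condemn_exactly_one_cycle(self):
        rng = np.random.default_rng(2)
        data = rng.normal(0, 1.0, (2, 5004))
        rec = _rec(data)
        rec.data[0, 10:20] = 85.0  # 10/417 = 2.4% > 2%
        rep = flag_noise(rec, self.grid)
        assert rep.noisy_cycles[0, 0]
        assert rep.noisy_cycles.sum() == 1

    def test_monotone_in_artifacts(self):
        rng = np.random.default_rng(3)
        data = rng.normal(0, 1.0, (2, 5004))
        base = flag_noise(_rec(data), self.grid)
        more = flag_noise(
            inject_artifacts(_rec(data), [(1, 500, "spike80"), (0, 900, "jump30")]),
            self.grid,
        )
        # adding artifacts never decreases any noisy count
        assert more.noisy_sample_mask.sum() >= base.noisy_sample_mask.sum()
        assert (more.noisy_cycles.sum(axis=1) >= base.noisy_cycles.sum(axis=1)).all()

    def test_matches_bruteforce_recount(self):
        # independent oracle: literal per-sample loop over the three criteria
        rng = np.random.default_rng(4)
        for _ in range(60):
            n = 5 * 50
            data = rng.normal(0, 30.0, (2, n))
            grid = [(i * 50, (i + 1) * 50) for i in range(5)]
            rep = flag_noise(_rec(data), grid)
            for c in range(2):
                mean, sd = data[c].mean(), data[c].std()
                mask = np.zeros(n, dtype=bool)
                for s in range(n):
                    if abs(data[c, s]) > 80.0:
                        mask[s] = True
                    if s > 0 and abs(data[c, s] - data[c, s - 1]) > 30.0:
                        mask[s] = True
                    if abs(data[c, s] - mean) > 5.0 * sd:
                        mask[s] = True
                assert np.array_equal(rep.noisy_sample_mask[c], mask)
                for j, (a, b) in enumerate(grid):
                    assert rep.noisy_cycles[c, j] == (mask[a:b].mean() > 0.02)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            flag_noise(_rec(np.zeros((2, 100))), [])


class TestInterpolation:
    positions = np.array(
        [[0, 0, 1], [0.2, 0, 0.98], [-0.2, 0, 0.98], [0, 0.2, 0.98], [0, -0.2, 0.98]]
    )

    def test_identical_neighbours_reproduce_the_signal(self):
        sig = np.sin(np.linspace(0, 10, 1000))
        data = np.tile(sig, (5, 1))
        data[0] = 99.0  # the bad channel
        rec = _rec(data, positions=self.positions)
        out = interpolate_bad_channels(rec, ["C0"])
        assert np.allclose(out.data[0], sig)

    def test_convex_combination_bounds(self):
        rng = np.random.default_rng(5)
        data = rng.normal(0, 1, (5, 500))
        rec = _rec(data, positions=self.positions)
        out = interpolate_bad_channels(rec, ["C0"])
        lo = data[1:].min(axis=0)
        hi = data[1:].max(axis=0)
        assert np.all(out.data[0] >= lo - 1e-12) and np.all(out.data[0] <= hi + 1e-12)

    def test_empty_bad_list_is_identity(self):
        rec = _rec(np.ones((5, 10)), positions=self.positions)
        assert np.array_equal(interpolate_bad_channels(rec, []).data, rec.data)

    def test_refuses_majority_bad(self):
        rec = _rec(np.ones((5, 10)), positions=self.positions)
        with pytest.raises(ValueError):
            interpolate_bad_channels(rec, ["C0", "C1", "C2"])


class TestExclusions:
    def test_trial_excluded_above_ten_percent_bad_channels(self):
        trials = [
            TrialQC("p1", "t1", n_channels=64, n_bad_channels=7),  # 10.9% > 10%
            TrialQC("p1", "t2", n_channels=64, n_bad_channels=6),  # 9.4%
        ]
        rep = apply_exclusions(trials)
        assert rep.bad_trials == ["t1"]

    def test_count_tolerance_is_plus_minus_three(self):
        ok = TrialQC("p", "a", 64, 0, reported_count=23, true_count=20)
        bad = TrialQC("p", "b", 64, 0, reported_count=24, true_count=20)
        rep = apply_exclusions([ok, bad])
        assert rep.invalid_response_trials == ["b"]

    def test_press_before_target_is_invalid(self):
        early = TrialQC("p", "a", 64, 0, pressed=True, press_time=3.0, target_time=5.0)
        never = TrialQC("p", "b", 64, 0, pressed=False)
        ontime = TrialQC("p", "c", 64, 0, pressed=True, press_time=5.5, target_time=5.0)
        rep = apply_exclusions([early, never, ontime])
        assert set(rep.invalid_response_trials) == {"a", "b"}

    def test_participant_excluded_above_twenty_percent_bad_trials(self):
        # 21% bad trials -> excluded; 20% exactly -> kept
        trials = [
            TrialQC("p1", f"p1t{i}", 100, 11 if i < 21 else 0) for i in range(100)
        ] + [
            TrialQC("p2", f"p2t{i}", 100, 11 if i < 20 else 0) for i in range(100)
        ]
        rep = apply_exclusions(trials)
        assert "p1" in rep.excluded_participants
        assert "p2" not in rep.excluded_participants

    def test_participant_excluded_above_thirty_percent_invalid(self):
        trials = [
            TrialQC("p", f"t{i}", 64, 0, reported_count=30 if i < 4 else 20, true_count=20)
            for i in range(10)
        ]
        rep = apply_exclusions(trials)
        assert "p" in rep.excluded_participants
        assert "invalid" in rep.excluded_participants["p"]
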