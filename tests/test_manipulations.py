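"""Unit tests for the six song manipulations and trial assembly."""

import numpy as np
import pytest
from scipy.fft import rfft

from songpref import (
    AudioClip,
    InfeasibleAdjustmentError,
    InvalidParameterError,
    SongSegmentation,
    Syllable,
    build_session_programs,
    from_units,
    irregularise,
    phase_scramble,
    phase_scrambled_waveform,
    pure_tone_song,
    randomise_syllable_order,
    reverse_song,
    super_regularise,
    to_units,
)
from songpref.manipulations import _sample_bounds, _syllable_rms


SR = 250_000


def seg_from_onsets(onsets, durations, total_s, sr=SR, seed=0):
    """Build a clip with noise-burst syllables at given onsets/durations."""
    rng = np.random.default_rng(seed)
    samples = np.zeros(int(round(total_s * sr)))
    syls = []
    for o, d in zip(onsets, durations):
        i0, i1 = int(round(o * sr)), int(round((o + d) * sr))
        samples[i0:i1] = rng.normal(size=i1 - i0)
        syls.append(Syllable(i0 / sr, i1 / sr))
    clip = AudioClip(samples, sr)
    return clip, SongSegmentation(tuple(syls), clip.duration_s)


class TestUnits:
    def test_pause_arithmetic(self, toy_segmentation):
        clip, seg = toy_segmentation
        us = to_units(clip, seg)
        pauses_s = [u.pause_n / SR for u in us.units]
        np.testing.assert_allclose(pauses_s, [0.10, 0.16])

    def test_empty_segmentation(self):
        clip = AudioClip(np.zeros(1000), SR)
        us = to_units(clip, SongSegmentation((), clip.duration_s))
        assert us.units == ()

    def test_round_trip_bitwise(self):
        # pauses are silence by construction in denoised stimuli, so the
        # unit decomposition reassembles the song sample-for-sample
        from songpref import SongModelParams, generate_song

        clip, seg, _ = generate_song(
            SongModelParams(n_syllables=25, noise_rms=0.0), seed=13
        )
        audio2, seg2 = from_units(to_units(clip, seg))
        assert np.array_equal(audio2.samples, clip.samples)
        np.testing.assert_allclose(seg2.onsets_s, seg.onsets_s, atol=1e-12)


class TestRandomise:
    def test_isi_multiset_conserved_exactly(self, small_song):
        clip, seg, _ = small_song
        out = randomise_syllable_order(clip, seg, seed=3)
        np.testing.assert_allclose(
            np.sort(np.diff(out.seg.onsets_s)), np.sort(np.diff(seg.onsets_s)), atol=1e-12
        )

    def test_waveform_multiset_conserved(self, small_song):
        clip, seg, _ = small_song
        out = randomise_syllable_order(clip, seg, seed=3)
        w_in = {np.asarray(clip.samples[a:b]).tobytes()
                for a, b in zip(*_sample_bounds(clip, seg))}
        w_out = {np.asarray(out.audio.samples[a:b]).tobytes()
                 for a, b in zip(*_sample_bounds(out.audio, out.seg))}
        assert w_in == w_out

    def test_matches_independently_applied_permutation(self, small_song):
        clip, seg, _ = small_song
        out = randomise_syllable_order(clip, seg, seed=11)
        us = to_units(clip, seg)
        order = np.random.default_rng(11).permutation(len(us.units) - 1)
        expected_durations = [us.units[i].duration_n for i in order] + [
            us.units[-1].duration_n
        ]
        got_durations = [
            round((s.offset_s - s.onset_s) * SR) for s in out.seg
        ]
        assert got_durations == expected_durations

    def test_single_syllable_identity_with_warning(self):
        clip, seg = seg_from_onsets([0.1], [0.02], 0.3)
        with pytest.warns(UserWarning):
            out = randomise_syllable_order(clip, seg, seed=0)
        assert np.array_equal(out.audio.samples, clip.samples)

    def test_seeded_determinism(self, small_song):
        clip, seg, _ = small_song
        a = randomise_syllable_order(clip, seg, seed=5)
        b = randomise_syllable_order(clip, seg, seed=5)
        assert np.array_equal(a.audio.samples, b.audio.samples)


class TestReverse:
    def test_involution_bitwise(self, small_song):
        clip, seg, _ = small_song
        back = reverse_song(reverse_song(clip, seg).audio, seg)
        assert np.array_equal(back.audio.samples, clip.samples)

    def test_palindrome_fixed_point(self):
        x = np.zeros(1001)
        x[498:503] = [0.2, 0.5, 1.0, 0.5, 0.2]
        clip = AudioClip(x, SR)
        assert np.array_equal(reverse_song(clip).audio.samples, x)

    def test_chirp_direction_reversed(self):
        t = np.arange(int(0.02 * SR)) / SR
        up = AudioClip(np.sin(2 * np.pi * (68_000 * t + 0.5 * (16_000 / 0.02) * t**2)), SR)
        rev = reverse_song(up).audio
        # instantaneous frequency at the start of the reversed chirp ~ 84 kHz
        from songpref import Syllable, peak_frequency

        early = peak_frequency(rev, Syllable(0.0, 0.004))
        late = peak_frequency(rev, Syllable(0.016, 0.02))
        assert early > late
        # each 4 ms segment spans 3.2 kHz of the sweep
        assert 80_000 <= early <= 84_500
        assert 67_500 <= late <= 72_000


class TestPhaseScramble:
    def test_magnitude_spectrum_preserved(self, small_song):
        clip, seg, _ = small_song
        scram = phase_scrambled_waveform(clip, seed=5)
        m0 = np.abs(rfft(clip.samples))
        m1 = np.abs(rfft(scram.samples))
        assert np.max(np.abs(m1 - m0) / (m0 + 1e-30)) < 1e-6

    def test_silent_outside_syllables(self, small_song):
        clip, seg, _ = small_song
        out = phase_scramble(clip, seg, seed=5)
        mask = np.ones(clip.n_samples, dtype=bool)
        for a, b in zip(*_sample_bounds(clip, seg)):
            mask[a:b] = False
        assert np.all(out.audio.samples[mask] == 0.0)

    def test_mean_syllable_rms_matched(self, small_song):
        clip, seg, _ = small_song
        out = phase_scramble(clip, seg, seed=5)
        on, off = _sample_bounds(clip, seg)
        r_in = _syllable_rms(clip.samples, on, off).mean()
        r_out = _syllable_rms(out.audio.samples, on, off).mean()
        assert abs(r_out / r_in - 1.0) < 0.01

    def test_short_syllable_ramp_truncated_with_warning(self):
        clip, seg = seg_from_onsets([0.1], [0.0008], 0.3)  # shorter than 2 ramps
        with pytest.warns(UserWarning):
            out = phase_scramble(clip, seg, seed=1)
        assert out.audio.n_samples == clip.n_samples


class TestPureTone:
    def test_all_peak_frequencies_at_tone(self, small_song):
        from songpref import peak_frequency

        clip, seg, _ = small_song
        out = pure_tone_song(seg, clip, tone_hz=76_000.0)
        bin_hz = SR / 512
        for s in out.seg:
            assert abs(peak_frequency(out.audio, s) - 76_000) <= bin_hz

    def test_timing_identical_to_input(self, small_song):
        clip, seg, _ = small_song
        out = pure_tone_song(seg, clip)
        np.testing.assert_array_equal(out.seg.onsets_s, seg.onsets_s)
        np.testing.assert_array_equal(out.seg.offsets_s, seg.offsets_s)

    def test_linear_ramps(self):
        clip, seg = seg_from_onsets([0.1], [0.02], 0.3)
        out = pure_tone_song(seg, clip)
        i0 = int(0.1 * SR)
        ramp_n = int(0.0005 * SR)
        n = ramp_n * 4
        got = np.abs(out.audio.samples[i0 : i0 + n])
        model = np.abs(np.sin(2 * np.pi * 76_000 * np.arange(n) / SR)) * np.minimum(
            np.arange(n) / ramp_n, 1.0
        )
        assert np.corrcoef(got, model)[0, 1] > 0.98

    def test_rms_matched(self, small_song):
        clip, seg, _ = small_song
        out = pure_tone_song(seg, clip)
        on, off = _sample_bounds(clip, seg)
        ratio = _syllable_rms(out.audio.samples, on, off).mean() / _syllable_rms(
            clip.samples, on, off
        ).mean()
        assert abs(ratio - 1.0) < 0.01

    def test_tone_above_nyquist_rejected(self, small_song):
        clip, seg, _ = small_song
        with pytest.raises(InvalidParameterError):
            pure_tone_song(seg, clip, tone_hz=130_000.0)


class TestIrregularise:
    def test_duration_conserved_exactly(self, small_song):
        clip, seg, _ = small_song
        out = irregularise(clip, seg, seed=9)
        assert out.audio.n_samples == clip.n_samples

    def test_syllable_waveforms_and_order_unchanged(self, small_song):
        clip, seg, _ = small_song
        out = irregularise(clip, seg, seed=9)
        on_i, off_i = _sample_bounds(clip, seg)
        on_o, off_o = _sample_bounds(out.audio, out.seg)
        for (a, b), (c, d) in zip(zip(on_i, off_i), zip(on_o, off_o)):
            assert np.array_equal(clip.samples[a:b], out.audio.samples[c:d])

    def test_seeded_determinism(self, small_song):
        clip, seg, _ = small_song
        a = irregularise(clip, seg, seed=4)
        b = irregularise(clip, seg, seed=4)
        assert np.array_equal(a.audio.samples, b.audio.samples)


class TestSuperRegularise:
    def test_hand_computed_grid_placement(self):
        # ISIs [0.10, 0.14] -> median m = 0.12; all durations < m
        clip, seg = seg_from_onsets([0.0, 0.10, 0.24], [0.02] * 3, 0.5)
        out = super_regularise(clip, seg)
        np.testing.assert_allclose(out.seg.onsets_s, [0.0, 0.12, 0.24], atol=1e-9)

    def test_skip_a_cycle_for_long_syllable(self):
        # ISIs [0.12, 0.18, 0.12] -> m = 0.12; middle syllable 0.15 > m
        clip, seg = seg_from_onsets(
            [0.0, 0.12, 0.30, 0.42], [0.02, 0.15, 0.02, 0.02], 0.8
        )
        out = super_regularise(clip, seg)
        gaps = np.diff(out.seg.onsets_s)
        np.testing.assert_allclose(gaps, [0.12, 0.24, 0.12], atol=1e-9)

    def test_within_bout_iqr_zero_without_skips(self):
        clip, seg = seg_from_onsets([0.0, 0.1, 0.22, 0.31], [0.02] * 4, 0.6)
        out = super_regularise(clip, seg)
        gaps = np.diff(out.seg.onsets_s)
        assert np.ptp(gaps) < 1e-9

    def test_duration_conserved(self, small_song):
        clip, seg, _ = small_song
        out = super_regularise(clip, seg)
        assert out.audio.n_samples == clip.n_samples

    def test_waveforms_preserved(self, small_song):
        clip, seg, _ = small_song
        out = super_regularise(clip, seg)
        on_i, off_i = _sample_bounds(clip, seg)
        on_o, off_o = _sample_bounds(out.audio, out.seg)
        for (a, b), (c, d) in zip(zip(on_i, off_i), zip(on_o, off_o)):
            assert np.array_equal(clip.samples[a:b], out.audio.samples[c:d])

    def test_infeasible_compression_raises(self):
        # median-ISI grid inflates the bout by more than the available
        # terminal silence and there are no inter-bout gaps to give back
        clip, seg = seg_from_onsets([0.0, 0.04, 0.10, 0.16], [0.02] * 4, 0.19)
        with pytest.raises(InfeasibleAdjustmentError):
            super_regularise(clip, seg)


class TestSessionPrograms:
    def test_sides_alternate(self):
        for seed in range(20):
            programs = build_session_programs(seed=seed)
            sides = [p.playback_side for p in programs]
            assert sides in (
                ["left", "right", "left", "right"],
                ["right", "left", "right", "left"],
            )

    def test_jitter_in_range(self):
        programs = build_session_programs(seed=1)
        for p in programs:
            assert all(0.020 <= j <= 0.090 for j in p.jitter_s)
            assert len(p.jitter_s) == 7

    def test_song_order_is_permutation(self):
        for p in build_session_programs(seed=2):
            assert sorted(p.song_order) == list(range(7))

    def test_first_song_marginally_uniform(self):
        # chi-square on the first position over many seeds
        from scipy.stats import chisquare

        firsts = [build_session_programs(seed=s)[0].song_order[0] for s in range(3500)]
        counts = np.bincount(firsts, minlength=7)
        assert chisquare(counts).pvalue > 0.01
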