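"""Feature pipeline: rate relabeling, framing, STFT/MSFB/MFCC, rendering."""

import numpy as np
import pytest
from matplotlib import colormaps
from scipy.fft import idct
from scipy.signal.windows import hann

from echoscope.features import (FeatureConfig, SpectrogramTensor,
                                compute_mfcc, compute_msfb, compute_stft,
                                mel_filterbank, n_stft_frames, relabel_rate,
                                render_input_image, segment_audio,
                                waveform_to_images)

CFG = FeatureConfig()


class TestRelabelRate:
    def test_samples_unchanged(self, rng):
        wave = rng.normal(size=1000)
        out, fs = relabel_rate(wave, 384_000, 44_100)
        assert fs == 44_100
        np.testing.assert_array_equal(out, wave)

    def test_frequency_scaling_oracle(self):
        """A 100 kHz tone at 384 kHz native reads as ~11.48 kHz after
        relabeling — time expansion shifts frequencies by fs_target/fs_native."""
        t = np.arange(384_000) / 384_000
        tone = np.sin(2 * np.pi * 100e3 * t)
        wave, fs = relabel_rate(tone, 384_000, 44_100)
        seg = wave[:CFG.segment_samples]
        stft = compute_stft(seg, CFG)
        peaks = stft.freq_axis[np.argmax(stft.values, axis=0)]
        expected = 100e3 * 44_100 / 384_000  # 11484.375 Hz
        bin_hz = 44_100 / CFG.fft_size
        assert np.all(np.abs(peaks - expected) <= bin_hz)

    def test_noop_and_error(self):
        wave = np.ones(10)
        out, fs = relabel_rate(wave, 44_100, 44_100)
        assert fs == 44_100 and out is not None
        with pytest.raises(ValueError):
            relabel_rate(wave, 22_050, 44_100)


class TestSegmentAudio:
    @pytest.mark.parametrize("seconds,keep,expected", [
        (9.0, False, 3), (10.0, False, 3), (10.0, True, 4),
        (2.0, True, 1), (2.0, False, 0)])
    def test_segment_counts(self, seconds, keep, expected):
        fs = 1000
        wave = np.ones(int(seconds * fs))
        segs = segment_audio(wave, fs, 3.0, keep_partial=keep)
        assert len(segs) == expected
        assert all(s.size == 3000 for s in segs)

    def test_partial_is_zero_padded(self):
        segs = segment_audio(np.ones(2000), 1000, 3.0, keep_partial=True)
        assert segs[0][:2000].all() and not segs[0][2000:].any()

    def test_empty_waveform(self):
        assert segment_audio(np.array([]), 1000, 3.0) == []


class TestComputeStft:
    def test_framing_formula_on_reference_segment(self):
        """A 3-s segment at 44.1 kHz gives 1 + (132300-1102)//441 = 298
        frames; 25/10 ms windows at 44.1 kHz are 1102/441 samples, a 661
        sample (~15 ms) overlap."""
        assert CFG.win_length == 1102 and CFG.hop_length == 441
        assert CFG.win_length - CFG.hop_length == 661  # ~15 ms overlap
        stft = compute_stft(np.zeros(132_300), CFG)
        assert stft.values.shape == (CFG.fft_size // 2 + 1, 298)
        assert not stft.values.any()

    @pytest.mark.parametrize("n_samples", [1102, 5000, 44_100, 132_300])
    def test_frame_count_closed_form(self, n_samples, rng):
        stft = compute_stft(rng.normal(size=n_samples), CFG)
        assert stft.values.shape[1] == n_stft_frames(n_samples, CFG)
        assert np.all(stft.values >= 0)

    def test_sine_argmax_bin(self):
        t = np.arange(44_100) / 44_100
        stft = compute_stft(np.sin(2 * np.pi * 10_000 * t), CFG)
        expected_bin = round(10_000 * CFG.fft_size / 44_100)
        assert np.all(np.argmax(stft.values, axis=0) == expected_bin)

    def test_window_dc_energy(self):
        """Constant input 1: DC power of a frame equals (sum of Hann)^2."""
        stft = compute_stft(np.ones(2 * CFG.win_length), CFG)
        expected = hann(CFG.win_length, sym=False).sum() ** 2
        np.testing.assert_allclose(stft.values[0, 0], expected, rtol=1e-9)

    def test_too_short_segment_raises(self):
        with pytest.raises(ValueError):
            compute_stft(np.zeros(CFG.win_length - 1), CFG)


class TestComputeMsfb:
    def test_zero_power_maps_to_log_floor(self):
        stft = compute_stft(np.zeros(132_300), CFG)
        msfb = compute_msfb(stft, CFG)
        assert msfb.values.shape[0] == 128
        np.testing.assert_allclose(msfb.values, np.log(CFG.log_floor))

    def test_single_bin_hits_at_most_two_adjacent_filters(self):
        """Triangular filters overlap so one FFT bin lands in <= 2 filters."""
        power = np.zeros((CFG.fft_size // 2 + 1, 3))
        power[500] = 1.0
        stft = SpectrogramTensor(power, "STFT")
        msfb = compute_msfb(stft, CFG)
        active = np.flatnonzero(msfb.values[:, 0] >
                                np.log(CFG.log_floor) + 1e-6)
        assert 1 <= active.size <= 2
        assert np.all(np.diff(active) == 1)

    def test_log_shift_under_power_scaling(self, rng):
        power = rng.random((CFG.fft_size // 2 + 1, 5)) + 0.5
        stft = SpectrogramTensor(power, "STFT")
        base = compute_msfb(stft, CFG).values
        scaled = compute_msfb(SpectrogramTensor(8 * power, "STFT"), CFG).values
        np.testing.assert_allclose(scaled - base, np.log(8), atol=1e-6)

    def test_kind_and_size_validation(self):
        with pytest.raises(ValueError):
            compute_msfb(SpectrogramTensor(np.zeros((5, 5)), "MSFB"), CFG)
        with pytest.raises(ValueError):
            mel_filterbank(FeatureConfig(n_mels=2000, fft_size=2048))


class TestComputeMfcc:
    def test_constant_column_closed_form(self):
        """Orthonormal DCT-II of a constant column c: coefficient 0 is
        c*sqrt(128), all higher coefficients vanish."""
        c = 3.7
        msfb = SpectrogramTensor(np.full((128, 4), c), "MSFB")
        mfcc = compute_mfcc(msfb, CFG)
        assert mfcc.values.shape == (20, 4)
        np.testing.assert_allclose(mfcc.values[0], c * np.sqrt(128),
                                   rtol=1e-12)
        np.testing.assert_allclose(mfcc.values[1:], 0, atol=1e-10)

    def test_full_order_roundtrip(self, rng):
        mat = rng.normal(size=(128, 6))
        cfg = FeatureConfig(n_mfcc=128)
        coeffs = compute_mfcc(SpectrogramTensor(mat, "MSFB"), cfg)
        back = idct(coeffs.values, type=2, norm="ortho", axis=0)
        np.testing.assert_allclose(back, mat, atol=1e-10)

    def test_kind_validation(self):
        with pytest.raises(ValueError):
            compute_mfcc(SpectrogramTensor(np.zeros((5, 5)), "STFT"), CFG)


class TestRenderInputImage:
    def test_shape_and_range(self, rng):
        img = render_input_image(rng.normal(size=(128, 298)))
        assert img.kind == "image"
        assert img.values.shape == (112, 170, 3)
        assert img.values.min() >= 0 and img.values.max() <= 1

    def test_constant_input_maps_to_colormap_midpoint(self):
        img = render_input_image(np.full((50, 60), 2.5)).values
        mid = np.asarray(colormaps["viridis"](0.5)[:3])
        np.testing.assert_allclose(img, np.broadcast_to(mid, img.shape),
                                   atol=1e-6)

    def test_small_ramp_matches_direct_lookup(self):
        """Brute-force oracle on a 2x2 ramp: rendering without resize is
        exactly min-max normalization + colormap lookup (flipped so low
        frequencies sit at the bottom)."""
        mat = np.array([[0.0, 1.0], [2.0, 3.0]])
        rendered = render_input_image(mat, out_shape=(2, 2)).values
        expected = colormaps["viridis"](mat / 3.0)[..., :3][::-1]
        np.testing.assert_allclose(rendered, expected, atol=1e-6)


class TestPipeline:
    def test_native_recording_to_images(self):
        """0.7 s at 384 kHz time-expands to ~6.1 nominal seconds -> 2 images."""
        t = np.arange(int(0.7 * 384_000)) / 384_000
        wave = np.sin(2 * np.pi * 60e3 * t)
        images = waveform_to_images(wave, 384_000)
        assert len(images) == 2
        for img in images:
            assert img.shape == (112, 170, 3)
            assert img.dtype == np.float32
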