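"""Synthetic call generator: spectral placement, pulse trains, determinism."""

import numpy as np
import pytest

from echoscope.synthetic_calls import (CallTemplate, RecordingSpec,
                                       default_templates, generate_dataset,
                                       synthesize_call, synthesize_recording,
                                       write_wav_dataset)

FS = 384_000


def _frame_peak_freq(wave, fs, start, length):
    """Closed-form oracle: argmax frequency of one rectangular frame."""
    frame = wave[start:start + length]
    spec = np.abs(np.fft.rfft(frame))
    return np.argmax(spec) * fs / length


class TestSynthesizeCall:
    def test_fm_sweep_length_and_ridge(self):
        """A linear 80->40 kHz chirp has its spectral ridge at the
        instantaneous frequency of the sweep at both ends."""
        tpl = CallTemplate("t", "FM_sweep", 80e3, 40e3, 0.005, 0.1,
                           amplitude_envelope="rect")
        wave = synthesize_call(tpl, FS, seed=0)
        assert wave.size == 1920  # round(0.005 * 384000)
        assert np.abs(wave).max() <= 1.0
        n = 256  # 0.67 ms frames; sweep moves ~5.3 kHz within one frame
        bin_hz = FS / n
        # instantaneous frequency at the first/last frame centers
        for start, t_mid in ((0, n / 2 / FS), (wave.size - n,
                                               (wave.size - n / 2) / FS)):
            expected = 80e3 + (40e3 - 80e3) * t_mid / 0.005
            peak = _frame_peak_freq(wave, FS, start, n)
            assert abs(peak - expected) <= 2 * bin_hz

    def test_cf_dominant_bin(self):
        """A constant-frequency call concentrates at the analytic FFT bin."""
        tpl = CallTemplate("t", "CF", 50e3, 50e3, 0.010, 0.1,
                           amplitude_envelope="rect")
        wave = synthesize_call(tpl, FS, seed=0)
        n = wave.size  # 3840
        spec = np.abs(np.fft.rfft(wave))
        assert np.argmax(spec) == round(50e3 / (FS / n))

    def test_zero_amplitude_yields_silence(self):
        tpl = CallTemplate("t", "FM_sweep", 80e3, 40e3, 0.005, 0.1)
        assert not synthesize_call(tpl, FS, seed=0, amplitude=0.0).any()

    def test_harmonics_above_nyquist_are_clipped(self):
        """Harmonic content above fs/2 is removed, not aliased."""
        tpl = CallTemplate("t", "CF", 150e3, 150e3, 0.005, 0.1, harmonics=3,
                           amplitude_envelope="rect")
        wave = synthesize_call(tpl, FS, seed=0)
        spec = np.abs(np.fft.rfft(wave))
        freqs = np.fft.rfftfreq(wave.size, 1 / FS)
        # 300 kHz and 450 kHz harmonics exceed the 192 kHz Nyquist
        assert spec[freqs > 160e3].max() < 0.01 * spec.max()

    @pytest.mark.parametrize("bad", [
        dict(f_start=0.0), dict(f_end=400e3), dict(pulse_duration=-1.0),
        dict(pulse_duration=0.2), dict(harmonics=0),
        dict(call_kind="chirp"),
    ])
    def test_invalid_template_rejected(self, bad):
        base = dict(species_name="t", call_kind="FM_sweep", f_start=80e3,
                    f_end=40e3, pulse_duration=0.005,
                    inter_pulse_interval=0.1)
        base.update(bad)
        with pytest.raises(ValueError):
            CallTemplate(**base).validate(FS)


class TestSynthesizeRecording:
    def _count_pulse_runs(self, wave):
        active = np.abs(wave) > 1e-9
        return int(np.sum(np.diff(active.astype(int)) == 1)
                   + (1 if active[0] else 0))

    @pytest.mark.parametrize("duration,ipi,expected", [
        (3.0, 0.100, 30), (1.0, 0.060, 16), (0.5, 0.090, 5)])
    def test_pulse_count_conservation(self, duration, ipi, expected):
        """floor(duration / IPI) pulses, verified by counting bursts."""
        assert expected == int(np.floor(duration / ipi))
        tpl = CallTemplate("t", "FM_sweep", 80e3, 40e3, 0.005, ipi)
        wave, _ = synthesize_recording(
            RecordingSpec(tpl, duration, snr_db=np.inf, seed=0))
        assert self._count_pulse_runs(wave) == expected

    def test_infinite_snr_equals_tiled_pulses(self):
        tpl = CallTemplate("t", "FM_sweep", 80e3, 40e3, 0.005, 0.1)
        wave, fs = synthesize_recording(
            RecordingSpec(tpl, 0.35, snr_db=np.inf, seed=7))
        pulse = synthesize_call(tpl, fs, seed=7)
        manual = np.zeros(wave.size)
        for k in range(3):
            start = int(round(k * 0.1 * fs))
            manual[start:start + pulse.size] = pulse
        np.testing.assert_allclose(wave, manual, atol=1e-12)

    def test_snr_calibration(self):
        """Noise power matches the requested SNR over pulse regions."""
        tpl = CallTemplate("t", "CF", 50e3, 50e3, 0.050, 0.060,
                           amplitude_envelope="rect")
        clean, fs = synthesize_recording(
            RecordingSpec(tpl, 3.0, snr_db=np.inf, seed=3))
        noisy, _ = synthesize_recording(
            RecordingSpec(tpl, 3.0, snr_db=10.0, seed=3))
        mask = np.abs(clean) > 0
        p_sig = np.mean(clean[mask] ** 2)
        p_noise = np.mean((noisy - clean)[~mask] ** 2)
        snr = 10 * np.log10(p_sig / p_noise)
        assert abs(snr - 10.0) < 0.5

    def test_seed_contract(self):
        tpl = CallTemplate("t", "FM_sweep", 80e3, 40e3, 0.005, 0.1)
        w1, _ = synthesize_recording(RecordingSpec(tpl, 0.5, 20.0, seed=1))
        w1b, _ = synthesize_recording(RecordingSpec(tpl, 0.5, 20.0, seed=1))
        w2, _ = synthesize_recording(RecordingSpec(tpl, 0.5, 20.0, seed=2))
        np.testing.assert_array_equal(w1, w1b)
        assert not np.array_equal(w1, w2)

    def test_too_short_duration_warns_noise_only(self):
        tpl = CallTemplate("t", "FM_sweep", 80e3, 40e3, 0.005, 0.1)
        with pytest.warns(UserWarning):
            wave, _ = synthesize_recording(
                RecordingSpec(tpl, 0.05, snr_db=20.0, seed=0))
        assert wave.size == int(round(0.05 * FS))


class TestGenerateDataset:
    def test_balanced_counts(self):
        tpls = default_templates()[:4]
        segs = generate_dataset(tpls, [10] * 4, segment_s=0.3, seed=0)
        assert len(segs) == 40
        labels = [s.label for s in segs]
        assert all(labels.count(c) == 10 for c in range(4))

    def test_imbalance_ratio_matches_reference_skew(self):
        """Counts in the published 1666:30 proportion give a ~55:1 skew."""
        tpls = default_templates()[:2]
        counts = [167, 3]  # 1666:30 scaled down tenfold
        segs = generate_dataset(tpls, counts, segment_s=0.3, seed=0)
        labels = np.asarray([s.label for s in segs])
        observed = [int((labels == c).sum()) for c in range(2)]
        assert observed == counts
        assert 55 <= max(observed) / min(observed) <= 60

    def test_deterministic_wav_output(self, tmp_path):
        tpls = default_templates()[:2]
        for d in ("a", "b"):
            segs = generate_dataset(tpls, [2, 2], segment_s=0.3, seed=9)
            write_wav_dataset(segs, tmp_path / d)
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_errors(self):
        with pytest.raises(ValueError):
            generate_dataset([], [], seed=0)
        with pytest.raises(ValueError):
            generate_dataset(default_templates()[:1], [0], seed=0)
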