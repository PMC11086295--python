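"""Synthetic echolocation recordings with the structure the classifier assumes.

Bat echolocation pulses are short (1–10 ms) ultrasonic events, repeated at a
species-typical rate, whose frequency content is either a downward
frequency-modulated (FM) sweep, a constant-frequency (CF) tone, or an FM sweep
followed by a CF tail. Species occupy different frequency bands between
roughly 20 and 150 kHz and differ in sweep shape, pulse duration and pulse
repetition rate — exactly the cues a spectrogram classifier exploits. This
module synthesizes labeled pulse trains with those properties, recorded
natively at 384 kHz, plus additive white Gaussian background noise at a
configurable SNR, and can emit datasets with a configurable class imbalance.

The eight default templates are fixture constants chosen to span 20–150 kHz
with partially overlapping bands; they are deliberately synthetic and make no
claim about any real species' parameters.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal.windows import hann

__all__ = [
    "CallTemplate", "RecordingSpec", "LabeledSegment", "default_templates",
    "synthesize_call", "synthesize_recording", "generate_dataset",
    "write_wav_dataset",
]

#: Native sampling rate of the emulated ultrasonic microphone, Hz.
NATIVE_FS = 384_000


@dataclass(frozen=True)
class CallTemplate:
    """Parametric description of one species' echolocation pulse."""

    species_name: str
    call_kind: str  # "FM_sweep" | "CF" | "FM_CF"
    f_start: float  # Hz, frequency at pulse onset
    f_end: float    # Hz, frequency at pulse offset
    pulse_duration: float        # s
    inter_pulse_interval: float  # s
    harmonics: int = 1
    amplitude_envelope: str = "hann"  # "rect" | "hann"
    #: fraction of the pulse occupied by the FM part for FM_CF calls
    fm_fraction: float = 0.6

    def validate(self, fs_native: float = NATIVE_FS) -> None:
        nyq = fs_native / 2
        if not (0 < self.f_start < nyq and 0 < self.f_end < nyq):
            raise ValueError(
                f"{self.species_name}: frequencies must lie in (0, {nyq}) Hz")
        if self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be positive")
        if self.pulse_duration >= self.inter_pulse_interval:
            raise ValueError("pulse_duration must be < inter_pulse_interval")
        if self.harmonics < 1:
            raise ValueError("harmonics must be >= 1")
        if self.call_kind not in ("FM_sweep", "CF", "FM_CF"):
            raise ValueError(f"unknown call_kind {self.call_kind!r}")
        if self.amplitude_envelope not in ("rect", "hann"):
            raise ValueError(
                f"unknown amplitude_envelope {self.amplitude_envelope!r}")


@dataclass(frozen=True)
class RecordingSpec:
    """One synthetic field recording: a pulse train plus background noise."""

    template: CallTemplate
    duration: float            # s
    snr_db: float = 20.0       # SNR over pulse regions; +inf disables noise
    fs_native: int = NATIVE_FS
    seed: int = 0

    def validate(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        self.template.validate(self.fs_native)


@dataclass
class LabeledSegment:
    waveform: np.ndarray
    fs: int
    label: int
    species: str


def default_templates() -> list[CallTemplate]:
    """Eight synthetic species templates spanning 20–150 kHz."""
    return [
        CallTemplate("Synthspecies fm150", "FM_sweep", 150e3, 80e3, 0.003, 0.060),
        CallTemplate("Synthspecies fm120", "FM_sweep", 120e3, 55e3, 0.004, 0.080),
        CallTemplate("Synthspecies fm90", "FM_sweep", 90e3, 45e3, 0.005, 0.090),
        CallTemplate("Synthspecies fm65", "FM_sweep", 65e3, 32e3, 0.006, 0.100),
        CallTemplate("Synthspecies cf110", "CF", 110e3, 110e3, 0.008, 0.070),
        CallTemplate("Synthspecies cf80", "CF", 80e3, 80e3, 0.010, 0.080, harmonics=2),
        CallTemplate("Synthspecies fmcf55", "FM_CF", 55e3, 28e3, 0.008, 0.090),
        CallTemplate("Synthspecies fm35", "FM_sweep", 35e3, 20e3, 0.007, 0.120),
    ]


def _instantaneous_frequency(template: CallTemplate, t: np.ndarray) -> np.ndarray:
    """Fundamental instantaneous frequency over the pulse, Hz."""
    dur = template.pulse_duration
    if template.call_kind == "CF":
        return np.full_like(t, template.f_start)
    if template.call_kind == "FM_sweep":
        return template.f_start + (template.f_end - template.f_start) * t / dur
    # FM_CF: linear sweep over the first fm_fraction, then hold f_end
    t_fm = template.fm_fraction * dur
    f = template.f_start + (template.f_end - template.f_start) * np.minimum(
        t, t_fm) / t_fm
    return f


def synthesize_call(template: CallTemplate, fs: float, seed: int = 0,
                    amplitude: float = 0.9) -> np.ndarray:
    """Synthesize one pulse at sampling rate ``fs``.

    The waveform has ``round(pulse_duration * fs)`` samples in [-1, 1]. For
    FM sweeps the instantaneous frequency moves linearly from ``f_start`` to
    ``f_end``. Harmonic components are masked wherever their instantaneous
    frequency would exceed the Nyquist frequency rather than aliasing.
    Harmonic phases are drawn from ``seed``, so the call is deterministic
    given (template, fs, seed).
    """
    template.validate(fs_native=max(fs, 2 * max(template.f_start,
                                                template.f_end) + 1))
    if fs <= 0:
        raise ValueError("fs must be positive")
    n = int(round(template.pulse_duration * fs))
    t = np.arange(n) / fs
    f_inst = _instantaneous_frequency(template, t)
    # phase = 2*pi * cumulative integral of f_inst
    phase = 2 * np.pi * np.cumsum(f_inst) / fs
    rng = np.random.default_rng(seed)
    wave = np.zeros(n)
    for h in range(1, template.harmonics + 1):
        phi0 = rng.uniform(0, 2 * np.pi)
        component = np.sin(h * phase + phi0) / h
        component[h * f_inst >= fs / 2] = 0.0  # clip above Nyquist
        wave += component
    if template.amplitude_envelope == "hann" and n > 1:
        wave *= hann(n, sym=True)
    peak = np.abs(wave).max()
    if peak > 0:
        wave *= amplitude / peak
    return wave


def synthesize_recording(spec: RecordingSpec) -> tuple[np.ndarray, int]:
    """Render a full recording: pulses every IPI plus Gaussian noise.

    Noise is scaled so that ``10*log10(P_signal / P_noise) = snr_db`` where
    ``P_signal`` is the mean power over pulse regions. The same seed yields
    identical samples; different seeds share pulse onsets (which are
    deterministic) but differ in noise.
    """
    spec.validate()
    fs = spec.fs_native
    tpl = spec.template
    n_total = int(round(spec.duration * fs))
    n_pulses = int(np.floor(spec.duration / tpl.inter_pulse_interval))
    rng = np.random.default_rng(spec.seed)
    out = np.zeros(n_total)
    pulse = synthesize_call(tpl, fs, seed=spec.seed)
    if n_pulses == 0:
        warnings.warn("duration shorter than one inter-pulse interval; "
                      "emitting noise-only recording", stacklevel=2)
    mask = np.zeros(n_total, dtype=bool)
    for k in range(n_pulses):
        start = int(round(k * tpl.inter_pulse_interval * fs))
        stop = min(start + pulse.size, n_total)
        out[start:stop] += pulse[:stop - start]
        mask[start:stop] = True
    if np.isfinite(spec.snr_db) and mask.any():
        p_signal = np.mean(out[mask] ** 2)
        sigma = np.sqrt(p_signal / 10.0 ** (spec.snr_db / 10.0))
        out = out + rng.normal(0.0, sigma, n_total)
    np.clip(out, -1.0, 1.0, out=out)
    return out, fs


def generate_dataset(templates: list[CallTemplate],
                     per_class_counts: list[int],
                     segment_s: float = 3.0,
                     snr_db: float = 20.0,
                     fs_native: int = NATIVE_FS,
                     seed: int = 0) -> list[LabeledSegment]:
    """Generate a labeled dataset of fixed-length recordings.

    Emits exactly ``per_class_counts[i]`` segments of ``segment_s`` seconds
    for class ``i``. Counts are free, so any class imbalance — including the
    roughly 60:1 skew of real passive-monitoring archives — can be emulated.
    """
    if not templates:
        raise ValueError("template list must not be empty")
    if len(per_class_counts) != len(templates):
        raise ValueError("per_class_counts must match templates")
    if any(c < 1 for c in per_class_counts):
        raise ValueError("per-class counts must be >= 1")
    root = np.random.SeedSequence(seed)
    segments: list[LabeledSegment] = []
    for label, (tpl, count) in enumerate(zip(templates, per_class_counts)):
        child_seeds = root.spawn(1)[0].generate_state(count) % (2 ** 31)
        for j in range(count):
            spec = RecordingSpec(tpl, duration=segment_s, snr_db=snr_db,
                                 fs_native=fs_native,
                                 seed=int(child_seeds[j]))
            wave, fs = synthesize_recording(spec)
            segments.append(LabeledSegment(wave, fs, label, tpl.species_name))
    return segments


def write_wav_dataset(segments: list[LabeledSegment], out_dir: str | Path,
                      manifest_name: str = "manifest.csv") -> Path:
    """Write 16-bit PCM WAV files plus a CSV manifest; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / manifest_name
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "species", "fs_native"])
        for i, seg in enumerate(segments):
            name = f"seg_{i:05d}_c{seg.label}.wav"
            pcm = np.clip(seg.waveform, -1, 1)
            wavfile.write(out / name, seg.fs,
                          (pcm * 32767).astype(np.int16))
            writer.writerow([name, seg.species, seg.fs])
    return manifest
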