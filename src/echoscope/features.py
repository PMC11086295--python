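"""Raw audio to model-ready spectrogram images.

The pipeline is fixed: rate relabeling, 3-s segmentation, short-time Fourier
transform (Hann window, 25 ms / 10 ms hop, i.e. 15 ms overlap), a 128-band
mel-scaled filter bank (MSFB) with log compression, optionally a DCT keeping
20 MFCC coefficients, and finally rendering to a 112x170x3 color image for
the CNN.

Rate relabeling, not resampling: ultrasonic recordings made at 384 kHz are
reinterpreted at a 44.1 kHz nominal rate with the samples untouched
(time-expansion semantics). A 160 kHz component then reads as
160 * 44100/384000 ~ 18.4 kHz — the call pattern shifts into the audible
band without its shape changing, and no anti-aliasing filter ever removes
the ultrasonic content. Segmentation into 3-s windows happens on the
relabeled (nominal) time axis, so one model input always covers
``round(3 * 44100) = 132300`` samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib import colormaps
from scipy.fft import dct, rfft, rfftfreq
from scipy.signal.windows import hann
from skimage.transform import resize as _sk_resize

__all__ = [
    "FeatureConfig", "SpectrogramTensor", "relabel_rate", "segment_audio",
    "compute_stft", "compute_msfb", "compute_mfcc", "render_input_image",
    "mel_filterbank", "waveform_to_images", "build_image_dataset",
    "n_stft_frames",
]


@dataclass(frozen=True)
class FeatureConfig:
    """DSP parameters of the feature pipeline.

    Defaults reproduce the reference configuration: 44.1 kHz nominal rate,
    3-s segments, 25 ms Hann window with 10 ms hop, 128 mel filters, 20
    MFCC coefficients, 2048-point zero-padded FFT.
    """

    fs_target: int = 44_100
    segment_s: float = 3.0
    win_ms: float = 25.0
    hop_ms: float = 10.0
    n_mels: int = 128
    n_mfcc: int = 20
    fft_size: int = 2048
    log_floor: float = 1e-10
    center: bool = False  # centered (half-window padded) framing if True

    def __post_init__(self):
        if self.hop_ms >= self.win_ms:
            raise ValueError("hop_ms must be < win_ms")
        if self.n_mfcc > self.n_mels:
            raise ValueError("n_mfcc must be <= n_mels")
        if self.fft_size < self.win_length:
            raise ValueError("fft_size must be >= window length")

    @property
    def win_length(self) -> int:
        return int(round(self.win_ms * self.fs_target / 1000.0))

    @property
    def hop_length(self) -> int:
        return int(round(self.hop_ms * self.fs_target / 1000.0))

    @property
    def segment_samples(self) -> int:
        return int(round(self.segment_s * self.fs_target))


@dataclass
class SpectrogramTensor:
    """A spectrogram-like array plus its axes.

    ``kind`` is one of STFT (power, freq x time), MSFB (log mel energies),
    MFCC (cepstral coefficients) or image (112x170x3 floats in [0, 1]).
    """

    values: np.ndarray
    kind: str
    freq_axis: np.ndarray | None = None
    time_axis: np.ndarray | None = None


def relabel_rate(waveform: np.ndarray, fs_native: int,
                 fs_target: int) -> tuple[np.ndarray, int]:
    """Reinterpret samples at a lower nominal rate (time expansion).

    The sample array is returned unchanged; only the rate label changes.
    Every frequency f in the native recording reads as
    ``f * fs_target / fs_native`` afterwards.
    """
    if fs_native < fs_target:
        raise ValueError("fs_native must be >= fs_target")
    return np.asarray(waveform), fs_target


def segment_audio(waveform: np.ndarray, fs: int, segment_s: float = 3.0,
                  keep_partial: bool = False) -> list[np.ndarray]:
    """Cut audio into fixed-length segments of round(segment_s * fs) samples.

    The trailing remainder is dropped, or zero-padded to full length when
    ``keep_partial`` is set. An empty waveform yields an empty list.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    waveform = np.asarray(waveform)
    n = int(round(segment_s * fs))
    full = len(waveform) // n
    segments = [waveform[i * n:(i + 1) * n] for i in range(full)]
    rem = len(waveform) - full * n
    if keep_partial and rem > 0:
        tail = np.zeros(n, dtype=waveform.dtype)
        tail[:rem] = waveform[full * n:]
        segments.append(tail)
    return segments


def n_stft_frames(n_samples: int, config: FeatureConfig) -> int:
    """Closed-form frame count: 1 + floor((L - win) / hop) (no padding)."""
    return 1 + (n_samples - config.win_length) // config.hop_length


def compute_stft(segment: np.ndarray, config: FeatureConfig) -> SpectrogramTensor:
    """Power STFT with a periodic Hann window and no-padding framing."""
    segment = np.asarray(segment, dtype=np.float64)
    win, hop = config.win_length, config.hop_length
    if config.center:
        segment = np.pad(segment, win // 2)
    if segment.size < win:
        raise ValueError("segment shorter than the analysis window")
    n_frames = n_stft_frames(segment.size, config)
    frames = np.lib.stride_tricks.sliding_window_view(segment, win)[::hop]
    frames = frames[:n_frames] * hann(win, sym=False)
    spec = rfft(frames, n=config.fft_size, axis=1)
    power = (spec.real ** 2 + spec.imag ** 2).T  # (freq, time)
    freqs = rfftfreq(config.fft_size, 1.0 / config.fs_target)
    times = (np.arange(n_frames) * hop + win / 2) / config.fs_target
    return SpectrogramTensor(power, "STFT", freqs, times)


def _hz_to_mel(f):
    """Slaney mel scale: linear below 1 kHz, logarithmic above."""
    f = np.asarray(f, dtype=np.float64)
    mel = f / (200.0 / 3.0)
    log_region = f >= 1000.0
    logstep = np.log(6.4) / 27.0
    mel = np.where(log_region, 15.0 + np.log(np.maximum(f, 1e-12) / 1000.0) / logstep, mel)
    return mel


def _mel_to_hz(m):
    m = np.asarray(m, dtype=np.float64)
    f = m * (200.0 / 3.0)
    logstep = np.log(6.4) / 27.0
    return np.where(m >= 15.0, 1000.0 * np.exp(logstep * (m - 15.0)), f)


def mel_filterbank(config: FeatureConfig) -> np.ndarray:
    """Slaney-style triangular mel filterbank, (n_mels, fft_size//2 + 1).

    Filters are area-normalized (each triangle scaled by 2 / bandwidth),
    spanning 0 Hz to the nominal Nyquist frequency.
    """
    n_bins = config.fft_size // 2 + 1
    if config.n_mels > n_bins:
        raise ValueError("n_mels exceeds the number of FFT bins")
    fmax = config.fs_target / 2.0
    edges_hz = _mel_to_hz(np.linspace(_hz_to_mel(0.0), _hz_to_mel(fmax),
                                      config.n_mels + 2))
    freqs = rfftfreq(config.fft_size, 1.0 / config.fs_target)
    fb = np.zeros((config.n_mels, n_bins))
    for m in range(config.n_mels):
        lo, ctr, hi = edges_hz[m], edges_hz[m + 1], edges_hz[m + 2]
        up = (freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - freqs) / max(hi - ctr, 1e-12)
        fb[m] = np.maximum(0.0, np.minimum(up, down)) * (2.0 / (hi - lo))
    return fb


def compute_msfb(stft_power: SpectrogramTensor,
                 config: FeatureConfig) -> SpectrogramTensor:
    """Log mel-filterbank energies from an STFT power spectrogram."""
    if stft_power.kind != "STFT":
        raise ValueError("compute_msfb expects an STFT power input")
    fb = mel_filterbank(config)
    mel_energy = fb @ stft_power.values
    values = np.log(mel_energy + config.log_floor)
    centers = _mel_to_hz(np.linspace(_hz_to_mel(0.0),
                                     _hz_to_mel(config.fs_target / 2.0),
                                     config.n_mels + 2))[1:-1]
    return SpectrogramTensor(values, "MSFB", centers, stft_power.time_axis)


def compute_mfcc(msfb: SpectrogramTensor,
                 config: FeatureConfig) -> SpectrogramTensor:
    """Orthonormal type-II DCT of the MSFB, keeping the first n_mfcc rows."""
    if msfb.kind != "MSFB":
        raise ValueError("compute_mfcc expects an MSFB input")
    coeffs = dct(msfb.values, type=2, norm="ortho", axis=0)[:config.n_mfcc]
    return SpectrogramTensor(coeffs, "MFCC",
                             np.arange(config.n_mfcc), msfb.time_axis)


def render_input_image(feature: SpectrogramTensor | np.ndarray,
                       colormap: str = "viridis",
                       out_shape: tuple[int, int] = (112, 170)) -> SpectrogramTensor:
    """Render a 2-D feature matrix as the CNN's fixed-shape color image.

    Per-image min-max normalization to [0, 1], colormap lookup to three
    channels, vertical flip so low frequencies sit at the bottom, then
    bilinear resize to ``out_shape``. A constant (degenerate) matrix maps to
    the colormap midpoint everywhere.
    """
    mat = feature.values if isinstance(feature, SpectrogramTensor) else feature
    mat = np.asarray(mat, dtype=np.float64)
    if mat.ndim != 2:
        raise ValueError("expected a 2-D feature matrix")
    lo, hi = mat.min(), mat.max()
    norm = np.full_like(mat, 0.5) if hi == lo else (mat - lo) / (hi - lo)
    rgb = colormaps[colormap](norm)[..., :3]
    rgb = rgb[::-1]  # low frequencies at the bottom, like a displayed spectrogram
    img = _sk_resize(rgb, out_shape, order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return SpectrogramTensor(img, "image")


def waveform_to_images(waveform: np.ndarray, fs_native: int,
                       config: FeatureConfig | None = None,
                       representation: str = "msfb",
                       keep_partial: bool = False,
                       colormap: str = "viridis") -> list[np.ndarray]:
    """Full pipeline: relabel -> segment -> STFT -> MSFB (-> MFCC) -> image.

    Returns one 112x170x3 float32 image per 3-s (nominal) segment.
    """
    config = config or FeatureConfig()
    wave, fs = relabel_rate(waveform, fs_native, config.fs_target)
    images = []
    for seg in segment_audio(wave, fs, config.segment_s, keep_partial):
        tensor = compute_stft(seg, config)
        if representation in ("msfb", "mfcc"):
            tensor = compute_msfb(tensor, config)
        if representation == "mfcc":
            tensor = compute_mfcc(tensor, config)
        images.append(render_input_image(tensor, colormap).values)
    return images


def build_image_dataset(segments, config: FeatureConfig | None = None,
                        representation: str = "msfb",
                        images_per_segment: int = 1
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Featurize labeled recordings into an image/label array pair.

    Each native recording time-expands into several nominal 3-s windows;
    ``images_per_segment`` of them (from the front) are kept, so counts per
    class stay exact multiples of the generated counts. Returns
    (images, labels) with images of shape (n, 112, 170, 3).
    """
    config = config or FeatureConfig()
    ims, labels = [], []
    for seg in segments:
        wave, fs = relabel_rate(seg.waveform, seg.fs, config.fs_target)
        windows = segment_audio(wave, fs, config.segment_s)
        for win in windows[:images_per_segment]:
            tensor = compute_stft(win, config)
            if representation in ("msfb", "mfcc"):
                tensor = compute_msfb(tensor, config)
            if representation == "mfcc":
                tensor = compute_mfcc(tensor, config)
            ims.append(render_input_image(tensor).values)
            labels.append(seg.label)
    return np.stack(ims), np.asarray(labels, dtype=np.int64)
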