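"""From a raw ultrasonic recording to the CNN's 112x170x3 input image.

Shows each stage: rate relabeling (time expansion), 3-s segmentation,
power STFT, log mel filter bank (MSFB), MFCC, and image rendering.
"""

import numpy as np

from echoscope.features import (FeatureConfig, compute_mfcc, compute_msfb,
                                compute_stft, relabel_rate, render_input_image,
                                segment_audio)
from echoscope.synthetic_calls import RecordingSpec, default_templates, \
    synthesize_recording

config = FeatureConfig()
tpl = default_templates()[0]  # FM sweep 150 -> 80 kHz
wave, fs_native = synthesize_recording(
    RecordingSpec(tpl, duration=3.0, snr_db=20.0, seed=0))
print(f"native recording: {len(wave)} samples at {fs_native} Hz")

wave, fs = relabel_rate(wave, fs_native, config.fs_target)
print(f"after rate relabeling: same samples, nominal rate {fs} Hz "
      f"({len(wave) / fs:.1f} nominal seconds)")
print(f"  the {tpl.f_start / 1e3:.0f} kHz sweep onset now reads as "
      f"{tpl.f_start * fs / fs_native / 1e3:.1f} kHz")

segment = segment_audio(wave, fs, config.segment_s)[0]
stft = compute_stft(segment, config)
print(f"STFT: {stft.values.shape} (freq bins x frames), "
      f"window {config.win_length} / hop {config.hop_length} samples")

msfb = compute_msfb(stft, config)
print(f"MSFB: {msfb.values.shape} log mel energies")

mfcc = compute_mfcc(msfb, config)
print(f"MFCC: {mfcc.values.shape} cepstral coefficients")

image = render_input_image(msfb)
print(f"model input image: {image.values.shape}, values in "
      f"[{image.values.min():.2f}, {image.values.max():.2f}]")
print("The image is what the compact CNN consumes: the sweep appears as a "
      "bright descending ridge against the noise floor.")
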