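import numpy as np
import pytest

from echoscope.features import build_image_dataset
from echoscope.synthetic_calls import default_templates, generate_dataset

#: indices into default_templates() with well-separated frequency bands
FOUR_CLASS_TEMPLATES = (0, 2, 5, 7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def four_class_images():
    """The 4-class synthetic study dataset: 100 segments per class, 20 dB SNR.

    Built once per session; used by the training and SGAN acceptance checks.
    Returns (images, labels) with images (400, 112, 170, 3).
    """
    templates = [default_templates()[i] for i in FOUR_CLASS_TEMPLATES]
    segments = generate_dataset(templates, [100] * 4, segment_s=3.0,
                                snr_db=20.0, seed=1)
    return build_image_dataset(segments)


@pytest.fixture(scope="session")
def tiny_images(rng):
    """Fast random image stand-ins for plumbing tests (not call-like)."""
    images = rng.random((24, 112, 170, 3)).astype(np.float32)
    labels = np.repeat(np.arange(4), 6)
    return images, labels
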