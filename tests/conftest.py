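import numpy as np
import pytest

from ecgallometry.preprocess import BeatTemplate
from ecgallometry.synth import make_template, mi_morphology


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def clean_template():
    """Noise-free lead-I-like template with its ground-truth fiducials."""
    samples, r_idx, fid = make_template(mi_morphology("I"), fs=500.0)
    return BeatTemplate(samples, 500.0, 30, 0, r_idx), fid


def template_with_noise(morph, noise_sd, rng, fs=500.0):
    samples, r_idx, fid = make_template(morph, fs=fs, noise_sd=noise_sd, rng=rng)
    return BeatTemplate(samples, fs, 30, 0, r_idx), fid
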