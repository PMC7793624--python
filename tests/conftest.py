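import numpy as np
import pytest

from usvkit import synth, segment, vae
from usvkit.pipeline import images_from_annotations


@pytest.fixture(scope="session")
def base_cond():
    return synth.ConditionParams()


@pytest.fixture(scope="session")
def short_session(base_cond):
    """20 s rendered session with ground-truth annotations."""
    return synth.render_session(base_cond, 20.0, seed=11)


@pytest.fixture(scope="session")
def short_session_spec(short_session):
    return segment.compute_spectrogram(short_session.samples, short_session.sample_rate)


@pytest.fixture(scope="session")
def syllable_images(base_cond):
    """~150 syllable images from annotation-only sessions (two conditions)."""
    sessions = synth.make_two_condition_dataset(
        2, base_cond, synth.ConditionShift(amplitude_gain=1.5, bandwidth_delta_hz=10_000.0),
        seed=5, session_duration=20.0, render_audio=False,
    )
    images, labels = images_from_annotations(sessions)
    return images, labels


@pytest.fixture(scope="session")
def trained_vae(syllable_images):
    images, _ = syllable_images
    cfg = vae.VAEConfig(latent_dim=16, epochs=60, batch_size=32, seed=0, mode="linear_fast")
    return vae.train_vae(images, cfg)
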