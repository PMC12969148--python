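import numpy as np
import pytest

from lesionforge import moglisa, surrogate, synthgen
from lesionforge.cli import _class_priors


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small imbalanced synthetic dataset shared across tests."""
    out = tmp_path_factory.mktemp("dataset")
    scene = synthgen.SceneSpec(canvas_size=(48, 48))
    manifest = synthgen.generate_dataset(
        {"benign": 16, "melanoma": 8}, _class_priors((48, 48)), scene, 11, out
    )
    return manifest


@pytest.fixture(scope="session")
def small_samples(small_dataset):
    return surrogate.load_samples(small_dataset)


@pytest.fixture(scope="session")
def trained_ae(small_samples):
    """A session-wide trained autoencoder over the small dataset."""
    spec = moglisa.AutoencoderSpec(epochs=30, seed=5)
    encoder, decoder, curve = moglisa.train_autoencoder(small_samples, spec)
    return encoder, decoder, curve, spec


def random_mask(rng, shape=(32, 32), p=0.3):
    """A random blobby binary mask (possibly empty)."""
    noise = rng.random(shape)
    from scipy import ndimage

    smooth = ndimage.gaussian_filter(noise, sigma=3.0)
    return (smooth > np.quantile(smooth, 1 - p)).astype(np.uint8)
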