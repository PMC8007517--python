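import numpy as np
import pytest

from ionclust import (ReferenceEmbedder, SyntheticConfig, embed_ion_image,
                      generate_msi_dataset, ion_images, plan_patch_grid,
                      standardize_image)


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig()


@pytest.fixture(scope="session")
def synthetic(default_config):
    """(dataset, ground truth) for the default generator config."""
    return generate_msi_dataset(default_config)


@pytest.fixture(scope="session")
def synthetic_images(synthetic):
    dataset, _ = synthetic
    return ion_images(dataset)


@pytest.fixture(scope="session")
def standardized_images(synthetic_images):
    return [standardize_image(img) for img in synthetic_images]


@pytest.fixture(scope="session")
def reference_vectors(synthetic, standardized_images):
    """Neural ion image matrix for the default synthetic dataset (2 mm patches)."""
    dataset, _ = synthetic
    grid = plan_patch_grid(standardized_images[0].shape, dataset.pixel_size_um,
                           target_mm=2.0, min_side=1)
    embedder = ReferenceEmbedder()
    return np.stack([embed_ion_image(img, grid, embedder).vector
                     for img in standardized_images])


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_ion_image(pixels, mz=700.0, pixel_size_um=10.0, mask=None):
    from ionclust import IonImage

    pixels = np.asarray(pixels, dtype=float)
    if mask is None:
        mask = np.ones_like(pixels, dtype=bool)
    return IonImage(pixels=pixels, mz=mz, pixel_size_um=pixel_size_um, mask=mask)
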