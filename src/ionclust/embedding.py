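"""Per-patch embedding and max-pool aggregation into neural ion images."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import ParameterError, ValidationError
from .msi_io import IonImage
from .patching import PatchGrid, extract_patches, upsample_image


@runtime_checkable
class Embedder(Protocol):
    """Deterministic patch-to-vector map; identical patches give identical vectors."""

    name: str
    dim: int
    min_side: int

    def __call__(self, patch: np.ndarray) -> np.ndarray: ...


@dataclass
class NeuralIonImage:
    """Fixed-length embedding of one ion image, with provenance."""

    vector: np.ndarray
    mz: float
    provenance: str

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=float)
        if not np.all(np.isfinite(self.vector)):
            raise ValidationError("embedding vector contains non-finite entries")


def _resize_bilinear(patch: np.ndarray, side: int) -> np.ndarray:
    rows = (np.arange(side) + 0.5) * patch.shape[0] / side - 0.5
    cols = (np.arange(side) + 0.5) * patch.shape[1] / side - 0.5
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return map_coordinates(patch, [rr, cc], order=1, mode="nearest")


def _block_means(img: np.ndarray, blocks: int) -> np.ndarray:
    side = img.shape[0]
    return img.reshape(blocks, side // blocks, blocks, side // blocks).mean(axis=(1, 3))


class ReferenceEmbedder:
    """Deterministic hand-crafted embedder used as the default test backbone.

    The patch is resized to 32x32; the vector concatenates block means over
    1x1, 2x2, 4x4 and 8x8 partitions (85 values) with 4x4 block means of the
    central-difference gradient magnitude (16 values) - 101 dimensions total.
    """

    name = "reference"
    dim = 101
    min_side = 1

    def __call__(self, patch: np.ndarray) -> np.ndarray:
        patch = np.asarray(patch, dtype=float)
        if patch.ndim != 2:
            raise ValidationError("patch must be 2-D")
        if patch.min() < -1e-9 or patch.max() > 1 + 1e-9:
            raise ValidationError("patch values must lie in [0, 1]")
        p = _resize_bilinear(patch, 32)
        feats = [_block_means(p, b).ravel() for b in (1, 2, 4, 8)]
        gy, gx = np.gradient(p)
        mag = np.hypot(gy, gx)
        feats.append(_block_means(mag, 4).ravel())
        return np.concatenate(feats)


def aggregate_max(patch_vectors: Sequence[np.ndarray]) -> np.ndarray:
    """Elementwise max across patch vectors - 'was the feature seen anywhere?'."""
    if len(patch_vectors) == 0:
        raise ParameterError("cannot aggregate an empty list of vectors")
    lengths = {len(v) for v in patch_vectors}
    if len(lengths) != 1:
        raise ParameterError("patch vectors have ragged lengths")
    return np.max(np.stack([np.asarray(v, dtype=float) for v in patch_vectors]), axis=0)


def embed_ion_image(image: IonImage, grid: PatchGrid, embedder: Embedder) -> NeuralIonImage:
    """Upsample, patch, embed each patch, and max-pool into one vector."""
    if grid.side_px < embedder.min_side:
        raise ParameterError(f"grid side {grid.side_px} below embedder minimum "
                             f"{embedder.min_side}")
    up = upsample_image(image.pixels, grid.upsample_factor)
    np.clip(up, 0.0, 1.0, out=up)
    patches = extract_patches(up, grid)
    vector = aggregate_max([embedder(p) for p in patches])
    return NeuralIonImage(vector=vector, mz=image.mz,
                          provenance=f"{embedder.name};{grid.summary()}")


def get_embedder(name: str, seed: int = 0) -> Embedder:
    """Look up an embedder by CLI name ('reference' or 'xception')."""
    if name == "reference":
        return ReferenceEmbedder()
    if name == "xception":
        from .xception import XceptionEmbedder

        return XceptionEmbedder(seed=seed)
    raise ParameterError(f"unknown embedder: {name!r}")
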