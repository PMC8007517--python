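"""Clustering of (neural) ion image vectors: UMAP->DBSCAN and k-means."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN, KMeans

from .errors import ParameterError
from .msi_io import IonImage
from .preprocess import standardize_image

NOISE_LABEL = -1


@dataclass
class ClusteringResult:
    """Per-ion-image integer labels; DBSCAN noise points carry label -1."""

    labels: np.ndarray
    method: str
    params: dict = field(default_factory=dict)
    embedding3d: np.ndarray | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.method == "kmeans" and np.any(self.labels == NOISE_LABEL):
            raise ParameterError("k-means results cannot contain the noise label")


def reduce_umap(vectors: np.ndarray, n_components: int = 3, metric: str = "cosine",
                n_neighbors: int = 15, min_dist: float = 0.1,
                seed: int = 0) -> np.ndarray:
    """Reduce vectors to ``n_components`` dimensions with seeded UMAP."""
    vectors = np.asarray(vectors, dtype=float)
    n = vectors.shape[0]
    if n <= n_neighbors:
        raise ParameterError(f"UMAP needs more than n_neighbors={n_neighbors} "
                             f"samples, got {n}")
    import umap  # deferred: numba compilation makes this import expensive

    reducer = umap.UMAP(n_components=n_components, metric=metric,
                        n_neighbors=n_neighbors, min_dist=min_dist,
                        random_state=seed)
    points = reducer.fit_transform(vectors)
    return np.asarray(points, dtype=float)


def cluster_dbscan(points: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """Euclidean DBSCAN over (typically 3-D UMAP) coordinates."""
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        raise ParameterError("empty input")
    if eps <= 0 or min_samples < 1:
        raise ParameterError("eps must be > 0 and min_samples >= 1")
    return DBSCAN(eps=eps, min_samples=min_samples).fit_predict(points)


def cluster_kmeans(vectors: np.ndarray, k: int, seed: int = 0,
                   n_init: int = 10) -> np.ndarray:
    """Seeded k-means with k-means++ restarts (Euclidean distance)."""
    vectors = np.asarray(vectors, dtype=float)
    n = vectors.shape[0]
    if not 1 <= k <= n:
        raise ParameterError(f"k must lie in [1, {n}], got {k}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(vectors)


def count_meaningful_clusters(result: ClusteringResult | np.ndarray) -> int:
    """Clusters that are neither the noise cluster nor singletons."""
    labels = result.labels if isinstance(result, ClusteringResult) else np.asarray(result)
    values, counts = np.unique(labels, return_counts=True)
    return int(np.sum((values != NOISE_LABEL) & (counts >= 2)))


def mean_cluster_image(images: list[IonImage], labels, cluster_id: int,
                       winsor_q: float = 0.95) -> IonImage:
    """Pixelwise mean of the winsorized, unit-scaled members of one cluster."""
    labels = np.asarray(labels)
    members = [img for img, lab in zip(images, labels) if lab == cluster_id]
    if not members:
        raise ParameterError(f"cluster {cluster_id} is empty or absent")
    std = [standardize_image(img, winsor_q) for img in members]
    pixels = np.mean([img.pixels for img in std], axis=0)
    ref = std[0]
    return IonImage(pixels=pixels, mz=float(np.mean([m.mz for m in members])),
                    pixel_size_um=ref.pixel_size_um, mask=ref.mask)
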