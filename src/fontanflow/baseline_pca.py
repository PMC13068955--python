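"""PCA + k-means baseline clustering of flow curves.

The conventional comparator to deep temporal clustering: the two 30-frame
channels of each sample are concatenated end-to-end into a 60-dimensional
feature vector, mean-centered over the whole dataset, decomposed by PCA, and
the component weights are clustered with k-means.  The silhouette score is
computed in the PC-weight space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .dtc import DTCInput, silhouette


@dataclass
class PCAKMeansResults:
    labels: np.ndarray
    centroid_curves: np.ndarray   # (k, n_frames, channels), original space
    silhouette: float
    explained_variance_ratio: np.ndarray
    n_components: int
    weights: np.ndarray           # (n, n_components) PC weights

    def summary(self) -> str:
        return (f"PCA + k-means (k={len(self.centroid_curves)}, "
                f"{self.n_components} components, "
                f"{self.explained_variance_ratio.sum():.1%} variance)\n"
                f"  silhouette (PC space): {self.silhouette:.3f}\n"
                f"  cluster sizes: "
                f"{np.bincount(self.labels).tolist()}")


def to_feature_vectors(data: DTCInput | np.ndarray) -> np.ndarray:
    """Concatenate channels end-to-end into (n, frames*channels) vectors."""
    curves = data.curves if isinstance(data, DTCInput) else np.asarray(data)
    n, t, c = curves.shape
    # channel-wise blocks: [ch0 frames..., ch1 frames...]
    return curves.transpose(0, 2, 1).reshape(n, t * c)


def pca_kmeans(data: DTCInput | np.ndarray, k: int,
               n_components: float | int = 0.95, seed: int = 0,
               n_restarts: int = 50) -> PCAKMeansResults:
    """Cluster PC weights of mean-centered concatenated curves with k-means.

    ``n_components`` follows scikit-learn semantics: a float in (0,1) keeps
    enough components to explain that variance fraction; an int keeps that
    many.
    """
    vectors = to_feature_vectors(data)
    n = len(vectors)
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    centered = vectors - vectors.mean(axis=0, keepdims=True)
    pca = PCA(n_components=n_components, random_state=seed)
    weights = pca.fit_transform(centered)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(weights)
    labels = km.labels_
    curves = data.curves if isinstance(data, DTCInput) else np.asarray(data)
    centroid_curves = np.stack([curves[labels == j].mean(axis=0)
                                for j in range(k)])
    sil = silhouette(labels, weights)
    return PCAKMeansResults(labels=labels, centroid_curves=centroid_curves,
                            silhouette=sil,
                            explained_variance_ratio=pca.explained_variance_ratio_,
                            n_components=pca.n_components_, weights=weights)
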