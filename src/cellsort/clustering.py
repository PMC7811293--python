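"""Dimensionality reduction and clustering plumbing.

The annotators only need a cell → cluster map; any external clustering can
be supplied as a CSV instead.  The built-in route projects the most
variable genes onto principal components and runs k-means or agglomerative
clustering, with k chosen by silhouette when not given.
"""

from __future__ import annotations

import numpy as np
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .io import ClusterLabels, ExpressionMatrix

__all__ = ["cluster_cells"]

N_VARIABLE_GENES = 1000


def _pca_embed(matrix: ExpressionMatrix, n_components: int, seed: int) -> np.ndarray:
    values = matrix.values
    variances = values.var(axis=1)
    top = variances.sort_values(ascending=False).index[:N_VARIABLE_GENES]
    data = values.loc[top].to_numpy().T  # cells × genes
    n_components = min(n_components, data.shape[0] - 1, data.shape[1])
    pca = PCA(n_components=n_components, random_state=seed)
    return pca.fit_transform(data)


def cluster_cells(
    matrix: ExpressionMatrix,
    n_components: int = 30,
    k: int | str = "auto",
    method: str = "kmeans",
    seed: int = 0,
    max_k: int = 10,
) -> ClusterLabels:
    """PCA on the most variable genes, then k-means or agglomerative.

    ``k="auto"`` picks the cluster count in 2..max_k with the best
    silhouette score on the embedding.  Deterministic at fixed seed.
    """
    emb = _pca_embed(matrix, n_components, seed)
    n_cells = emb.shape[0]

    def run(kk: int) -> np.ndarray:
        if kk == 1:
            return np.zeros(n_cells, dtype=int)
        if method == "kmeans":
            return KMeans(n_clusters=kk, random_state=seed, n_init=10).fit_predict(emb)
        if method == "agglomerative":
            return AgglomerativeClustering(n_clusters=kk).fit_predict(emb)
        raise ValueError(f"unknown clustering method {method!r}")

    if k == "auto":
        best, best_score = None, -np.inf
        for kk in range(2, min(max_k, n_cells - 1) + 1):
            lab = run(kk)
            score = silhouette_score(emb, lab)
            if score > best_score:
                best, best_score = lab, score
        labels = best
    else:
        k = int(k)
        if k > n_cells:
            raise ValueError(f"k={k} exceeds cell count {n_cells}")
        labels = run(k)

    # relabel so cluster indices are contiguous and order-stable
    _, contiguous = np.unique(labels, return_inverse=True)
    return ClusterLabels.from_mapping(dict(zip(matrix.cells, contiguous.astype(int))))
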