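"""Therapeutic clusters: cells grouped by shared drug response.

Clustering runs on the score matrix, not on expression, so the groups it
finds are response phenotypes — cells that score similarly across the drug
collection — which may cut across transcriptional clusters.  The pipeline is
the standard one transplanted onto the score matrix: PCA for noise control,
a k-nearest-neighbour graph with Leiden community detection (k-means as a
deterministic fallback), and a 2-D UMAP embedding for visualisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .datatypes import ScoreMatrix, TherapeuticClusters

__all__ = ["Reduction", "reduce_scores", "find_clusters"]


@dataclass
class Reduction:
    """PCA components (cells × n_pcs) plus the optional 2-D embedding."""

    components: pd.DataFrame
    embedding: pd.DataFrame | None
    explained_variance_ratio: np.ndarray
    params: dict = field(default_factory=dict)


def _score_values(scores: ScoreMatrix, use: str) -> pd.DataFrame:
    if use == "residuals":
        if scores.residuals is None:
            raise ValueError("no residuals present; run regress_out first")
        mat = scores.residuals
    elif use == "scaled":
        mat = scores.scaled
    else:
        raise ValueError(f"unknown matrix choice: {use!r}")
    if not np.isfinite(mat.to_numpy()).all():
        raise ValueError(
            "score matrix contains NaN; impute (knn_impute) before reduction"
        )
    return mat


def reduce_scores(
    scores: ScoreMatrix,
    use: str = "scaled",
    n_pcs: int = 20,
    seed: int = 0,
    *,
    embed: bool = True,
    n_neighbors: int = 15,
) -> Reduction:
    """PCA of the score matrix followed by a 2-D UMAP embedding.

    ``use`` selects the scaled scores or the covariate-regressed residuals.
    ``n_pcs`` is clipped (with a warning) to ``min(n_cells, n_signatures) − 1``.
    The seed controls both the PCA solver and UMAP and is recorded in
    ``params``.  Set ``embed=False`` to skip the (comparatively slow) UMAP
    step when only clustering is needed.
    """
    mat = _score_values(scores, use)
    n_cells, n_sigs = mat.shape
    max_pcs = max(1, min(n_cells, n_sigs) - 1)
    if n_pcs > max_pcs:
        warnings.warn(f"n_pcs={n_pcs} clipped to {max_pcs}")
        n_pcs = max_pcs
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=seed)
    comps = pca.fit_transform(mat.to_numpy())
    components = pd.DataFrame(
        comps, index=mat.index, columns=[f"PC{i + 1}" for i in range(n_pcs)]
    )
    embedding = None
    if embed:
        if comps.var(axis=0).sum() < 1e-24:
            # all cells identical: nothing to embed, place them at the origin
            warnings.warn("zero-variance score matrix: degenerate embedding")
            coords = np.zeros((n_cells, 2))
        else:
            import umap  # deferred: numba compilation is slow at import time

            nn = min(n_neighbors, n_cells - 1)
            reducer = umap.UMAP(
                n_components=2, n_neighbors=nn, random_state=seed, n_jobs=1
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # umap chatters about n_jobs/seed
                coords = reducer.fit_transform(comps)
        embedding = pd.DataFrame(
            coords, index=mat.index, columns=["UMAP1", "UMAP2"]
        )
    return Reduction(
        components=components,
        embedding=embedding,
        explained_variance_ratio=pca.explained_variance_ratio_,
        params={"use": use, "n_pcs": n_pcs, "seed": seed,
                "n_neighbors": n_neighbors},
    )


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..K−1 by decreasing size (ties: smaller old id first)."""
    ids, counts = np.unique(labels[labels >= 0], return_counts=True)
    order = ids[np.lexsort((ids, -counts))]
    mapping = {old: new for new, old in enumerate(order)}
    return np.array([mapping.get(l, -1) for l in labels], dtype=int)


def find_clusters(
    reduction: Reduction,
    method: str = "graph_community",
    resolution: float = 0.4,
    k: int | None = None,
    seed: int = 0,
    *,
    n_neighbors: int = 15,
) -> TherapeuticClusters:
    """Cluster cells in PCA space into therapeutic clusters.

    ``graph_community`` builds a k-nearest-neighbour graph (``n_neighbors``)
    and runs Leiden community detection at the given ``resolution``;
    ``kmeans`` partitions into exactly ``k`` clusters.  Both are deterministic
    given the seed; labels are relabelled by decreasing cluster size.
    """
    comps = reduction.components.to_numpy()
    n_cells = comps.shape[0]
    if method == "graph_community":
        import igraph
        import leidenalg

        nn = min(n_neighbors, n_cells - 1)
        knn = NearestNeighbors(n_neighbors=nn + 1).fit(comps)
        _, idx = knn.kneighbors(comps)
        edges = {tuple(sorted((i, j))) for i, row in enumerate(idx)
                 for j in row[1:]}
        graph = igraph.Graph(n=n_cells, edges=sorted(edges), directed=False)
        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution,
            seed=seed,
        )
        labels = np.asarray(part.membership, dtype=int)
    elif method == "kmeans":
        from sklearn.cluster import KMeans

        if k is None:
            raise ValueError("kmeans requires k")
        if k > n_cells:
            raise ValueError(f"k={k} exceeds the number of cells ({n_cells})")
        labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(
            comps
        )
    else:
        raise ValueError(f"unknown clustering method: {method!r}")

    labels = _relabel_by_size(labels)
    return TherapeuticClusters(
        labels=pd.Series(labels, index=reduction.components.index, name="tc"),
        embedding=reduction.embedding,
        params={
            "method": method,
            "resolution": resolution,
            "k": k,
            "seed": seed,
            "n_neighbors": n_neighbors,
            **reduction.params,
        },
    )
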