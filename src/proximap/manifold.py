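"""Manifold reduction: N x D features -> N x 2/3 coordinates.

Second stage of the staged reduction, plus the nonstaged baseline that
feeds an all-pairs shortest-path distance matrix straight into the manifold
learner. UMAP is used for both, for its preservation of local and global
geometry. Reconstructed coordinates are defined only up to a similarity
transform (rotation/reflection/translation/scale); downstream metrics are
invariant or align explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .discovery import EmbeddingMatrix
from .graphs import ProximityGraph
from .scene import PointCloud


@dataclass(frozen=True)
class ReductionConfig:
    """Manifold-learning settings.

    ``n_neighbors`` controls the local/global balance of UMAP (15 mirrors
    the typical 3D Voronoi neighbour count), ``min_dist`` the packing of
    the embedding. ``target_dim`` must match the scene dimension for
    ground-truth evaluation.
    """

    target_dim: int = 2
    n_neighbors: int = 15
    min_dist: float = 0.1
    metric: str = "euclidean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_dim not in (2, 3):
            raise ValueError(f"target_dim must be 2 or 3, got {self.target_dim}")
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be at least 2")
        if self.min_dist < 0:
            raise ValueError("min_dist must be nonnegative")


#: Below this many samples UMAP's spectral machinery is degenerate; classical
#: MDS is exact for such tiny inputs and is used instead.
_MDS_FALLBACK_N = 8


def _classical_mds(dist: np.ndarray, dim: int) -> np.ndarray:
    """Torgerson MDS: eigendecomposition of the double-centred squared
    distance matrix. Deterministic; used only for tiny inputs."""
    n = dist.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dist ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    idx = np.argsort(vals)[::-1][:dim]
    return vecs[:, idx] * np.sqrt(np.clip(vals[idx], 0, None))


def _umap(config: ReductionConfig, n_samples: int, metric: str):
    import umap

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="n_jobs value 1 overridden")
        return umap.UMAP(
            n_components=config.target_dim,
            n_neighbors=min(config.n_neighbors, n_samples - 1),
            min_dist=config.min_dist,
            metric=metric,
            random_state=int(config.seed) % (2 ** 31),
        )


def reduce_to_space(features: EmbeddingMatrix, config: ReductionConfig) -> PointCloud:
    """Embed feature vectors into ``target_dim`` spatial coordinates."""
    if not np.all(np.isfinite(features.vectors)):
        raise ValueError("feature vectors must be finite")
    if features.n_nodes <= config.target_dim:
        raise ValueError("need more points than target dimensions")
    if features.n_nodes < _MDS_FALLBACK_N:
        from scipy.spatial.distance import pdist, squareform

        coords = _classical_mds(
            squareform(pdist(features.vectors.astype(np.float64))),
            config.target_dim,
        )
    else:
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", module="umap")
            coords = _umap(config, features.n_nodes, config.metric).fit_transform(
                features.vectors
            )
    return PointCloud(features.node_ids, np.asarray(coords, dtype=np.float64))


def baseline_nonstaged(graph: ProximityGraph, config: ReductionConfig) -> PointCloud:
    """Nonstaged reconstruction: manifold learning on the full N x N
    shortest-path distance matrix.

    Hop counts are used for unweighted graphs; for weighted graphs edge
    length is taken as ``1 / weight`` (weights are inverse distances, so
    this restores distance units). Memory and time are O(N^2) — the staged
    pipeline exists to avoid exactly this.
    """
    n = graph.n_nodes
    if n > 20_000:
        warnings.warn(
            f"nonstaged baseline at N={n} needs an {n} x {n} dense matrix",
            stacklevel=2,
        )
    if graph.is_weighted:
        adj = graph.to_csr(weighted=True)
        adj.data = 1.0 / adj.data
        dist = shortest_path(adj, method="D", directed=False)
    else:
        dist = shortest_path(
            graph.to_csr(weighted=False), method="D", unweighted=True, directed=False
        )
    if np.isinf(dist).any():
        raise ValueError(
            "graph is disconnected (infinite shortest paths); reduce to the "
            "giant component first"
        )
    if n < _MDS_FALLBACK_N:
        coords = _classical_mds(dist, config.target_dim)
    else:
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", module="umap")
            warnings.filterwarnings(
                "ignore", message="using precomputed metric.*"
            )
            coords = _umap(config, n, "precomputed").fit_transform(dist)
    return PointCloud(graph.node_ids, np.asarray(coords, dtype=np.float64))
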