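"""Structural discovery: adjacency -> N x D feature matrix.

First stage of the staged reduction. Biased random walks sample the local
and global neighbourhood structure of every node; the walks are treated as
sentences and fed to skip-gram with negative sampling, so nodes that share
walk contexts (i.e. are close in the graph, hence in space) get similar
feature vectors. Output is N x D with D << N, which is what keeps the
downstream manifold stage near-linear in N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .graphs import ProximityGraph


@dataclass(frozen=True)
class WalkConfig:
    """Hyperparameters of the walk-sampling and skip-gram stage.

    Defaults were benchmarked on 2D/3D scenes of N in the low thousands as
    a compromise between reconstruction accuracy and training cost; larger
    systems need longer walks and a larger ``embedding_dim`` to keep
    accuracy (both scale with the amount of structure to encode).

    Parameters
    ----------
    embedding_dim : int
        Feature dimension D.
    walk_length, walks_per_node : int
        Each node starts ``walks_per_node`` walks of ``walk_length`` nodes.
    window_size : int
        Skip-gram context half-window (sub-sampled per position).
    return_param, inout_param : float
        Node2Vec p and q. With p = q = 1 walks are first-order (plain
        weight-proportional) and a faster kernel is used.
    n_negative : int
        Negative samples per positive pair.
    epochs : int
        Training passes over the walk corpus.
    learning_rate : float
        Initial SGD step size, decayed linearly to 1e-4.
    seed : int
        Drives both walk sampling and training.
    """

    embedding_dim: int = 32
    walk_length: int = 60
    walks_per_node: int = 6
    window_size: int = 4
    return_param: float = 1.0
    inout_param: float = 1.0
    n_negative: int = 4
    epochs: int = 3
    learning_rate: float = 0.025
    seed: int = 0

    def __post_init__(self) -> None:
        for f in ("embedding_dim", "walk_length", "walks_per_node",
                  "window_size", "n_negative", "epochs"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be a positive integer")
        if not (self.return_param > 0 and self.inout_param > 0):
            raise ValueError("return_param and inout_param must be positive")


@dataclass
class EmbeddingMatrix:
    """Node IDs with their D-dimensional feature vectors (row-aligned)."""

    node_ids: np.ndarray
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.vectors = np.asarray(self.vectors)
        if len(self.node_ids) != len(self.vectors):
            raise ValueError("node_ids and vectors must be row-aligned")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding vectors must be finite")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


def _csr_arrays(graph: ProximityGraph):
    adj = graph.to_csr()
    deg = np.diff(adj.indptr)
    if np.any(deg == 0):
        isolated = graph.node_ids[deg == 0][:10].tolist()
        raise ValueError(
            f"graph has isolated nodes (e.g. {isolated}); reduce to the "
            "giant component first"
        )
    return adj


def generate_walks(graph: ProximityGraph, config: WalkConfig) -> np.ndarray:
    """Sample ``walks_per_node`` biased walks of ``walk_length`` per node.

    Returns an array of node IDs, one walk per row. Transitions are
    proportional to edge weight times the Node2Vec p/q bias; unweighted
    edges count as weight 1. Reproducible from ``config.seed``.
    """
    adj = _csr_arrays(graph)
    seed = int(config.seed) % (2 ** 31)
    if config.return_param == 1.0 and config.inout_param == 1.0:
        weighted = graph.is_weighted
        if weighted:
            # per-row cumulative weights for O(log deg) sampling
            cumw = np.copy(adj.data)
            for i in range(graph.n_nodes):
                lo, hi = adj.indptr[i], adj.indptr[i + 1]
                cumw[lo:hi] = np.cumsum(cumw[lo:hi])
        else:
            cumw = np.empty(0, dtype=np.float64)
        walks = _kernels.first_order_walks(
            adj.indptr, adj.indices, cumw, weighted, graph.n_nodes,
            config.walks_per_node, config.walk_length, seed,
        )
    else:
        walks = _kernels.second_order_walks(
            adj.indptr, adj.indices, adj.data.astype(np.float64),
            graph.n_nodes, config.walks_per_node, config.walk_length,
            float(config.return_param), float(config.inout_param), seed,
        )
    return graph.node_ids[walks]


def embed_walks(walks: np.ndarray, config: WalkConfig,
                node_ids: np.ndarray | None = None) -> EmbeddingMatrix:
    """Train skip-gram with negative sampling on walks-as-sentences.

    ``walks`` is an array of node IDs (one walk per row). Every node of the
    graph must occur in at least one walk (guaranteed when walks start from
    each node). Training is single-threaded and seeded, hence deterministic.
    """
    walks = np.asarray(walks)
    uniq = np.unique(walks)
    if node_ids is None:
        node_ids = uniq
    else:
        node_ids = np.asarray(node_ids, dtype=np.int64)
        missing = np.setdiff1d(node_ids, uniq)
        if len(missing):
            raise ValueError(
                f"nodes missing from all walks: {missing[:10].tolist()}"
            )
    if config.embedding_dim >= len(node_ids) / 2:
        warnings.warn(
            f"embedding_dim={config.embedding_dim} is not << n_nodes="
            f"{len(node_ids)}; the compression stage is ineffective",
            stacklevel=2,
        )
    # map node IDs -> dense training indices
    lookup = {int(n): i for i, n in enumerate(node_ids)}
    flat = np.fromiter((lookup[int(v)] for v in walks.ravel()),
                       dtype=np.int32, count=walks.size)
    dense = flat.reshape(walks.shape)
    counts = np.bincount(flat, minlength=len(node_ids)).astype(np.float64)
    weights = counts ** 0.75
    neg_cum = np.cumsum(weights / weights.sum())
    vectors = _kernels.train_skipgram(
        dense, len(node_ids), config.embedding_dim, config.window_size,
        config.epochs, config.n_negative, config.learning_rate, 1e-4,
        neg_cum, _kernels.EXP_TABLE, (int(config.seed) + 1) % (2 ** 31),
    )
    return EmbeddingMatrix(node_ids, vectors)


def discover(graph: ProximityGraph, config: WalkConfig) -> EmbeddingMatrix:
    """Convenience: walks + skip-gram in one call."""
    walks = generate_walks(graph, config)
    return embed_walks(walks, config, node_ids=graph.node_ids)
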