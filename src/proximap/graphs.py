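"""Proximity-graph generators and their diagnostics.

A proximity graph connects spatially scattered nodes according to a
distance-dependent rule — the in-silico analogue of proximity-dependent
DNA association. Seven rule families are provided:

* ``knn`` / ``knn_weighted`` — connect to the k closest neighbours
  (optionally weighting edges by inverse distance),
* ``epsilon_ball`` — connect to every node within distance epsilon,
* ``voronoi`` — connect nodes whose Voronoi cells share a border
  (computed as the Delaunay dual),
* ``decaying`` — Bernoulli edges with a distance-decaying probability,
* ``random_rule`` — Bernoulli edges under an arbitrary bounded
  acceptance function (three representative shapes ship in
  :data:`ACCEPTANCE_LIBRARY`).

All rules produce symmetric simple graphs. Default parameters are
calibrated so the mean degree is ~15 regardless of rule, dimension and
system size, mirroring the near-constant neighbour count of 3D Voronoi
tessellations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.integrate import quad
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial import Delaunay, QhullError, cKDTree
from scipy.spatial.distance import pdist, squareform

from .scene import PointCloud

RULE_KINDS = (
    "knn",
    "knn_weighted",
    "epsilon_ball",
    "voronoi",
    "decaying",
    "random_rule",
)

#: Mean degree the default parameter calibration targets, for every rule.
TARGET_MEAN_DEGREE = 15.0


class ParameterError(ValueError):
    """Raised when a graph-rule parameter violates its contract."""


@dataclass(frozen=True)
class RuleConfig:
    """Which proximity rule to apply and its parameters.

    Exactly the parameters the rule needs may be set: ``k`` for the kNN
    rules, ``epsilon`` for the epsilon-ball rule, ``decay_scale`` for the
    decaying rule, ``acceptance_fn`` (distance -> probability in [0, 1])
    for ``random_rule``. ``seed`` drives the Bernoulli draws of the
    stochastic rules. ``name`` is a display label for sweeps.
    """

    rule_kind: str
    k: Optional[int] = None
    epsilon: Optional[float] = None
    decay_scale: Optional[float] = None
    acceptance_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None
    seed: int = 0
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.rule_kind not in RULE_KINDS:
            raise ParameterError(
                f"rule_kind must be one of {RULE_KINDS}, got {self.rule_kind!r}"
            )
        required = {
            "knn": {"k"},
            "knn_weighted": {"k"},
            "epsilon_ball": {"epsilon"},
            "voronoi": set(),
            "decaying": {"decay_scale"},
            "random_rule": {"acceptance_fn"},
        }[self.rule_kind]
        given = {
            f for f in ("k", "epsilon", "decay_scale", "acceptance_fn")
            if getattr(self, f) is not None
        }
        if given != required:
            raise ParameterError(
                f"rule {self.rule_kind!r} requires exactly {sorted(required)}, "
                f"got {sorted(given)}"
            )
        if self.k is not None and self.k < 1:
            raise ParameterError(f"k must be positive, got {self.k}")
        if self.epsilon is not None and not self.epsilon > 0:
            raise ParameterError(f"epsilon must be positive, got {self.epsilon}")
        if self.decay_scale is not None and not self.decay_scale > 0:
            raise ParameterError(
                f"decay_scale must be positive, got {self.decay_scale}"
            )

    @property
    def label(self) -> str:
        return self.name or self.rule_kind


class ProximityGraph:
    """Symmetric simple graph over labelled nodes, optionally edge-weighted.

    Edges are stored as unordered pairs of *node IDs* with ``i < j``; the
    adjacency (the N x N binary matrix of the network) is available as a
    symmetric CSR matrix via :meth:`to_csr`.
    """

    def __init__(
        self,
        node_ids: np.ndarray,
        edges: np.ndarray,
        weights: Optional[np.ndarray] = None,
    ):
        self.node_ids = np.asarray(node_ids, dtype=np.int64)
        if len(np.unique(self.node_ids)) != len(self.node_ids):
            raise ValueError("node_ids must be unique")
        edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        lo = np.minimum(edges[:, 0], edges[:, 1])
        hi = np.maximum(edges[:, 0], edges[:, 1])
        if np.any(lo == hi):
            raise ValueError("self-loops are not allowed")
        order = np.lexsort((hi, lo))
        self.edges = np.column_stack([lo, hi])[order]
        if weights is not None:
            weights = np.asarray(weights, dtype=np.float64)[order]
            if np.any(~(weights > 0)):
                raise ValueError("edge weights must be positive")
        self.weights = weights
        if len(self.edges) and len(np.unique(self.edges, axis=0)) != len(self.edges):
            raise ValueError("duplicate edges are not allowed")
        known = set(self.node_ids.tolist())
        if len(self.edges) and not set(self.edges.ravel().tolist()) <= known:
            raise ValueError("edges reference unknown node IDs")
        self._index = {int(n): i for i, n in enumerate(self.node_ids)}

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def is_weighted(self) -> bool:
        return self.weights is not None

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.n_edges / self.n_nodes

    def edge_index(self) -> np.ndarray:
        """Edges as row indices into ``node_ids`` (m x 2)."""
        flat = np.fromiter(
            (self._index[int(v)] for v in self.edges.ravel()),
            dtype=np.int64,
            count=2 * self.n_edges,
        )
        return flat.reshape(-1, 2)

    def to_csr(self, weighted: Optional[bool] = None) -> sp.csr_matrix:
        """Symmetric CSR adjacency over internal indices 0..n-1.

        ``weighted=None`` uses weights when present; ``False`` forces a
        binary matrix; ``True`` requires weights.
        """
        if weighted is None:
            weighted = self.is_weighted
        if weighted and not self.is_weighted:
            raise ValueError("graph has no weights")
        e = self.edge_index()
        data = self.weights if weighted else np.ones(self.n_edges)
        n = self.n_nodes
        a = sp.coo_matrix(
            (np.concatenate([data, data]),
             (np.concatenate([e[:, 0], e[:, 1]]),
              np.concatenate([e[:, 1], e[:, 0]]))),
            shape=(n, n),
        )
        return a.tocsr()

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        if self.n_edges:
            e = self.edge_index()
            np.add.at(deg, e[:, 0], 1)
            np.add.at(deg, e[:, 1], 1)
        return deg

    def to_networkx(self):
        """Export as a :class:`networkx.Graph` (node labels = node IDs)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.node_ids.tolist())
        if self.is_weighted:
            g.add_weighted_edges_from(
                (int(a), int(b), float(w))
                for (a, b), w in zip(self.edges, self.weights)
            )
        else:
            g.add_edges_from((int(a), int(b)) for a, b in self.edges)
        return g


def _pair_distances(points: PointCloud, edges: np.ndarray) -> np.ndarray:
    pos = {int(n): i for i, n in enumerate(points.node_ids)}
    a = np.fromiter((pos[int(v)] for v in edges[:, 0]), dtype=np.int64,
                    count=len(edges))
    b = np.fromiter((pos[int(v)] for v in edges[:, 1]), dtype=np.int64,
                    count=len(edges))
    return np.linalg.norm(points.coordinates[a] - points.coordinates[b], axis=1)


def build_knn_graph(points: PointCloud, k: int, weighted: bool = False) -> ProximityGraph:
    """k-nearest-neighbour graph, symmetrised by union.

    Each node nominates its ``k`` closest neighbours; an edge exists when
    either endpoint nominates the other. With ``weighted=True`` edges carry
    weight ``1 / d_ij`` (inverse separation distance). Distance ties at the
    k-th neighbour (possible with duplicated coordinates) are broken in
    favour of the smaller node ID.
    """
    n = points.n_points
    if k >= n:
        raise ParameterError(f"k={k} must be smaller than n_points={n}")
    coords = points.coordinates
    # Duplicate coordinates break kd-tree tie determinism; fall back to an
    # explicit lexicographic sort in that (degenerate) case.
    has_dupes = len(np.unique(coords, axis=0)) != n
    if has_dupes:
        d = squareform(pdist(coords))
        np.fill_diagonal(d, np.inf)
        order = np.lexsort((np.broadcast_to(np.arange(n), (n, n)), d), axis=1)
        nbrs = order[:, :k]
    else:
        tree = cKDTree(coords)
        _, idx = tree.query(coords, k=k + 1)
        nbrs = np.where(idx[:, :k] != np.arange(n)[:, None], idx[:, :k], idx[:, k:])
    rows = np.repeat(np.arange(n), k)
    cols = nbrs.ravel()
    lo = np.minimum(rows, cols)
    hi = np.maximum(rows, cols)
    pairs = np.unique(np.column_stack([lo, hi]), axis=0)
    edges = np.column_stack([points.node_ids[pairs[:, 0]], points.node_ids[pairs[:, 1]]])
    weights = None
    if weighted:
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        if np.any(d == 0):
            raise ParameterError(
                "coincident points have zero separation; inverse-distance "
                "weights are undefined"
            )
        weights = 1.0 / d
    return ProximityGraph(points.node_ids, edges, weights)


def build_epsilon_ball_graph(points: PointCloud, epsilon: float) -> ProximityGraph:
    """Edge between every pair at distance <= epsilon (closed ball)."""
    if not epsilon > 0:
        raise ParameterError(f"epsilon must be positive, got {epsilon}")
    tree = cKDTree(points.coordinates)
    pairs = tree.query_pairs(epsilon, output_type="ndarray")
    edges = points.node_ids[pairs.reshape(-1)].reshape(-1, 2)
    return ProximityGraph(points.node_ids, edges)


def build_voronoi_graph(points: PointCloud) -> ProximityGraph:
    """Connect nodes whose Voronoi cells share a border (Delaunay dual).

    Degenerate inputs (all points collinear/coplanar) are jittered by
    ``1e-9 * L`` with a warning; if that still fails, an error suggests
    jittering the input.
    """
    coords = points.coordinates
    n, dim = coords.shape
    if n < dim + 1:
        raise ParameterError(
            f"Voronoi rule needs at least {dim + 1} points in {dim}D, got {n}"
        )
    try:
        tri = Delaunay(coords)
    except QhullError:
        scale = coords.max() - coords.min() or 1.0
        warnings.warn(
            "degenerate point configuration; jittering by 1e-9 * L for the "
            "Delaunay triangulation",
            stacklevel=2,
        )
        rng = np.random.default_rng(0)
        try:
            tri = Delaunay(coords + rng.normal(0, 1e-9 * scale, coords.shape))
        except QhullError as err:  # pragma: no cover - pathological input
            raise ParameterError(
                "points are degenerate even after jitter; perturb the input"
            ) from err
    s = tri.simplices
    pairs = set()
    for i in range(s.shape[1]):
        for j in range(i + 1, s.shape[1]):
            a, b = s[:, i], s[:, j]
            lo, hi = np.minimum(a, b), np.maximum(a, b)
            pairs.update(zip(lo.tolist(), hi.tolist()))
    pairs = np.array(sorted(pairs), dtype=np.int64)
    edges = np.column_stack([points.node_ids[pairs[:, 0]], points.node_ids[pairs[:, 1]]])
    return ProximityGraph(points.node_ids, edges)


def build_stochastic_graph(points: PointCloud, config: RuleConfig) -> ProximityGraph:
    """Independent Bernoulli edges with distance-dependent probability.

    Each unordered pair (i, j) receives an edge with probability
    ``f(d_ij)`` where ``f`` is ``exp(-d / decay_scale)`` truncated at
    ``3 * decay_scale`` for the decaying rule, or ``config.acceptance_fn``
    for ``random_rule``. Draws are independent and seeded.
    """
    if config.rule_kind == "decaying":
        lam = config.decay_scale
        fn = lambda d: np.exp(-np.asarray(d, dtype=float) / lam) * (
            np.asarray(d, dtype=float) <= 3.0 * lam
        )
    elif config.rule_kind == "random_rule":
        fn = config.acceptance_fn
    else:
        raise ParameterError(
            f"build_stochastic_graph handles decaying/random_rule, got "
            f"{config.rule_kind!r}"
        )
    coords = points.coordinates
    n = points.n_points
    rng = np.random.default_rng(config.seed)
    rows, cols = [], []
    for i in range(n - 1):
        d = np.linalg.norm(coords[i + 1:] - coords[i], axis=1)
        p = np.asarray(fn(d), dtype=np.float64)
        if np.any((p < 0) | (p > 1)):
            raise ParameterError("acceptance_fn must return values in [0, 1]")
        hit = np.where(rng.random(n - 1 - i) < p)[0]
        rows.append(np.full(len(hit), i))
        cols.append(hit + i + 1)
    rows = np.concatenate(rows) if rows else np.empty(0, dtype=np.int64)
    cols = np.concatenate(cols) if cols else np.empty(0, dtype=np.int64)
    edges = np.column_stack([points.node_ids[rows], points.node_ids[cols]])
    return ProximityGraph(points.node_ids, edges)


def build_graph(points: PointCloud, config: RuleConfig) -> ProximityGraph:
    """Dispatch to the generator for ``config.rule_kind``."""
    if config.rule_kind == "knn":
        return build_knn_graph(points, config.k, weighted=False)
    if config.rule_kind == "knn_weighted":
        return build_knn_graph(points, config.k, weighted=True)
    if config.rule_kind == "epsilon_ball":
        return build_epsilon_ball_graph(points, config.epsilon)
    if config.rule_kind == "voronoi":
        return build_voronoi_graph(points)
    return build_stochastic_graph(points, config)


def giant_component(graph: ProximityGraph):
    """Largest connected component and the fraction of nodes it retains.

    Ties between equal-sized components go to the one containing the
    smallest node ID. Returns ``(subgraph, retained_fraction)``.
    """
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    adj = graph.to_csr(weighted=False)
    _, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels)
    best = np.flatnonzero(sizes == sizes.max())
    if len(best) > 1:
        # smallest minimum node ID wins
        mins = [graph.node_ids[labels == b].min() for b in best]
        pick = best[int(np.argmin(mins))]
    else:
        pick = best[0]
    keep_idx = np.flatnonzero(labels == pick)
    keep_ids = set(graph.node_ids[keep_idx].tolist())
    mask = np.fromiter(
        (int(a) in keep_ids for a, _ in graph.edges),
        dtype=bool,
        count=graph.n_edges,
    )
    sub = ProximityGraph(
        graph.node_ids[keep_idx],
        graph.edges[mask],
        graph.weights[mask] if graph.is_weighted else None,
    )
    return sub, len(keep_idx) / graph.n_nodes


def acceptance_curve(
    points: PointCloud, graph: ProximityGraph, n_bins: int = 30
) -> pd.DataFrame:
    """Empirical edge probability vs. pair distance.

    Bins all unordered pairs by Euclidean distance and reports the fraction
    carrying an edge per bin (the empirical acceptance function of the
    generating rule). Empty bins are omitted. O(N^2) — intended for
    diagnostic scenes.
    """
    pts = points.subset(graph.node_ids)
    d = pdist(pts.coordinates)
    n = pts.n_points
    e = graph.edge_index()
    i, j = e[:, 0], e[:, 1]
    # condensed index of pair (i, j), i < j
    cond = (n * i - i * (i + 1) // 2 + (j - i - 1)).astype(np.int64)
    has_edge = np.zeros(len(d), dtype=bool)
    has_edge[cond] = True
    bins = np.linspace(0, d.max() * (1 + 1e-12), n_bins + 1)
    which = np.digitize(d, bins) - 1
    total = np.bincount(which, minlength=n_bins)
    hits = np.bincount(which, weights=has_edge, minlength=n_bins)
    occupied = total > 0
    centers = 0.5 * (bins[:-1] + bins[1:])
    return pd.DataFrame(
        {
            "distance_bin": centers[occupied],
            "edge_probability": hits[occupied] / total[occupied],
            "n_pairs": total[occupied],
        }
    )


def neighbor_frequency(
    points: PointCloud, graph: ProximityGraph, n_bins: int = 30
) -> pd.DataFrame:
    """Distribution of edge (neighbour) distances, normalised to sum to 1."""
    pts = points.subset(graph.node_ids)
    d = _pair_distances(pts, graph.edges)
    bins = np.linspace(0, d.max() * (1 + 1e-12), n_bins + 1)
    counts, _ = np.histogram(d, bins=bins)
    centers = 0.5 * (bins[:-1] + bins[1:])
    return pd.DataFrame(
        {"distance_bin": centers, "normalized_count": counts / counts.sum()}
    )


def hop_distance_profile(
    points: PointCloud, graph: ProximityGraph, max_pairs: int = 4_000_000
) -> pd.DataFrame:
    """Mean Euclidean distance per shortest-path hop count.

    The monotone growth of this profile is what makes geometry recoverable
    from topology: each hop count maps to an expected physical distance.
    Computed over all pairs of the (connected) graph; O(N^2) memory.
    """
    pts = points.subset(graph.node_ids)
    n = pts.n_points
    if n * (n - 1) // 2 > max_pairs:
        raise ValueError("graph too large for an all-pairs hop profile")
    hops = shortest_path(graph.to_csr(weighted=False), method="D", unweighted=True)
    if np.isinf(hops).any():
        raise ValueError("graph is disconnected; reduce to the giant component")
    iu = np.triu_indices(n, 1)
    h = hops[iu].astype(np.int64)
    d = pdist(pts.coordinates)
    df = (
        pd.DataFrame({"hops": h, "distance": d})
        .groupby("hops")["distance"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_distance", "count": "n_pairs"})
    )
    return df


# --- default rule library ------------------------------------------------

def _soft_step(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return 0.8 / (1.0 + np.exp((x - 0.75) / 0.1)) * (x <= 1.2)


def _nonmonotone_mixture(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return (
        0.9 * np.exp(-(x ** 2) / (2 * 0.35 ** 2))
        + 0.4 * np.exp(-((x - 0.8) ** 2) / (2 * 0.15 ** 2))
    ) * (x <= 1.2)


def _annulus(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return 0.7 * ((x >= 0.15) & (x <= 1.0)).astype(float)


#: Representative bounded acceptance shapes for the "arbitrary rule"
#: families: a blurred step (a noisy epsilon-ball), a nonmonotone mixture,
#: and a hard-shell annulus. Each maps a *scaled* distance x = d / s; the
#: scale s is calibrated per scene by :func:`calibrate_scale`.
ACCEPTANCE_LIBRARY = {
    "random1": (_soft_step, 1.2),
    "random2": (_nonmonotone_mixture, 1.2),
    "random3": (_annulus, 1.0),
}

#: Dimensionless support bound of the truncated exponential decay shape.
_DECAY_SHAPE = (lambda x: np.exp(-np.asarray(x, dtype=float))
                * (np.asarray(x, dtype=float) <= 3.0), 3.0)


def calibrate_scale(
    shape_fn: Callable[[float], float],
    x_max: float,
    dimension: int,
    density: float,
    target_degree: float = TARGET_MEAN_DEGREE,
) -> float:
    """Distance scale s so a Bernoulli rule p(d) = shape(d / s) yields the
    target mean degree at the given point density.

    Uses the bulk approximation E[deg] = density * integral of shape(r / s)
    over the sphere shell measure; boundary effects reduce the realised
    degree slightly.
    """
    if dimension == 2:
        c = quad(lambda x: float(shape_fn(x)) * 2 * np.pi * x, 0, x_max)[0]
    elif dimension == 3:
        c = quad(lambda x: float(shape_fn(x)) * 4 * np.pi * x ** 2, 0, x_max)[0]
    else:
        raise ParameterError(f"dimension must be 2 or 3, got {dimension}")
    return (target_degree / (density * c)) ** (1.0 / dimension)


def default_rules(
    dimension: int,
    n_points: int,
    seed: int = 0,
    side_length: float = 1.0,
    target_degree: float = TARGET_MEAN_DEGREE,
    include_weighted: bool = False,
) -> list[RuleConfig]:
    """The seven standard rule configs, calibrated to a common mean degree.

    Returns knn, epsilon_ball, voronoi, decaying and the three library
    random rules (plus the distance-weighted kNN variant when
    ``include_weighted``). kNN uses k such that union symmetrisation lands
    near the target degree; epsilon and the stochastic scales follow the
    closed-form/bulk-integral calibration. The Voronoi rule has no
    parameter (its 3D mean degree is ~15 by itself; in 2D it is ~6).
    """
    density = n_points / side_length ** dimension
    if dimension == 2:
        eps = (target_degree / (np.pi * density)) ** 0.5
    else:
        eps = (target_degree / (4.0 / 3.0 * np.pi * density)) ** (1.0 / 3.0)
    # union symmetrisation inflates mean degree ~25-40% above k
    k = max(1, int(round(target_degree / 1.28)))
    decay_shape, decay_xmax = _DECAY_SHAPE
    lam = calibrate_scale(decay_shape, decay_xmax, dimension, density, target_degree)
    rules = [
        RuleConfig("knn", k=k, name="knn"),
        RuleConfig("epsilon_ball", epsilon=eps, name="epsilon_ball"),
        RuleConfig("voronoi", name="voronoi"),
        RuleConfig("decaying", decay_scale=lam, seed=seed, name="decaying"),
    ]
    if include_weighted:
        rules.insert(1, RuleConfig("knn_weighted", k=k, name="knn_weighted"))
    for i, (label, (fn, x_max)) in enumerate(ACCEPTANCE_LIBRARY.items()):
        s = calibrate_scale(fn, x_max, dimension, density, target_degree)
        rules.append(
            RuleConfig(
                "random_rule",
                acceptance_fn=lambda d, fn=fn, s=s: fn(np.asarray(d, dtype=float) / s),
                seed=seed + 1 + i,
                name=label,
            )
        )
    return rules
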