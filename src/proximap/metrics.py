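"""Ground-truth quality metrics for reconstructed point clouds.

Three standards, from fine to coarse:

* **KNN quality** — mean overlap fraction between each node's K nearest
  neighbours in the original vs. the reconstructed cloud. Invariant to any
  similarity transform of either cloud. A random arrangement scores about
  K / (N - 1).
* **CPD quality** — Pearson correlation of all pairwise distances between
  the two clouds. Scale- and rigid-motion-invariant; 1 means relative
  distances are perfectly preserved.
* **Mean distortion** — per-node displacement after a least-squares affine
  alignment of the reconstruction onto the original, in units of the scene
  length L. The affine fit absorbs the similarity ambiguity of manifold
  output (and any shear), so only genuine shape error remains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr

from .scene import PointCloud

#: Above this many pairs, CPD subsamples with a seeded generator.
CPD_PAIR_CAP = 20_000_000


class MetricError(ValueError):
    """Raised when a metric is undefined for the given inputs."""


@dataclass(frozen=True)
class MetricConfig:
    """Evaluation settings. ``knn_k`` defaults to 15, the typical neighbour
    count of a 3D Voronoi tessellation."""

    knn_k: int = 15
    cpd_seed: int = 0

    def __post_init__(self) -> None:
        if self.knn_k < 1:
            raise ValueError("knn_k must be positive")


@dataclass
class QualityReport:
    """Bundle of the three metrics plus bookkeeping.

    ``retained_fraction`` is the share of input nodes kept by the
    giant-component reduction (1.0 when nothing was dropped).
    """

    knn_quality: float
    cpd_quality: float
    mean_distortion: float
    per_node_distortion: np.ndarray
    retained_fraction: float = 1.0
    n_points: int = 0

    def __post_init__(self) -> None:
        self.per_node_distortion = np.asarray(self.per_node_distortion, dtype=float)
        if not 0 <= self.knn_quality <= 1:
            raise ValueError("knn_quality must be in [0, 1]")
        if not -1 <= self.cpd_quality <= 1 + 1e-12:
            raise ValueError("cpd_quality must be in [-1, 1]")
        if self.mean_distortion < 0:
            raise ValueError("mean_distortion must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "knn_quality": float(self.knn_quality),
            "cpd_quality": float(self.cpd_quality),
            "mean_distortion": float(self.mean_distortion),
            "retained_fraction": float(self.retained_fraction),
            "n_points": int(self.n_points),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _aligned(original: PointCloud, reconstructed: PointCloud):
    o_ids = set(original.node_ids.tolist())
    r_ids = set(reconstructed.node_ids.tolist())
    if o_ids != r_ids:
        missing = sorted(o_ids ^ r_ids)[:10]
        raise MetricError(
            f"node ID sets differ (e.g. {missing}); clouds must label the "
            "same nodes"
        )
    recon = reconstructed.subset(original.node_ids)
    return original.coordinates, recon.coordinates


def knn_quality(
    original: PointCloud,
    reconstructed: PointCloud,
    config: MetricConfig = MetricConfig(),
) -> float:
    """Mean K-nearest-neighbour overlap fraction between the clouds."""
    a, b = _aligned(original, reconstructed)
    n = len(a)
    k = config.knn_k
    if k >= n:
        raise MetricError(f"knn_k={k} must be smaller than n_points={n}")
    _, ia = cKDTree(a).query(a, k=k + 1)
    _, ib = cKDTree(b).query(b, k=k + 1)
    # drop self (column of the query point itself)
    ia = ia[:, 1:]
    ib = ib[:, 1:]
    overlap = np.empty(n)
    for i in range(n):
        overlap[i] = len(np.intersect1d(ia[i], ib[i], assume_unique=True))
    return float(overlap.mean() / k)


def cpd_quality(
    original: PointCloud,
    reconstructed: PointCloud,
    config: MetricConfig = MetricConfig(),
) -> float:
    """Pearson correlation of pairwise distances (original vs. recon).

    Above :data:`CPD_PAIR_CAP` pairs, a seeded random subsample of pairs is
    used instead of the full O(N^2) set.
    """
    a, b = _aligned(original, reconstructed)
    n = len(a)
    if n < 3:
        raise MetricError("CPD needs at least 3 points")
    n_pairs = n * (n - 1) // 2
    if n_pairs > CPD_PAIR_CAP:
        rng = np.random.default_rng(config.cpd_seed)
        i = rng.integers(0, n, size=CPD_PAIR_CAP)
        j = rng.integers(0, n, size=CPD_PAIR_CAP)
        keep = i != j
        i, j = i[keep], j[keep]
        da = np.linalg.norm(a[i] - a[j], axis=1)
        db = np.linalg.norm(b[i] - b[j], axis=1)
    else:
        da = pdist(a)
        db = pdist(b)
    if da.std() == 0 or db.std() == 0:
        raise MetricError("pairwise distances have zero variance")
    return float(pearsonr(da, db)[0])


def fit_affine(original: PointCloud, reconstructed: PointCloud):
    """Least-squares affine map (A, b) minimising
    sum ||A @ recon_i + b - orig_i||^2, by the normal equations."""
    y, x = _aligned(original, reconstructed)
    n, dim = x.shape
    if n <= dim + 1:
        raise MetricError(f"need more than {dim + 1} points for an affine fit")
    design = np.column_stack([x, np.ones(n)])
    if np.linalg.matrix_rank(design) < dim + 1:
        raise MetricError(
            "points are rank-deficient (collinear/coplanar); affine map is "
            "not identifiable"
        )
    sol, *_ = np.linalg.lstsq(design, y, rcond=None)
    return sol[:-1].T, sol[-1]


def mean_distortion(original: PointCloud, reconstructed: PointCloud):
    """Per-node displacement after affine alignment; returns
    ``(mean, per_node)`` in units of the original cloud's length scale."""
    a_mat, offset = fit_affine(original, reconstructed)
    y, x = _aligned(original, reconstructed)
    aligned = x @ a_mat.T + offset
    per_node = np.linalg.norm(aligned - y, axis=1)
    return float(per_node.mean()), per_node


def evaluate(
    original: PointCloud,
    reconstructed: PointCloud,
    config: MetricConfig = MetricConfig(),
    retained_fraction: float = 1.0,
) -> QualityReport:
    """All three metrics on the nodes present in the reconstruction.

    When the reconstruction covers a subset of the original nodes (giant
    component), the original cloud is restricted to that subset first.
    """
    orig = original
    if set(original.node_ids.tolist()) != set(reconstructed.node_ids.tolist()):
        orig = original.subset(reconstructed.node_ids)
    mean_d, per_node = mean_distortion(orig, reconstructed)
    return QualityReport(
        knn_quality=knn_quality(orig, reconstructed, config),
        cpd_quality=cpd_quality(orig, reconstructed, config),
        mean_distortion=mean_d,
        per_node_distortion=per_node,
        retained_fraction=retained_fraction,
        n_points=reconstructed.n_points,
    )
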