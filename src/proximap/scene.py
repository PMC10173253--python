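"""Ground-truth molecular scenes: uniform point clouds in a square or cube.

A scene models the dispersion of DNA molecules over a region of
characteristic length ``L`` (default 1) ahead of network formation.
Molecule identities carry no positional information, so positions are drawn
i.i.d. uniform over ``[0, L]^dimension``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConfigurationError(ValueError):
    """Raised when a config field violates its contract."""


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a simulated molecular scene.

    Parameters
    ----------
    dimension : int
        Spatial dimension, 2 or 3.
    n_points : int
        Number of molecules N. Must be at least ``dimension + 2`` so that
        Voronoi tessellation and the manifold stage are non-degenerate.
    side_length : float
        Characteristic length L of the square/cube; coordinates live in
        ``[0, L]``.
    seed : int
        Seed for the position sampler.
    """

    dimension: int
    n_points: int
    side_length: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dimension not in (2, 3):
            raise ConfigurationError(
                f"dimension must be 2 or 3, got {self.dimension}"
            )
        if self.n_points < self.dimension + 2:
            raise ConfigurationError(
                f"n_points must be >= dimension + 2 = {self.dimension + 2}, "
                f"got {self.n_points}"
            )
        if not self.side_length > 0:
            raise ConfigurationError(
                f"side_length must be positive, got {self.side_length}"
            )


@dataclass
class PointCloud:
    """Node IDs with their (ground-truth or reconstructed) coordinates.

    ``node_ids[i]`` labels row ``i`` of ``coordinates`` (N x dimension).
    """

    node_ids: np.ndarray
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, dtype=np.float64))
        if self.node_ids.ndim != 1:
            raise ValueError("node_ids must be one-dimensional")
        if len(self.node_ids) != len(self.coordinates):
            raise ValueError(
                f"{len(self.node_ids)} node_ids vs {len(self.coordinates)} rows"
            )
        if len(np.unique(self.node_ids)) != len(self.node_ids):
            raise ValueError("node_ids must be unique")

    @property
    def n_points(self) -> int:
        return len(self.node_ids)

    @property
    def dimension(self) -> int:
        return self.coordinates.shape[1]

    def subset(self, node_ids: np.ndarray) -> "PointCloud":
        """Rows for the given node IDs, in the given order."""
        pos = {nid: i for i, nid in enumerate(self.node_ids)}
        missing = [int(n) for n in node_ids if n not in pos]
        if missing:
            raise KeyError(f"node IDs not in cloud: {missing[:10]}")
        rows = np.fromiter((pos[n] for n in node_ids), dtype=np.int64,
                           count=len(node_ids))
        return PointCloud(np.asarray(node_ids), self.coordinates[rows])


def generate_scene(config: SceneConfig, sampler=None) -> PointCloud:
    """Draw ``n_points`` positions i.i.d. uniform over ``[0, L]^dimension``.

    Node IDs are dense integers ``0 .. N-1``. The draw is reproducible:
    identical configs give bit-identical clouds.

    ``sampler`` is an extension hook for nonuniform scenes (e.g. density
    anomalies): a callable ``(rng, n_points, dimension) -> (n, dim) array``
    in ``[0, 1]^dimension``, scaled by ``side_length`` afterwards.
    """
    rng = np.random.default_rng(config.seed)
    if sampler is None:
        unit = rng.random((config.n_points, config.dimension))
    else:
        unit = np.asarray(sampler(rng, config.n_points, config.dimension))
        if unit.shape != (config.n_points, config.dimension):
            raise ConfigurationError(
                f"sampler returned shape {unit.shape}, expected "
                f"{(config.n_points, config.dimension)}"
            )
    return PointCloud(np.arange(config.n_points), unit * config.side_length)
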