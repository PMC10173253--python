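"""File formats: coordinate tables, edge lists, embeddings, reports.

Coordinates travel as CSV with header ``node_id,x,y[,z]``. Edge lists are
TSV ``source<TAB>target[<TAB>weight]`` without a header by default — the
interchange format standing in for the edge catalogue a sequencing run
produces. Embeddings checkpoint as TSV with a ``node_id`` column plus one
column per feature dimension.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .discovery import EmbeddingMatrix
from .graphs import ProximityGraph
from .scene import PointCloud

PathLike = Union[str, Path]

_AXES = ("x", "y", "z")


def write_points(points: PointCloud, path: PathLike) -> None:
    cols = {"node_id": points.node_ids}
    for i in range(points.dimension):
        cols[_AXES[i]] = points.coordinates[:, i]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_points(path: PathLike) -> PointCloud:
    df = pd.read_csv(path)
    if "node_id" not in df.columns:
        raise ValueError(f"{path}: missing 'node_id' column")
    axes = [a for a in _AXES if a in df.columns]
    if len(axes) not in (2, 3):
        raise ValueError(f"{path}: expected coordinate columns x,y[,z]")
    return PointCloud(df["node_id"].to_numpy(), df[axes].to_numpy(float))


def write_edge_list(graph: ProximityGraph, path: PathLike, header: bool = False) -> None:
    cols = {"source": graph.edges[:, 0], "target": graph.edges[:, 1]}
    if graph.is_weighted:
        cols["weight"] = graph.weights
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, header=header)


def read_edge_list(path: PathLike, header: Optional[bool] = None) -> ProximityGraph:
    """Parse a TSV/CSV edge list into a :class:`ProximityGraph`.

    Two node-ID columns, optional third weight column. ``header=None``
    auto-detects a header row (non-numeric first line). Malformed lines are
    reported with their line number.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty edge list")
    start = 0
    first = lines[0].split(sep)
    if header or (header is None and any(not _is_number(t) for t in first[:2])):
        start = 1
    src, dst, wts = [], [], []
    has_weight = None
    for ln, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.split(sep)
        if len(parts) not in (2, 3):
            raise ValueError(
                f"{path}:{ln}: expected 2 or 3 columns, got {len(parts)}"
            )
        try:
            src.append(int(parts[0]))
            dst.append(int(parts[1]))
        except ValueError as err:
            raise ValueError(f"{path}:{ln}: non-integer node ID") from err
        row_weighted = len(parts) == 3
        if has_weight is None:
            has_weight = row_weighted
        elif has_weight != row_weighted:
            raise ValueError(f"{path}:{ln}: inconsistent column count")
        if row_weighted:
            try:
                wts.append(float(parts[2]))
            except ValueError as err:
                raise ValueError(f"{path}:{ln}: non-numeric weight") from err
    edges = np.column_stack([src, dst]).astype(np.int64)
    node_ids = np.unique(edges)
    weights = np.asarray(wts) if has_weight else None
    return ProximityGraph(node_ids, edges, weights)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_embedding(embedding: EmbeddingMatrix, path: PathLike) -> None:
    df = pd.DataFrame(
        embedding.vectors,
        columns=[f"f{i}" for i in range(embedding.dim)],
    )
    df.insert(0, "node_id", embedding.node_ids)
    df.to_csv(path, sep="\t", index=False)


def read_embedding(path: PathLike) -> EmbeddingMatrix:
    df = pd.read_csv(path, sep="\t")
    if "node_id" not in df.columns:
        raise ValueError(f"{path}: missing 'node_id' column")
    feats = [c for c in df.columns if c != "node_id"]
    return EmbeddingMatrix(df["node_id"].to_numpy(), df[feats].to_numpy(np.float32))


def write_distortion_map(
    node_ids: np.ndarray, per_node_distortion: np.ndarray, path: PathLike
) -> None:
    """Per-node distortions as CSV, for plotting distortion maps."""
    pd.DataFrame(
        {"node_id": node_ids, "distortion": per_node_distortion}
    ).to_csv(path, index=False)
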