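"""Recover coordinates from an edge-list file of unknown origin.

Writes a proximity network to the TSV interchange format (the stand-in for
an edge catalogue distilled from sequencing reads), then reconstructs
molecular positions from that file alone — no coordinates, no knowledge of
the generating rule.
"""

import tempfile
from pathlib import Path

from proximap import (
    ReductionConfig,
    SceneConfig,
    WalkConfig,
    build_voronoi_graph,
    evaluate,
    generate_scene,
    io,
    run_recover,
)

scene = generate_scene(SceneConfig(dimension=2, n_points=800, seed=5))
graph = build_voronoi_graph(scene)

workdir = Path(tempfile.mkdtemp())
edge_file = workdir / "network.tsv"
io.write_edge_list(graph, edge_file)
print(f"wrote {graph.n_edges} edges to {edge_file}")

recon = run_recover(edge_file, WalkConfig(seed=6),
                    ReductionConfig(target_dim=2, seed=7))
report = evaluate(scene, recon)
print(f"recovered {recon.n_points} positions from the edge list alone")
print(f"KNN quality {report.knn_quality:.3f}, CPD {report.cpd_quality:.3f} "
      "against the (withheld) ground truth")
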