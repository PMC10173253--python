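"""Diagnostics of a proximity rule: acceptance curve, edge lengths, hops.

The empirical acceptance curve recovers the rule's distance-to-probability
mapping; the hop-distance profile shows the monotone link between graph
shortest paths and physical distance that makes reconstruction possible.
"""

from proximap import (
    SceneConfig,
    acceptance_curve,
    build_epsilon_ball_graph,
    generate_scene,
    giant_component,
    hop_distance_profile,
    neighbor_frequency,
)

scene = generate_scene(SceneConfig(dimension=2, n_points=1000, seed=3))
graph = build_epsilon_ball_graph(scene, epsilon=0.07)
graph, retained = giant_component(graph)
print(f"epsilon-ball graph: mean degree {graph.mean_degree:.1f}, "
      f"{100 * retained:.1f}% of nodes in the giant component")

curve = acceptance_curve(scene, graph, n_bins=20)
print("\nacceptance probability by distance (step at epsilon = 0.07):")
print(curve.head(8).to_string(index=False))

freq = neighbor_frequency(scene, graph, n_bins=10)
print("\nedge-length distribution (sums to 1):")
print(freq.to_string(index=False))

profile = hop_distance_profile(scene, graph)
print("\nmean Euclidean distance per hop count (monotone increase):")
print(profile.head(8).to_string(index=False))
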