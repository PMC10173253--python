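# Methods

## The problem

Imaging-by-sequencing experiments record which pairs of DNA molecules became
physically associated, producing — after sequencing and edge cataloguing — a
*proximity graph*: nodes are molecules, edges encode spatial closeness, and
no coordinates are observed. `proximap` reconstructs 2D/3D molecular
coordinates from such a graph alone, without knowledge of the rule that
generated the edges, and quantifies reconstruction quality against simulated
ground truth.

## The reconstruction model

Reconstruction is a staged dimensionality reduction of the N x N adjacency
matrix:

1. **Structural discovery.** Biased random walks (Node2Vec-style, with
   return parameter p and in-out parameter q; p = q = 1 by default, i.e.
   first-order walks) sample each node's neighbourhood. The walks are
   treated as sentences and fed to skip-gram with negative sampling, giving
   every node a feature vector of dimension D << N. Because walk
   co-occurrence decays with graph distance, and graph distance grows
   monotonically with physical distance for all the proximity rules
   considered (see the hop-distance profile diagnostic), feature-space
   proximity encodes spatial proximity.
2. **Manifold reduction.** UMAP maps the N x D feature matrix to N x 2 or
   N x 3 coordinates. Output is defined only up to a similarity transform;
   all evaluation metrics are invariant to that ambiguity or align first.

The staged route never materialises an N x N matrix, so its cost grows
near-linearly with N. The package also ships the *nonstaged baseline* —
UMAP applied directly to the all-pairs shortest-path distance matrix —
whose cost and memory grow near-quadratically; it exists for comparison,
not production use.

The skip-gram trainer is implemented in-package as a single-threaded numba
kernel (sigmoid lookup table, linear learning-rate decay, per-position
window subsampling, unigram^0.75 negative table). Being single-threaded and
fully seeded, the entire pipeline is deterministic given a master seed —
walks, training and the seeded UMAP reduction included.

## Scene and graph simulators

Scenes are N points i.i.d. uniform over a square or cube of side L = 1
(hard boundaries; no periodic wrap — border nodes genuinely have
anisotropic neighbourhoods, and they show elevated distortion in
reconstructions). Seven proximity-rule families convert a scene to a graph:

| rule | edge criterion | default parameter |
|---|---|---|
| kNN (optionally inverse-distance weighted) | either endpoint is among the other's k nearest | k = 12 |
| epsilon-ball | d <= epsilon (closed ball) | epsilon s.t. expected degree 15 |
| Voronoi | cells share a border (Delaunay dual) | parameter-free |
| decaying | Bernoulli, p(d) = exp(-d/lambda), truncated at 3 lambda | lambda s.t. expected degree 15 |
| random1 | Bernoulli, soft step (blurred epsilon-ball) | scale s.t. expected degree 15 |
| random2 | Bernoulli, nonmonotone two-bump mixture | scale s.t. expected degree 15 |
| random3 | Bernoulli, hard-shell annulus | scale s.t. expected degree 15 |

Parameters are calibrated so every rule yields mean degree ~15 (the typical
neighbour count of a 3D Voronoi tessellation) via the bulk integral
`E[deg] = density * Int p(r) dV`; boundary effects push realised degrees a
little lower (~12-14). The Voronoi rule has no dial: its mean degree is ~6
in 2D and ~15.5 in 3D. kNN uses k = 12 because union symmetrisation
inflates the realised degree by ~25-40% above k.

The three "arbitrary" stochastic shapes are this package's own choices (the
class is open-ended by definition). They are given *compact, near-origin
support*: acceptance functions whose mass sits far from the origin node
produce graphs whose 1-hop neighbourhoods carry little fine-grained spatial
information, and local reconstruction quality degrades accordingly — see
"known limitations" below. A custom acceptance function can be supplied
through `RuleConfig("random_rule", acceptance_fn=...)`.

## Structural-discovery defaults

Defaults: D = 32, walk length 60, 6 walks/node, window 4, 4 negatives,
3 epochs, initial learning rate 0.025. These were benchmarked across rule
families at N around 2000 in both dimensions: against heavier settings
(D = 64, walk length 100, window 10, 5 epochs) they gave equal or *better*
KNN/CPD quality at roughly an eighth of the training cost. Quality is flat
in a broad region around these values; window size is the most sensitive
knob (large windows blur local structure). Larger systems (N >> 10^4) need
D and walk length scaled up to keep accuracy, which is exposed in
`WalkConfig`.

UMAP defaults: n_neighbors = 15 (mirroring the K = 15 evaluation
neighbourhood), min_dist = 0.1, Euclidean metric on feature vectors.
Raising n_neighbors to 30 and the optimisation to 800 epochs moves results
by under one point of either metric at desk scale; min_dist = 0.01 hurts
both metrics. For inputs with fewer than 8 points UMAP's spectral machinery
is degenerate and a classical (Torgerson) MDS is used instead — relevant
only to toy graphs.

## Quality metrics

* **KNN quality** (local): mean overlap fraction of each node's K = 15
  nearest neighbours in original vs. reconstructed clouds. Chance level is
  K/(N-1).
* **CPD quality** (global): Pearson correlation over all N(N-1)/2 pairwise
  distance pairs; above 2 x 10^7 pairs a seeded random pair subsample is
  used.
* **Mean distortion**: per-node displacement after a least-squares *affine*
  alignment of the reconstruction onto the original (normal equations). The
  affine fit absorbs the similarity ambiguity of manifold output exactly,
  so an exact affine image scores zero. The exact neighbourhood-overlap
  form of the local metric is this package's reading of "difference between
  original and reconstructed neighbourhoods"; alternatives (e.g. Jaccard)
  order methods identically in practice.

Reconstruction runs on the giant component only; the retained fraction is
carried in the `QualityReport`. With degree ~15 the giant component is
>99.9% of nodes for every default rule.

## Numerical and degenerate-input choices

* epsilon-ball uses the closed ball (d <= epsilon); the boundary has
  measure zero for continuous coordinates.
* kNN distance ties (possible only with duplicated coordinates) are broken
  toward the smaller node ID via an explicit brute-force path; the kd-tree
  fast path handles the generic case.
* Degenerate (collinear/coplanar) inputs to the Voronoi rule are jittered
  by 1e-9 L with a warning.
* Giant-component ties go to the component containing the smallest node ID.
* Affine fits reject rank-deficient designs rather than returning a
  pseudo-inverse solution silently.

## What the simulator does and does not emulate

The generator reproduces the geometry side of an imaging-by-sequencing
experiment: unknown molecule positions, proximity-driven association under
diverse (including stochastic and nonmonotone) rules, and loss of all
coordinate information. It does **not** model sequencing errors, chimeric
edges, density inhomogeneities, or any association chemistry; passing tests
therefore demonstrate recoverability of geometry from clean topology, not
robustness to systematic network noise.

## Problem sizes used in tests and the acceptance script

The shipped validation runs the rule-robustness sweep at N = 2000 with
three seeds per dimension, single-rule checks at N = 1000, and the scaling
trend over N in {1000, 2000, 4000, 8000} — desk-scale sizes chosen so the
whole suite completes comfortably on one CPU. The scaling comparison needs
the N = 8000 point: below it the nonstaged baseline's quadratic terms
(breadth-first searches, distance-matrix row sorts) carry such small
constants that its linear UMAP optimisation phase dominates the wall time,
and the asymptotic gap between the two routes is not yet visible. These are reduced-scale
reproductions; metric *levels* at these sizes are below their large-N
plateau, and cross-rule *variation* is correspondingly wider (see below).

## Known limitations

* **Cross-rule variation at reduced scale.** At N = 2000 the local (KNN)
  quality differs by rule family by roughly 10-16 percentage points
  (2D/3D), dominated by two effects: the Voronoi rule's short, regular
  edges make it the easiest graph locally, and stochastic rules whose
  acceptance functions spread edge mass toward larger distances (notably
  the truncated-exponential decaying rule) are intrinsically harder — each
  node's 1-hop neighbourhood is a noisy sample of a wider ball. The
  variation shrinks with system size (e.g. 2D CPD variation halves from
  N = 2000 to N = 5000 and KNN variation falls by ~3 points), and
  benchmarking heavier walk/training/UMAP settings moved no rule by more
  than a point, indicating an information limit of small noisy graphs
  rather than an optimisation shortfall.
* 3D reconstructions at desk scale have lower CPD than 2D ones and their
  cross-rule CPD spread is larger; the ordering of 2D vs. 3D global
  variation can invert relative to large-scale behaviour.
* Walks and training are single-threaded by design (determinism); large-N
  users pay for reproducibility in wall-clock time.
* No ground-truth-free quality metrics: evaluation requires the original
  coordinates, so experimental use gives reconstructions without scores.
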