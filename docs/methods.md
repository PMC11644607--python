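# Methods

This note documents the models and numerical choices behind `phenopot3d`:
what each stage assumes, which parameters matter and why their defaults are
what they are, what the synthetic generator does and does not emulate, and
the known limitations.

## Pipeline model and assumptions

The toolkit assumes a single potted plant standing upright in a metric (or
metrically calibratable) point cloud: one stem rising from the lowest point
of the plant, leaves attached along and atop the stem, background and pot
below a separable z level. Under these assumptions geodesics from the stem
base to any surface point run up the stem before dead-ending inside a
blade, which is what the path segmentation exploits.

### Calibration and filtering

Scale correction multiplies all coordinates by `K = h_real/h_model`; it is
applied before any filtering so that every later threshold (voxel size,
neighbor radii, slab heights) is in meters. The pass-through filter keeps
`z_min < z < z_max` with strict inequalities; bounds are set per plant (the
pot rim and a generous top margin). Statistical outlier removal uses
`k = 20` neighbors and `ratio = 2.0` — conventional values; the filter's
job here is to trim the far tail of the sensor-noise distribution, to which
the caliper-type measurements below are the most sensitive.

### Voxel graph and path analysis

Voxelization regularizes the sampling before graph construction; the voxel
size defaults to 0.002 m. The neighbor threshold for graph edges is
0.003 m, so an occupied 3D grid at the default voxel size is 18-connected
(face neighbors at 0.002, edge diagonals at 0.0028). A voxel size of
0.004 m would leave the radius graph at this threshold with no edges at
all, which is why the default sits at half that; users changing one of the
two parameters should keep `voxel_size < nbrs_threshold / sqrt(2)`.

Disconnected surface patches (petioles, occlusion holes) are bridged by
gap filling: candidate edges are each node's `k_nn` nearest neighbors and
the shortest inter-component candidates are accepted until the graph is
connected (Kruskal restricted to the k-NN candidate set, so each accepted
bridge is the closest available inter-component pair). `k_nn` is a budget:
too small a budget (e.g. 5) cannot see across real gaps and the build
fails with an explicit disconnection error listing component sizes.
Components below 1 % of the voxels are tolerated and later labeled noise.

The shortest-path tree is grown from the lowest voxel (ties broken by x,
then y) with Dijkstra. *Backtracking*: walking back from every path tip
toward the root, a node remains leaf only while all walks through it are
within their first `k_retrace` hops — equivalently, a node is leaf iff
every tip reachable from it through nodes at greater root distance lies
fewer than `k_retrace` hops beyond it. This is computed in one descending
sweep over the geodesic distance field with a union-find over superlevel
components (a merge-tree traversal). The formulation matters: on densely
sampled 2D surfaces the shortest-path tree itself is unreliable — branches
coalesce, most nodes are spurious tree leaves (in our probes over half the
stem voxels were tree tips) — whereas the superlevel-component form depends
only on the distance field and degrades gracefully. On 1D chains and
Y-graphs both formulations coincide exactly.

One hop is the median tree-edge length, ~1.4× the voxel size on an
18-connected grid, so `k_retrace` has metric reach `≈ 1.4 · voxel_size ·
k_retrace`. The default `k_retrace = 135` corresponds to the effective
operating point reported for greenhouse-scale plants; for the 0.25 m
synthetic fixtures the same rule gives `k_retrace ≈ 44–50`
(`suggested_config` sizes it as 1.1× the longest blade arc plus petiole,
plus two hops of margin). Behavior at the extremes is intrinsic and
monotone: too few steps leave blade interiors labeled stem, too many eat
the upper stem; the mid-range maximizes both F1 scores.

The stem class is the inverse of the leaf mask over reachable voxels;
unreachable voxels are noise. A radius filter (default: at least 5
neighbors within 0.005 m) then removes isolated stem points.

### Leaf instances

k-means (seeded k-means++, Lloyd, tolerance 1e-6, ≤300 iterations) first
cuts the canopy into k groups, with k estimated as the number of
radius-graph connected components at 3× the DBSCAN radius, ignoring
components smaller than the minimum instance size — stray debris must not
inflate the leaf count. DBSCAN inside each k-means group separates leaves
that k-means merged and sheds sparse debris as noise. The DBSCAN radius
defaults to 4× the median nearest-neighbor distance: with the density
criterion `min_pts = 10`, interior blade points then have ~25 neighbors,
comfortably above threshold; a radius of 2.5× spacing puts the expected
neighbor count *at* `min_pts`, i.e. at the percolation threshold, and
blades shatter. DBSCAN is implemented exactly (core iff ≥ min_pts
neighbors within eps, self included; border points go to the cluster of
their first-discovered core neighbor in index order) so results are
deterministic and oracle-checkable.

Two refinements follow. First, canopy patches that are surface-continuous
with the stem (point gap ≤ 1.5 voxels) *and* tube-shaped (OBB thickness ≥
half its width) are handed back to the stem class: they are backtracking
overshoot around the apex, not blades — blades hang off the stem behind a
petiole gap and are sheet-like. Second, fragments of a single blade are
merged when their oriented boxes overlap by ≥ 30 % of the smaller volume,
or when the boxes touch *and* the fragments' point sets come within 5 mm.
Box contact alone is not trusted: loose boxes of tilted blades often
intersect even for clearly distinct leaves. Degenerate flat boxes are
inflated to 0.1 mm half-thickness before volume computation. The
`low_confidence` flag is raised when instances sit closer than eps or an
instance falls apart at eps/2 — the signature of adjacent blades fused
through a marginal density bridge, the known failure mode of tightly
packed rosettes; the touching-leaves fixture exercises it.

### Trait measurements and noise

Height, caliper widths and OBB extents are *extrema*, and extrema feel the
tail of the noise distribution, not its width: with isotropic noise
σ = 0.5 mm, the two-furthest-points stem caliper across a few hundred slab
points overreads by ~2·(2.5σ) ≈ 2.5 mm — 20 % of a 12 mm stem. All extent
measurements therefore run on a voxel-centroid-denoised copy of the organ:
points are averaged within grid cells, which suppresses noise by roughly
the square root of the cell occupancy, and cells below a minimum occupancy
are dropped, because a lone point in an otherwise empty cell *is* the
un-averaged tail. Grids: 0.003 m with occupancy ≥ 2 for leaf measurements
(a coarser grid erodes the blade rim, a finer one keeps too much noise —
0.003 m ≈ 6σ balances rim expansion against centroid erosion at the
default sampling density); 0.004 m with occupancy ≥ 8 for the stem
caliper, which is the most tail-sensitive quantity. The stem slab is
6 mm thick, centered 0.05 m above the pot surface (taken as the minimum z
of the stem class — the soil goes out with the background, so the stem
base is the available proxy); a thinner slab also limits the smear a
leaning stem projects into the horizontal plane.

Leaf area uses projected Delaunay triangulation: blade points are
projected onto the plane of the two leading OBB axes, triangulated there,
and triangles with any 3D edge longer than `max_edge` (default 4× the
median point spacing) are pruned so holes and concave outlines are not
bridged; Heron areas of the surviving triangles are summed. Compared with
greedy surface meshing this is simpler and deterministic and produces the
same triangle-soup contract. It assumes the blade projects injectively
onto its principal plane — true for flat and moderately curled leaves,
wrong for a blade rolled past a half-cylinder.

Length is reported as the maximum pairwise distance (convex-hull
accelerated above 50 points, brute force below): for a curled blade this
is the tip-to-tip chord, not the unrolled arc. Width is the full extent
along the second OBB axis.

## The synthetic generator

Synthetic plants are built from parts with closed-form traits so that
recovery can be scored against analytic truth: a stem tube swept along a
cubic Bézier spine (sampled uniformly by arc length), elliptical blades
(semi-axes a, b) attached along/atop the stem behind a 6 mm petiole gap,
optionally bent isometrically around a cylinder — bending preserves area
(πab) and arc length (2a) exactly while the measurable tip-to-tip length
becomes `2R·sin(a/R)` — plus a pot disc below the stem base labeled noise,
isotropic Gaussian sensor noise (σ = 0.5 mm) added after labeling, and 1 %
uniform box outliers. Default sampling density is 2×10⁶ points/m²
(≈ 50–70 k points per plant). Generation is deterministic given the seed.

The reference fixtures: `straight_3leaf` and `curved_5leaf` (stem radius
6 mm — a mature potted pepper; the curved spine keeps its lower third
vertical, as pot-grown stems do, and bends in the top third to chord/arc
≈ 0.97), `touching_leaves` (two apical blades separated by less than the
clustering radius), `stem_only`, and `split_leaf` (a blade with a missing
4 mm strip, for the fragment-merge path). A randomized population spans
heights 0.18–0.32 m, stem radii 4.5–7.5 mm, 3–6 leaves with golden-angle
phyllotaxis and mixed flat/bent blades.

What the generator does *not* emulate: reconstruction artifacts with
spatially correlated noise, holes from occlusion (beyond the deliberate
split fixture), petiole geometry (the gap is empty space), leaf venation
or serration, and multi-stem or rosette architectures. Passing the
synthetic suite therefore demonstrates the algorithmic chain under
idealized single-stem geometry with honest sensor-scale noise — not
robustness to every failure mode of field reconstructions.

## Evaluation choices

Rates are reported both as percentages and as half-up 3-decimal
proportions (matching how such tables are printed). The cloud-to-cloud
"average distance" is implemented as the root mean square of the per-point
nearest distances, with the arithmetic mean also exposed. Population-level
trait agreement fits the calibration line measured ~ true and reports the
R² of the fit (the squared Pearson correlation), which is how
recovered-vs-manual scatter is conventionally summarized; the plain
`R² = 1 − SSE/SST` of predictions against references is available
separately. ICP is point-to-point with an SVD update and no
correspondence rejection.

## Problem sizes

Tests and the acceptance study run at desk scale deliberately: fixtures of
5–7×10⁴ points, a 20-plant population, oracle checks at n ≤ 300 (DBSCAN),
n ≤ 200 (shortest paths), n ≤ 500 (filters). These sizes keep every oracle
exhaustive (full distance matrices, Bellman–Ford) while exercising the
same code paths as larger clouds; the pipeline itself is near-linear in
point count (KD-trees, sparse Dijkstra) and handles the published
10⁵–10⁶-point clouds.

## Known limitations

- One plant, one stem, lowest-point rooting: multi-stem pots and hanging
  growth violate the path model.
- The apex region within the backtrack range of the top is intrinsically
  ambiguous; with no apical leaf it is labeled leaf (small for small
  `k_retrace`), with an apical leaf it is absorbed or reclaimed by the
  tube-shape rule.
- Leaves fused below the clustering resolution are returned as one
  instance with `low_confidence = True` rather than split.
- Stem thickness assumes the stem is roughly upright at the measurement
  height; a strong lean at 5 cm biases the horizontal caliper upward by
  1/cos(tilt).
- Triangulated area requires an injective principal-plane projection of
  each blade.
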