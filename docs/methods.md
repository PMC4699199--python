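# Methods

## Network model and units

A vein network is a planar graph whose nodes carry coordinates in cm and
whose edges are straight segments carrying a vein width in mm and a
centerline length in mm (defaulting to the Euclidean endpoint distance).
Curved veins must be pre-discretized into polyline chains by the upstream
vectorizer; chains between junctions behave identically to single edges in
the decomposition, because only the widths of shared areole boundaries
matter. Straight parallel edges between the same node pair are
geometrically coincident and are rejected at validation; crossing segments
are an embedding error (checked with an STRtree sweep on file input).

Pruning keeps exactly the edges that lie on at least one cycle. Since an
edge is on a cycle iff it is not a bridge, one bridge-removal pass followed
by dropping isolated nodes reaches the fixed point of iterative spur/bridge
peeling. If several loopy components survive (damage, clearing artifacts),
the component with the most faces is analyzed and a warning logged.

Faces are traced from the geometric rotation system: incident edges are
sorted by angle at every node and each half-edge is followed to the next
half-edge in clockwise rotation, visiting every face exactly once. The
outer face is the walk with negative signed area (tie-broken by largest
absolute area) and is excluded; the count of internal faces is checked
against Euler's formula F = E − V + 1, which guards against silently
accepting a non-planar input.

## Decomposition

All areoles start as tree leaves. The globally thinnest edge that
separates two *distinct* current facets picks the pair to merge (width
ties break on the smaller edge id, so the algorithm is deterministic and
seed-free); the entire shared boundary between the pair is removed, edges
that end up with the same facet on both sides are discarded without
creating tree nodes, and a new internal node adopts the two facet
representatives. When a pair shares several edges, the selection score is
configurable (`pair_weight`: min / mean / max of the shared widths,
default min — the single-thinnest-edge reading); for single-edge
boundaries all three agree.

Because only width ranks and face adjacency enter, the tree is invariant
under strictly monotone width transforms and under junction-preserving
geometric deformation. Both invariances are property-tested, and the
implementation is cross-checked against an independent brute-force
facet-merging oracle on hundreds of random small networks.

## Metrics

- Nesting ratios/numbers use internal nodes with subtree degree
  d ≤ 256 (full organs) or d ≤ 128 (fragments); the filter is applied per
  node, not per whole subtree. The degree-weighted number uses weights
  ∝ d − 1 normalized to 1. An empty filter raises an undefined-metric
  error rather than returning a silent NaN.
- The tapering walk moves to the adjacent edge of maximal width among
  those *strictly* thinner than the current edge (ties by edge id).
  Strictness guarantees termination on quantized widths without a visited
  set.
- Blade area is the area of the outer boundary polygon (not the convex
  hull, so lobed outlines are handled). The mean inter-vein distance `a`
  is estimated by sampling a uniform grid of points inside the blade
  polygon — default spacing min(0.1 mm, blade diameter / 500),
  configurable — and averaging the distance to the nearest vein segment
  (STRtree nearest-neighbor queries). The analytic value for a square
  blade with no interior veins (side/6) is reproduced to 0.1%.

## Fragmentation

Fragments are axis-aligned tiles (default 1.2 cm — the herbarium-fragment
scale) anchored at the bounding-box lower-left corner; an optional seeded
random grid offset exists for robustness experiments. Edges are clipped
geometrically at tile borders (cut points become boundary nodes,
centerline lengths are scaled by the clipped fraction), then each tile is
re-pruned so that loops opened by the cut vanish: fragment areoles are
always whole. Tiles with fewer than `min_areoles` (default 10) facets are
dropped because nesting statistics on a handful of areoles are
meaningless. Float-epsilon slivers produced by clipping along a border
are discarded below a 1e-9 cm length threshold.

## Statistics

Fingerprint tables are standardized before PCA and LDA because the eight
metrics have incommensurate units; PCA is therefore correlation-based.
LDA identification uses stratified k-fold cross-validation (k = 10) with
the scaler fit inside each training fold — a pure-noise-feature test
guards against standardization leakage. Classes with fewer rows than
folds are dropped, not merged. Accuracy is the plain fraction of correct
assignments. Welch's unequal-variance t with Welch–Satterthwaite degrees
of freedom compares the two fold-accuracy samples. The network distance
is the two-sample KS statistic between nesting-ratio samples; it is
symmetric and bounded in [0, 1] but not claimed to be a metric.

## Growth model

The simulator starts from a 0.5 cm square loop. Per step the lamina
expands by `growth_rate` (default 5% — coordinates are simulated in the
initial frame with a running scale factor), and every areole
independently subdivides with probability logistic((A − A₀)/σ_A), where
A₀ = 1 cm² by default and σ_A = β·A₀. A subdivision inserts a straight
new vein perpendicular to the areole's longer axis at relative position
½ + ρ·(u − ½), u ~ U(0, 1), so areoles remain rectangles (the subdivision
geometry of the archetypal model); at most one split per areole per step.
New veins start at width w₀ (0.01 mm) and all widths grow linearly by
α·growth_rate·w₀ per step, so at termination (areole count ≥
`target_areoles`) older veins are strictly wider. Finally widths are
multiplied by (1 + f_n·ξ), ξ ~ N(0, 1), clipped at 0.05·w₀ to stay
positive.

Design choices where the model family was genuinely open, fixed once and
exposed as parameters: the sigmoid is logistic (rather than an error
function), the terminal noise is multiplicative (per maximal vein segment,
so all sub-edges of one vein share the perturbation), and splits keep
areoles rectangular. With f_n = 0 the width ranks encode creation times
exactly, so the nesting tree provably replays the split genealogy in
reverse — the test suite checks clade-set equality between the
decomposition and the recorded event log. Increasing f_n scrambles width
ranks and monotonically degrades the ensemble-mean nesting number; the
suite tests the ordering over f_n ∈ {0, 0.2, 0.45} with 20 seeds per
level at 64 areoles per run.

What the simulator emulates: hierarchical loop genesis with tunable
developmental noise, realistic nesting-ratio and tapering statistics.
What it does not: curved veins, non-rectangular areole shapes, free-ending
veinlets, major-vein patterning, and leaf-shaped outlines. Tests passing
on simulated networks therefore validate the topological machinery and
the statistical pipeline, not the geometric realism of any particular
species.

## Problem sizes

The default test suite uses networks up to ~200 edges, 200 random
instances for the oracle cross-check, and 20-seed ensembles at 64
areoles. `scripts/acceptance.py` uses 16-seed ensembles at 96 areoles,
10 self-consistency seed pairs, and a 10-specimen × 10-replicate
synthetic identification table with the inter-vein grid coarsened to
0.5 mm; these sizes make the whole script run in seconds while keeping
the ensemble standard errors a few percent.

## Known limitations

- The analyses of the published 186-leaf fingerprint databases require
  the database tables as CSV under `data/`; the tables are not
  redistributed with the package, so the corresponding acceptance tests
  only run where the data is available.
- The inter-vein distance estimator is grid-based; extremely thin,
  elongated blades may need a finer explicit `grid_spacing_mm`.
- Face extraction assumes exact planarity; nearly-degenerate embeddings
  (collinear overlapping segments) are rejected rather than repaired.
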