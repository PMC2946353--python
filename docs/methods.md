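# Methods

## Problem and model

Biological ontologies — a pathway ontology (PO) organizing pathways under
functional categories, or the Gene Ontology (GO) — are rooted directed
acyclic graphs: a term may sit under several parents. `ersfviz` draws the
whole ontology at once as an enhanced radial space-filling (ERSF) scene,
maps gene-level experimental summaries onto it, and lays out individual
typed pathway graphs on aligned 3D tiers. The three computations are
independent layers with explicit data contracts between them:

1. **Spanning-tree decomposition** (`ontology`). Every non-root term keeps
   exactly one *major parent* — the parent whose edge appears first in the
   input edge order — and every other in-edge becomes a non-tree edge from a
   *minor parent*. First-listed-wins is the only rule that is both
   deterministic from the input file alone and reproduces the intended
   major/minor assignment of the packaged toy graph G2 (C is the minor
   parent of AA1 and AA2); a smallest-depth rule would invert it. Depths
   are computed over tree edges only, so the identity
   `|non-tree edges| = |E| − |V| + 1` holds for any single-root DAG and is
   property-tested against brute-force parent counting. Multi-root inputs
   (e.g. GO's three namespaces) get a virtual root rather than a rejection.

2. **ERSF geometry** (`ersf`). The sunburst rules: each tree depth is one
   annular ring of fixed width `ring_width` (default 10 layout units, root
   as the central disc); a leaf's sweep angle is `360·w/Σw` over leaf
   weights (default equal — every pathway spans the same angle); an
   internal node's sweep is exactly the sum of its children's, so angular
   conservation and 360° closure are exact invariants (tested to 1e-9°).
   Siblings are placed in lexicographic id order — the layout is a pure
   function of the input. Angular weight is carried by *tree* leaves
   (nodes with no spanning-tree children): in a DAG a term can lose all
   its children to other major parents and still needs a visible region.

   Structure-based color: leaf hue = angular midpoint / 360 on the HSV
   wheel at full saturation/value; internal nodes are the sweep-weighted
   mean of their children's RGB, computed bottom-up. Averaging is done in
   linear RGB; the upstream description does not fix a color space, and
   RGB keeps the recursion trivially checkable against an independent
   recomputation. Extrusion height is `H0·(1 + subtree height)` with
   `H0 = 5` units, so leaves get `H0` instead of the zero that strict
   proportionality to subtree height would give.

   Non-tree edges: one **orbit** circle per multi-parent node, drawn on
   that node's ring inside the fractional band (0.3, 0.7) of the ring
   width (the "middle area", leaving a visible gap between rings).
   Within a ring, orbits sorted by `(downlink count, child id)` receive
   evenly spaced radii across the band and evenly spaced altitudes —
   most-linked outermost and highest. Altitudes start one `H0` above the
   tallest extruded region of that ring and step by `H0`; this is one
   concrete reading of the qualitative "different heights and distances"
   rule and is config-exposed. Each minor parent gets a single radial
   **downlink ray** anchored at its region's angular midpoint and radial
   center, spanning to the linked orbit radially farthest from the
   anchor; **access points** mark every ray/orbit intersection, one per
   non-tree edge.

3. **Statistic mapping** (`stats`). A term's gene set is its direct
   annotations united with its tree descendants' sets (union, not
   multiset, so shared genes count once; the propagation rule is our
   choice, made to avoid double counting). Summaries per term: mean and
   median per condition; CoV = σ/μ with *population* σ (divisor N),
   averaged over the term's genes across conditions — CoV is flagged
   missing when μ ≤ 0 rather than patched with absolute values; a gene is
   differentially expressed when |treatment − control| is *strictly*
   greater than the threshold (default 0.7, intended for log-scale
   values), down-regulated when the treatment value is lower;
   overrepresentation is the one-sided upper-tail hypergeometric
   probability P(X ≥ k) (Fisher's exact test), computed with
   `scipy.stats.hypergeom` and cross-checked against exhaustive
   enumeration of all tables with universe ≤ 20 at 1e-12. Raw p-values
   are reported; no multiple-testing correction is applied by default.

   Visual encodings: a linear green→yellow→red ramp for a chosen
   statistic (range defaults to data min/max, fixable for cross-frame
   comparability); the *differential view* sets height = `H0·log2(n_de+1)`
   and color from `s = log2((n_up+1)/(n_down+1))` clipped to [−3, 3]
   (green → white → red), and makes regions with fewer than `min_de = 5`
   DE genes fully transparent. A multi-condition matrix yields one frame
   per condition in column order (reorderable), and the KML writer turns
   frames into time-stamped folders.

4. **Tiered layout** (`tiered`). Entity types map to z-planes in the
   order metabolite, polypeptide, RNA, DNA, other, spaced `dz = 20`
   units; an alias table folds input types (protein, complex, reaction)
   onto planes, with reactions riding the metabolite plane so
   metabolite–reaction–metabolite chains stay flat. The user-selected
   major plane is laid out with networkx's spring embedding (fixed 500
   iterations, seeded, default seed 42); edges through a single
   non-major intermediary are collapsed so the embedding sees the real
   connectivity. Remaining planes cascade: each node takes the centroid
   of its already-placed neighbours, unplaceable nodes wait a pass, and
   leftovers park on a margin grid. Nodes closer than `r_min = 0.5`
   units within a plane are fanned on a radius-`r_min` circle in id
   order. Major-plane coordinates are never touched after embedding —
   the testable core of the "aligned" claim, along with the projection
   property that a single-neighbour node sits exactly under its
   neighbour.

5. **Rendering** (`render`). SVG 1.1 (top-down 2D projection: annular
   sector paths, dashed orbit circles, ray segments, access-point discs)
   and KML 2.2 (extruded polygons at altitude, orbit rings, 3D line
   strings; arcs tessellated at 4° steps). Layout units map to lon/lat
   by a local equirectangular projection about an anchor (default lat/lon
   0/0, 10 m per unit); anchors within 5° of a pole are rejected. Output
   element order is sorted by node id, so files are byte-stable. Offline
   validation checks well-formed XML, the KML 2.2 namespace, and element
   censuses rather than validating against the official XSD.

## Synthetic data

`synth_expression` emulates a gene-per-row, condition-per-column
expression table: genes are assigned round-robin to the eight leaves of
the toy graph G2, values are i.i.d. Normal(μ0 = 8, σ0 = 0.5) — a log2
microarray-like scale — and designated leaves receive additive shifts in
designated conditions. Under this null, the between-condition difference
is Normal(0, σ0√2), so the expected null DE fraction at the 0.7 cutoff is
2·Φ̄(0.7/(σ0√2)) ≈ 0.32, which the tests verify against the closed form.
What the generator does *not* emulate: gene–gene correlation, replicate
structure, intensity-dependent variance, or missingness patterns of real
microarrays — passing recovery tests show the mappings are wired
correctly, not that the pipeline's statistics are calibrated for real
data.

The toy graphs: G1 is the fixed 13-node tree (8 leaf pathways, 5
categories); G2 adds four non-tree edges. Two of them (C→AA1, C→AA2) are
fixed by the reference figure; the remaining two (B→C1, A→B1) are a
synthetic completion chosen so multi-parent nodes land on two distinct
rings and orbit placement across layers is exercised. G1's edges are
listed before the extras so first-listed major-parent selection keeps the
original tree parents major.

Problem sizes in tests and the acceptance script are kept small on
purpose — 200 random graphs of ≤ 50 nodes for layout properties, 800
genes for effect recovery, 48 genes (6 per leaf) for the
transparency check so the expected null DE count per leaf (≈ 1.9) sits
clearly below the `min_de = 5` cutoff while the shifted leaf's (≈ 5.8)
sits above. With a +2 shift the per-gene up probability is
Φ̄((0.7−2)/(σ0√2)) ≈ 0.967, so the observed up-fraction on a 100-gene
leaf fluctuates a few percent around 96.7 across seeds.

## Numerical and design choices

- Ties everywhere break on lexicographic id order; identical inputs give
  byte-identical JSON/SVG/KML.
- Angle conservation is exact by construction (sums, not rescaling);
  tests allow 1e-9° for float accumulation.
- The DE rule uses absolute difference on values as supplied (log-scale
  input gives fold-change semantics); strict inequality, so a change
  exactly at the threshold is *unchanged*.
- The root is drawn as a full disc by default; `--hide-root` drops it for
  ontologies whose root is purely organizational.
- Orbit altitude is placed above the tallest region of its own ring;
  when data-driven heights are large the orbits rise with them, one
  reading of an underdetermined rule.
- Missing expression values are excluded pairwise; DE classification of
  a missing pair is "unchanged" and logged.

## Known limitations

- No label de-overlap or level-of-detail culling — delegated to the
  viewer consuming the KML.
- OBO support is the id/name/is_a subset; other relationship types are
  counted and ignored, not reasoned over.
- The spring embedding is deterministic but not canonical: different
  seeds give different (all valid) major-plane geometries.
- Overrepresentation p-values are raw; interpretively, with hundreds of
  terms a multiple-testing correction is the user's responsibility.
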