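# Methods

## The integration problem

A CellDesigner map stores each molecule as an *entity* with one or more
*aliases* — visual copies, each with an `x/y/w/h` bounding box on a fixed
canvas (origin top-left, y downward). Metabolic maps annotate each
reaction with the HUGO symbols of its regulating proteins but draw no
protein nodes; signalling maps draw proteins explicitly. To present both
as interconnected layers, catalyst nodes must be created on the metabolic
canvas near their reactions, the layers merged, and the module/subsystem
gene-set hierarchies compared through their shared proteins.

## Catalyst extraction

Gene rules are boolean expressions over Entrez ids with optional
transcript suffixes (`8639.1 and 26.1`). Placement needs only membership,
so the expression is flattened to its ordered, deduplicated gene list and
the `and`/`or` distinction (enzyme complexes vs isozymes) is deliberately
dropped; a warning is logged once per process. This is a simplification:
co-factors and regulatory subunits are treated the same as the catalytic
subunit, and post-translational activation states are ignored. Entrez ids
are converted with a user-supplied single-valued table; conflicting or
missing mappings are surfaced as diagnostics rather than dropped silently.
Model input is a two-column TSV export rather than a MATLAB model file —
only the reaction→gene link is used.

## Reaction central glyphs

CellDesigner draws a small square at each reaction's midpoint but does not
store its coordinate. We define it as the midpoint of the segment joining
the centres of the first base reactant's and first base product's alias
boxes, which coincides with CellDesigner's default glyph placement for
two-anchor reactions and is deterministic. For reactions with additional
anchors this is a declared stand-in; no better definition is available
from the file format.

## Placement

*Seeds.* One seed per alias (box centre) and one per reaction glyph.
Exactly coincident locations are separated by a deterministic golden-angle
spiral jitter of 1e-3 canvas units (the tessellation needs distinct
sites; 1e-3 px is far below visual resolution).

*Clipped Voronoi.* Seeds are reflected across the four canvas edges; in
the Voronoi diagram of the 5N mirrored sites every original site's region
is bounded, and intersecting it with the canvas rectangle gives the
exactly clipped cell. The construction makes the cells convex (an
intersection of half-planes with a rectangle) and makes them tile the
canvas: the residual relative area error is pure floating-point noise
(observed ~1e-16, asserted < 1e-6). A single seed owns the whole canvas.

*Sampling.* 100 points per reaction cell by default — ample relative to
typical catalyst counts, following the original choice. Points are drawn
by exact fan triangulation (triangle chosen ∝ area, then uniform within),
valid because the cells are convex; boundary hits (measure zero) are
rejected so all points are strictly interior. If a reaction has more
catalysts than points, the sample size is doubled (up to `max_resample`
times) — real maps contain reactions with dozens of regulators.

*Clustering.* scikit-learn K-means, k-means++ initialisation, 10
restarts, best within-cluster sum of squares kept. K = 1 short-circuits to
the exact arithmetic mean. Centroids are sorted lexicographically by
(x, y) before symbols are assigned, making the symbol→coordinate pairing
deterministic. Cluster centroids are convex combinations of in-cell
points, hence inside the cell: every placed node's nearest map element is
its own reaction glyph. Node boxes default to 80×40 canvas units
(configurable; the box may overlap a neighbouring box — only
centre-containment is guaranteed, and no force-directed refinement is
attempted).

*Naming.* The k-th occurrence of a symbol across the placed layer (k ≥ 2)
carries k−1 apostrophes. Occurrences are counted in sorted reaction-id
order, then association order within a reaction, so names are stable.

*Determinism.* One `numpy` generator seeded from `rng_seed` is consumed
in sorted reaction-id order (K-means consumes a child seed drawn from it
per reaction); identical inputs give bit-identical results.

## Overlay construction and merging

The placed layer becomes a proteins-only map: one entity per distinct
symbol, one alias per placement (a protein catalysing many reactions has
many aliases). A node whose box would cross the canvas edge is shrunk
about its centre — the centroid itself is always on-canvas. Merging keeps
the base map's ids and rewrites overlay ids to fresh `s<N>`/`sa<N>`/`re<N>`
values continuing past the base maximum; names, geometry and annotations
transfer bit-exactly and same-name entities are *not* unified — the
multi-layer resource links layers by protein name, not merged identity.
Canvas dimensions must match exactly.

## Crosstalk analysis

The universe is the union of both layers' proteins; every set is
intersected with the universe before sizing. A set with K universe
proteins, queried with the n shared proteins, scores
p = P[X ≥ k] for X ~ Hypergeom(N, K, n) at the observed overlap k
(`scipy.stats.hypergeom.sf(k−1, …)`), so zero overlap gives exactly 1.
Only sets with K ≥ `min_size` (default 10) are tested, and Bonferroni
multiplies by the number of sets actually tested *within each collection*
(the two layers are corrected separately; whether the original analysis
pooled them is not documented, and per-collection matches the stated
"modules containing at least 10 proteins" rule). The crosstalk network is
bipartite with edge weight |module ∩ subsystem ∩ shared|; the
reaction-regulation table counts each reaction once per (module,
subsystem) pair regardless of how many of its catalysts belong to the
module, and requires a single subsystem per reaction (multi-assignments
are rejected at load because they would double-count).

## Synthetic bundles

The generator emulates the structural features the workflow depends on:
grid-jittered metabolite layout (no coincident seeds by construction, but
one entity deliberately gets two aliases), reactions between random
metabolite pairs, catalysts drawn from a small symbol pool and written
both into reaction `Identifiers` annotations and into random boolean gene
rules over a reserved synthetic Entrez range (9,000,000+, disjoint from
real ids), subsystem assignment round-robin, and a module layer holding a
chosen fraction of the used catalysts plus private signalling-only genes.
Ground truth (catalysts, glyph coordinates, shared set, expected edge
weights) is emitted alongside. Two presets: `small` (6 metabolites, 2
reactions, 1–2 catalysts) for I/O and unit fixtures, `dense` (30
metabolites, 20 reactions, 1–5 catalysts, 5 subsystems, 4 modules) for
end-to-end property checks. What the bundles do **not** emulate: real
maps' hyper-edge reactions with many anchors, protein complexes and
post-translational states (out of scope for placement of simple
proteins), compartment geometry, and the heavy-tailed catalyst counts of
genome-scale models; passing tests therefore demonstrate the algorithmic
contracts, not biological fidelity of layout aesthetics on real maps.

Synthetic gene-set layers are far smaller than real module/subsystem
collections, so examples and the acceptance script run enrichment with
`min_size=1` (the default 10 reflects real collections and would filter
every synthetic set).

## Numerical choices and degenerate inputs

- Voronoi tiling tolerance 1e-6 relative (observed error ~1e-16).
- Hypergeometric p-values agree with exact combinatorial enumeration to
  1e-12 on universes up to 25.
- Zero-area (collinear) cells are rejected with the owner id; empty seed
  sets are an error; a single seed degenerates to the full canvas.
- Duplicate genes in a rule or GMT line collapse to the first occurrence.
- Serialization refuses documents violating referential integrity or
  canvas containment, naming the offending ids.

## Known limitations

- The midpoint glyph rule is a stand-in for reactions with more than two
  anchors.
- Protein node boxes can overlap each other for dense reactions; only
  centre-separation from pre-existing elements is guaranteed.
- GPR flattening over-approximates catalysis (complexes, cofactors).
- Only simple proteins are created; complexes and state variables in
  input maps are passed through opaquely, never manipulated.
- Community detection over the crosstalk network is out of scope.
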