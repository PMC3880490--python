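# Methods

## The descriptor

A molecule's shape is summarized by the statistics of an interior billiard.
The molecular surface — the surface swept by the inward face of a solvent
probe rolling over the van der Waals spheres — is triangulated, and a ray is
launched from the center of a randomly chosen contact element, antiparallel
to its outward normal. The ray propagates by specular reflection (plus a
small random cone perturbation) and the straight paths between consecutive
reflections are recorded as *segments*. Two families of probability
histograms are accumulated:

- **1D**: the distribution of segment lengths, binned at `bin_width`
  (default 0.5 Å).
- **2D**: at each interior reflection, the joint distribution of the summed
  incoming + outgoing segment lengths and the molecular electrostatic
  potential (MEP) at the reflection point. The MEP axis is either fully
  binned (`mep_bin_width`, default 0.025 e/Å, clamped symmetrically at ±1
  e/Å with overflow bins) or *reduced* to its sign (two bins; an exactly
  zero potential counts as positive by convention), with a *reduced
  inverted* variant that flips the sign first for electrostatic
  complementarity matching.

Histograms are normalized for comparison; raw counts are retained because
they weight the fragment-mapped score and make the global-histogram
reconstruction exact.

### Fragment partitioning

The heavy-atom graph is partitioned around its ring systems. Ring closures
(one per independent cycle) are the non-tree edges of a maximal spanning
subtree grown depth-first from the lowest-index bond; the union of
non-self-intersecting paths joining the two ends of a closure — equivalently
the biconnected component holding that edge — is a ring system, and systems
sharing an atom (fused or spiro) merge. Remaining acyclic components become
separate fragments when they border two or more ring systems, or border one
and carry **more than five** heavy atoms (exactly five is subsumed);
otherwise they are absorbed into the neighbouring ring system. Hydrogens
follow the heavy atom they are bonded to. A ring-free molecule is a single
fragment, which reduces the whole method to its global, non-fragment form.
Fragment ids ascend with each fragment's lowest member atom index, so the
labelling is reproducible under any traversal.

Every ray-trace segment is tagged by the fragments of the primary atoms of
its two bounding elements, and each histogram is kept separately per
fragment (intra) and per unordered fragment pair (inter). Summing raw counts
over all of them recovers the global histogram exactly. Inter-fragment
histograms are stored but not scored. A 2D reflection belongs to the
fragment of its element's primary atom; when an incident segment crosses
fragments the count goes to that pair's inter histogram (the incoming
segment takes precedence if both cross). This attribution is a package
convention — fragment partitioning is unambiguous only for 1D segments —
and it preserves the partition property: 2D raw counts partition the
interior reflections.

## Surface construction

The surface generator is a signed-distance-grid backend behind the
`TriSurface` contract (watertight, consistently outward-oriented, classified
elements); the ray-trace statistics depend on the geometry of the surface,
not on how it was tessellated.

1. The signed distance to the probe-center surface (atom spheres inflated by
   the probe radius) is evaluated on a uniform grid. Outside the union of
   inflated spheres the field `A(x) = min_i(|x − aᵢ| − (rᵢ + r_p))` is exact.
2. Inside, the depth below the surface is estimated as
   `min_w (|x − w| − A(w))` over the EDT-nearest exterior voxel `w` and its
   26 neighbours. For any exterior point the quantity `|x − w| − A(w)` is
   provably **at least** the true depth (the segment x→w crosses the
   surface, and `A(w)` is at most w's distance back to it), with
   near-equality when w lies along the local normal, so the estimate
   converges to the depth from above and never erodes the surface.
3. The molecular surface is the `−r_p` level set, extracted by marching
   cubes. Orientation is fixed globally by requiring positive enclosed
   volume; interior cavity components (negative volume under the global
   orientation) are discarded, while disjoint exterior shells are kept.

Element classification displaces each element center outward by the probe
radius and counts the atoms whose inflated sphere passes within
`CLASSIFY_TOL = 0.15 Å` of that probe position: one atom → contact, two →
saddle, three (or more; the three nearest are kept) → reentrant. An element
touching no atom within tolerance falls back to its nearest atom with a
logged warning (a rare, numerically marginal case). The *primary atom* of an
element is the assigned atom nearest the element center; exact ties go to
the lowest atom index.

Vertex MEP values are plain Coulomb sums `Σ qᵢ / (ε·|v − rᵢ|)` in units of
elementary charge per Ångström (dielectric ε defaults to 1; only relative
values and signs matter downstream). Reflection MEPs are barycentric
interpolations of the element's three vertex values.

**Parameters.** `probe_radius` 1.4 Å (water); `mesh_density` 0.4 Å — the
grid step, which the median triangle edge tracks (the single-atom surface
area is then within 2 % of 4πr², improving to <1 % at 0.22 Å); radii from
the packaged Bondi table; charges from the input file when present, else a
Gasteiger calculation (`zero` is available for pure-shape work).

## Ray-trace numerics

- Intersections use Möller–Trumbore with a 1e−9 barycentric slack; hits
  closer than 1e−6 Å are rejected and the launching element is excluded for
  one step (self-hit guards). Exact distance ties go to the lower element
  index.
- The public acceleration grid registers each element in the cubes holding
  its corners (1–3 cubes) and queries the 27-cube neighbourhood of every
  cube the ray walks through; the `trace` kernel uses an internal
  bounding-box-complete registration so a single-cube scan suffices. Both
  are exactly equivalent to a brute-force scan over all elements — verified
  bit-for-bit in the tests — and results are independent of the spacing
  (default 0.5 Å, a speed knob only).
- The cone perturbation samples uniformly over the spherical cap of
  half-angle `cone_angle` (default 3°) around the ideal mirror direction;
  candidates pointing back out of the surface are redrawn (at most 20
  times), with the ideal direction as fallback. Grazing incidence
  (|d·n| < 1e−12) or a missing intersection truncates the run, which
  restarts from a fresh random contact element; more than 50 consecutive
  fruitless restarts abort with a mesh-quality error.
- All randomness flows through one seeded generator inside the trace kernel;
  a trace is bit-reproducible for a given seed, and the seed is recorded in
  the result. Library builds derive a per-molecule seed from the base seed
  and a CRC of the molecule id, so signatures are independent across
  molecules yet reproducible.
- `n_segments` defaults to 100,000: at 0.5 Å bins this keeps the
  seed-to-seed L1 distance of per-fragment histograms below 0.05 on the toy
  molecules, so self-comparisons score well under any sensible hit
  threshold.

### Mixing on near-integrable geometry

For an ergodic interior billiard the mean chord equals 4·Volume/Area
(Cauchy), which the cube fixture reproduces to ~0.1 %. A perfect sphere,
however, is integrable — specular reflection conserves the incidence angle —
so at 10⁵ segments the only angular mixing comes from the cone perturbation,
which is too slow to equilibrate and carries a small drift toward the
uniform direction measure (grazing-ward, i.e. short-chord biased): on a
finely tessellated sphere (5,120 elements) the mean chord lands 6–11 % low.
A moderately faceted sphere (icosphere subdivision 2, 320 elements) restores
mixing through the varying facet normals while 4V/S of the faceted body
remains the exact oracle; the geometric tests use that configuration. Real
molecular surfaces are irregular and mix rapidly, so this is a property of
the degenerate test geometry, not of descriptor generation.

## Scoring

The distance between two normalized histograms is the discretized L1 metric
`S(q,t) = Σ_μ |h_μ^q − h_μ^t|` ∈ [0, 2] (0 identical, 2 disjoint support);
the shorter histogram is zero-padded, and differing bin widths or MEP axes
are refused as incomparable.

Fragment mappings are injective link sets between the fragment graphs of
query and target, *consistent* in that bonded mapped query fragments must
map to bonded target fragments (the converse is not required: non-adjacent
query fragments may map to adjacent target fragments). Enumeration expands
every single link recursively in all consistent ways and keeps a mapping iff
no single-link extension is possible — equivalently, the consistent mappings
maximal under inclusion; duplicates are removed. For linear (path) fragment
topologies the number of contiguous-interval mappings has the closed form
`mn + 2·Σ_{k=2..min(m,n)} (m−k+1)(n−k+1)` (85 at m = n = 5), which is
exposed for estimating comparison cost.

A mapping's score is the count-weighted mean of per-link L1 distances,
weight = the sum of the two linked fragments' intra-segment counts. A link
whose two fragments both collected no segments contributes nothing; if
exactly one side is empty the link scores the maximal distance 2. *Unused*
percentages report the share of each molecule's total segments lying in
fragments the mapping does not cover; screening drops hits whose best
mapping leaves more than 25 % of either molecule unused. Ranking uses the
raw score; `T(s) = 1 − log₂(s)` is reported as a readable similarity (0 at
the maximal distance, unbounded as s → 0; a raw score of exactly 0 — which
stochastic descriptors essentially never produce between independent traces
— reports T as undefined). Scoring uses the 1D descriptor by default;
`full`, `reduced` and `reduced_inverted` 2D variants are selectable.
Equal-score mappings order by more links first, then lexicographic links.

## Prefiltering

The reduced record of a library molecule keeps only per-fragment shape
histograms and segment counts, connectivity dropped. For each query fragment
the best (lowest) distance to any target fragment is found, target reuse
unlimited. The default bound is the **minimum** of these optima: every
mapped score is a weighted mean of link distances, each at least its query
fragment's optimum, so the bound never exceeds the best full mapped score
and a large-enough shortlist never loses the true best hit. The
count-weighted mean of the per-fragment optima (the same weighting as full
scoring) is available as `method="weighted"`; it discriminates more sharply
but is *not* admissible — a strong substructure match leaves query fragments
uncovered, and on random synthetic pairs the weighted value exceeded the
best full score in about half the cases — so it is offered as a heuristic
only. Defaults mirror screening practice: shortlist 20,000 (clamped to the
library), 5,000 hits maximum, 25 % unused-fraction threshold.

## Storage

A signature database is a single keyed container file (zip layout): a JSON
header with the generation parameters and id index, one serialized signature
per unique id (duplicates skipped and counted), and the reduced prefilter
records as a binary array bundle built in the same pass and loaded into
memory once per process. Signatures themselves serialize as a versioned,
SHA-256-checksummed, zlib-compressed JSON payload (magic `FSIG`); truncation
or version mismatch raise explicit errors, and an XML export exists for
interoperability. Databases with different binning parameters refuse to mix,
and comparisons across incompatible parameters are refused at call time.

## Synthetic data

The toy molecules are built from idealized bond lengths and angles (planar
rings, zig-zag chains, out-of-plane hydrogens) with small preset charges
(+0.06 e per hydrogen, compensated on the bonded heavy atom): real enough in
size, topology and surface shape to exercise fragmentation, surfacing,
tracing and scoring, but they are not conformers of real drug-like
molecules — no heteroatom chemistry, no realistic charge distributions, no
conformational flexibility. Passing tests therefore demonstrate the
correctness of the machinery (geometry, counting, bounds, determinism,
self-retrieval) rather than screening enrichment on real libraries. The
30-molecule library (the nine named toys plus alkanes, cycloalkanes,
alkylbenzenes, xylenes and fused-ring systems) is sized so that every
molecule's nearest neighbour is distinct at the descriptor's stochastic
noise level. Synthetic signatures (random Dirichlet-multinomial histograms
with declared path/star topology and random counts of 2,000–20,000 segments
per fragment) feed the mapping and prefilter tests without any geometry.

Problem sizes used by the test suite: 10⁵ segments for the geometric
oracles and the 30-molecule self-retrieval; 3–5·10⁴ segments for histogram
conservation and stability checks; 200 random pairs for prefilter
admissibility; exhaustive enumeration up to 6 fragments.

## Known limitations

- Exterior (receptor-site) ray-tracing is not implemented; the launch
  interface reserves the mode.
- Surfaces come from a finite grid: features below the mesh density
  (~0.4 Å) are smoothed over, and pathological self-intersecting geometry
  is not repaired.
- The MEP is a vacuum Coulomb sum of fixed partial charges; no screening or
  polarization.
- Conformer generation, protonation states and tautomers are out of scope;
  the descriptors characterize the 3D structure as given.
- Scoring ignores inter-fragment histograms (retained in the container for
  future scoring schemes).
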