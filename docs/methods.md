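# Methods

## The two-file model

The toolkit separates geometry from annotation. A *dataset* is an
ordered sequence of N points in R³ with a name and a boolean `chain`
flag; an *information file* holds one or more *layers*, each a vector of
N class identifiers with a declared class count (`numClass`) and
optional class labels. Points carry no identifiers: a layer refers to
points purely by position, so order preservation is a correctness
requirement throughout (parsers, writers and converters never reorder,
and the test fixtures use injective coordinates precisely so that any
reordering would be observable).

Coordinates are dimensionless reals: the model deliberately knows
nothing about physical units, since inputs range from micrometre-scale
cell positions to unitless PCA scores. Duplicate points are legal
(colocated biological replicates); non-finite coordinates are not.

## Dialects and canonicalisation

Each family has JSON, XML and CSV dialects. JSON and XML are lossless
and carry the full model; CSV is a deliberately minimal interchange form
(three coordinate columns for datasets, one integer column per layer for
information files) that cannot express names, labels, the chain flag, or
a `numClass` larger than the number of distinct values. Lossiness is
total and explicit: writing to CSV emits one `LOSSY_CSV` warning per
dropped field and alters nothing else.

Class identifiers are canonically 0-based integers. Files whose values
occupy exactly 1..numClass with no 0 are accepted as 1-based and shifted
down (warning `ONE_BASED_NORMALISED`): both conventions are plausible in
the wild and silent misclassification would be worse than either.
Values otherwise outside [0, numClass) are an error by default; an
opt-in `repair` mode instead raises `numClass` to cover them
(strictness first, usability second). CSV information columns declare no
`numClass`, so their arbitrary integer ids are rank-mapped onto
0..k−1 with an explicit warning when the mapping is not the identity.
Class values are integers only; string-valued classes are not accepted
(use `labels_to_layer` to convert categorical vectors).

Writers emit a canonical form — fixed key order, two-space indentation,
shortest round-trip decimal representation of floats — so that writing
is byte-stable and format conversion is testable as an exact
round-trip. Formal schemas for the canonical output (JSON Schema, XML
DTD, CSV grammar) ship under `src/pointworlds/schemas/`; the DTDs are
enforceable with standard XML tooling and are exercised by the test
suite.

Format detection is by root token (`dataset` / `information`) for JSON
and XML. CSV has no root, so detection is structural: three numeric
columns with a non-integer field is a dataset; all-integer columns are
an information file; a three-column all-integer file is genuinely
ambiguous and is rejected (`AMBIGUOUS_CSV_FAMILY`) rather than guessed —
the caller must state the family.

All diagnostics are `ValidationIssue` records (severity, a code from a
closed documented catalogue, message, locus), so scripted consumers can
match on codes rather than prose.

## Scenes, worlds and display

A scene holds at most four worlds — parallel sub-views for comparing
datasets or layers side by side. Binding a layer to a dataset requires
the pair to cross-validate (equal lengths); it yields one display state
(visible flag + RGB colour) per class, coloured from a deterministic
palette of evenly spaced HSV hues at saturation 0.65 and value 0.9.
Evenly spaced hues maximise the minimum pairwise hue separation, which
is the property that matters for telling k categories apart; the palette
is pairwise distinct far beyond the k ≤ 64 range checked in the tests.
Customised states are cached per (dataset, layer) key and survive
detaching and re-attaching a layer.

Settings are global across worlds: per-axis scale factors, opacities and
sizes for raw versus layer-coloured points, and optional centering.
Centering subtracts the per-axis bounding-box midpoint (not the
centroid): the goal is symmetric display extents around the origin, and
the midpoint achieves that regardless of how mass is distributed within
the box. Whether a centroid convention would better match users'
expectations was considered and documented as an open choice; the
midpoint is what the transform tests pin down. Applied transform order
is centre-then-scale; centering is idempotent.

Default settings are raw_opacity 0.15, layer_opacity 0.9, both sizes
1.0. No authoritative values exist for these; they were chosen once so
that the coloured classes dominate visually while the raw shadow stays
legible, and they are ordinary configurable fields.

## Rendering

Worlds compile to renderer-agnostic primitives: particle batches and
polylines with one colour, opacity and size each, tagged with their
provenance. Per bound dataset the compilation emits (a) a shadow batch
of all raw points at raw opacity — so hidden classes and unannotated
points remain faintly visible, which is the only sensible depiction of
"the rest of the data" in a class-overlay view; (b) one batch per
visible, non-empty class; (c) for chain datasets, one polyline through
all N points in file order, i.e. N−1 segments (none for N = 1). Chain
polylines use a fixed dark-grey at opacity 0.8 — package defaults, as
module constants. Two conservation laws follow and are tested: visible
class points plus hidden class points equal N, and segments equal N−1.

The interactive back-end writes one self-contained HTML file: inline
styles, an inline hand-written canvas renderer (orthographic projection,
drag-to-rotate, scroll-to-zoom), and the geometry embedded in a
versioned, machine-extractable data island (`#pointworlds-geometry 1`;
one metadata line per primitive with percent-encoded names, then one
`x,y,z` line per point). The island is the contract: tests and the
acceptance script parse it back with `extract_primitives` and compare
against the compiled primitive set exactly, so document content is
verified without a browser. The rendering technique itself
(quadrilaterals, WebGL, canvas) is an implementation detail outside the
contract. Worlds lay out full-window for one world, split for two, and
a 2×2 grid for three or four.

The static back-end draws the same primitives with matplotlib's 3D axes
(Agg) at a caller-given pixel size and azimuth/elevation, with fixed
PNG metadata so output is byte-deterministic.

## Importers

`table_to_dataset` maps delimited text tables (e.g. R PCA scores) to
datasets; column selectors may be header names or 0-based indices, and a
header row is auto-recognised (selected-column cells in the first row
non-numeric) so both selector styles give identical output.
`labels_to_layer` converts a categorical vector to a layer with classes
in first-appearance order — class 0 is the first cluster seen, which
keeps class indices stable under streaming input — and keeps the
original category names as labels. `pdb_to_chain_dataset` extracts a
C-alpha trace (first model, chosen or first chain, first alternate
location) via Biopython and returns a chained dataset; coordinates are
rounded to the 3 decimal places the ATOM record format actually stores.
Full-atom import, mmCIF and multi-model ensembles are out of scope.

## Synthetic data

`simulate_clusters` emulates a clustered spatial cell map (the kind
produced by binning a gene-expression atlas into pseudo-cells and
clustering by expression profile): k isotropic Gaussian clusters,
N(center_c, σ²I₃), with the generating cluster index as the true-label
layer. Defaults are k = 3, 50 points per cluster, σ = 0.05 with centres
drawn uniformly in the unit cube — at that spread clusters are visually
distinct but adjacent ones can touch, which is the regime a practitioner
actually inspects. The generator is bit-reproducible given its seed.

What the simulation does *not* emulate: anisotropic or curved cluster
shapes, density gradients, outliers/noise points, and spatially
autocorrelated class mixing, all present in real tissue maps. Passing
tests therefore demonstrate that geometry and annotations are carried,
validated, composed and rendered faithfully — not that any clustering of
real data is correct, which is outside this package's job.

`emit_fixture_suite` additionally writes a corrupted-file corpus, one
planted defect per file, with a manifest mapping file → expected issue
code; parser completeness is tested as exact recovery of every planted
code.

## Problem sizes and numerical choices

The test suite and the acceptance script use 100 random files per
family for round-trip checks, 25–50 random scenes for conservation
checks, 50 seeds × 200 points per cluster for the simulator calibration
(sample means within 4σ/√n of the generating centres), and one
100,000-point scene for the large-document render. These sizes make the
properties sharp while keeping a full run in seconds on one CPU.
Floating-point round-trips are exact (shortest-repr serialisation), so
equality assertions are exact; transform checks use absolute tolerances
of 1e-9–1e-12 to absorb arithmetic reordering only.

## Known limitations

- No streaming parser: documents are read fully into memory.
- The interactive viewer is a minimal canvas renderer (no depth sorting
  within a primitive, no picking, no camera paths, no level of detail);
  the document's data island, not the pixels, is the tested contract.
- CSV information files cannot represent declared-but-empty classes;
  converting such a layer to CSV warns and the re-read file infers the
  smaller class count.
- Class values are integers; categorical strings must be converted at
  import time.
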