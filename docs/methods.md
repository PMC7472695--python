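# Methods

## Scope and model of the data

The package processes serial 2D images of histological rodent brain
sections at three stages of a quantification workflow:

1. **Pre-processing** — very large scanner images (tens of thousands of
   pixels on a side) are converted to tiled TIFF, re-oriented
   (rotation/mirroring), cropped, downscaled, renamed into serial-section
   order, and thumbnailed.
2. **Registration inputs** — each section is assumed to have been registered
   to a 3D reference atlas elsewhere, yielding (a) an *atlas map*: a 2D grid
   of integer region IDs with the section's field of view, and (b) a linear
   *anchoring* placing the section plane in 3D atlas space.
3. **Post-processing (quantifier)** — segmentation images (one exact RGB
   color per analysis class) are combined with the atlas maps to quantify
   labeling per brain region and to export 3D point clouds.

## Tiled images and the bounded-memory contract

A raster is stored as a grid of `ceil(w/t) x ceil(h/t)` independently
decodable `t x t` tiles (TIFF 6.0 tiled extension; BigTIFF automatically
above 4 GiB).  All raster operations read through an LRU tile cache with a
fixed capacity, so the decoded working set is bounded regardless of image
size; the cache is instrumented (decode/hit/max-resident counters) and the
tests assert both the bound and that results are independent of capacity.
Tile size defaults to 256 (a common scanner convention) and must be a
multiple of 16 as TIFF requires.  Pixels are 8-bit RGB throughout; grayscale
inputs are promoted on read.  `none` and `lzw` compression are lossless and
carry an exact round-trip guarantee; `jpeg` is supported for writing but
excluded from any exactness claim.

## Geometry of the 2D transform

All resampling is **nearest-neighbor inverse mapping** (pointwise sampling,
no antialiasing, matching the behaviour expected by downstream segmentation
tools).  Conventions, fixed once and relied on by tests:

* Composition order: flip, then rotate, then scale.
* Rotation is counter-clockwise positive about the pixel-index center
  `((w-1)/2, (h-1)/2)`; the output canvas is the ceiling of the axis-aligned
  extent of the four rotated corners, which makes quarter-turns exact
  permutations of the pixel grid.
* Scaling samples source index `floor((i + 0.5)/scale)` (clamped); the scale
  parameter is a linear fraction in (0, 1], with a helper converting an
  area percentage by square root.  No enlargement.
* Nearest-neighbor ties at exact half-pixel preimages round *down*
  (`ceil(v - 0.5)`).
* Auto-crop takes the tightest box of non-background pixels, computed
  per-tile during the main pass; an all-background image keeps its full
  frame (an empty raster would break every downstream consumer).
* The tile-wise path and a flat whole-raster reference implementation are
  pixel-identical by construction and by test.

A consequence of pointwise sampling worth stating: rotating by θ and then by
−θ is pixel-exact only when θ is a multiple of 90°.  For general angles the
two rounding steps can displace a sample by at most one source pixel in each
axis (½ from the first rounding, rotated and re-rounded); the tests assert
exactly this bound — quarter-turns restore the raster exactly, arbitrary
angles restore >95 % of footprint pixels exactly and never fetch from more
than one pixel away.  No interpolation scheme without antialiasing can do
better, and antialiasing is deliberately absent.

The bilinear option of the bulk resizer uses pixel-center alignment
(source coordinate `(x+0.5)/scale − 0.5`, delegated to Pillow); its
unfiltered option is the same pointwise sampling as the transform, so the
two tools agree exactly.

## Object extraction and anchoring

Objects are connected components of pixels **exactly equal** to the
configured RGB class color (segmentation tools emit exact class colors, so
no tolerance is used).  Labeling is breadth-first search; the frontier is
expanded one layer at a time with vectorised neighbor arithmetic, which
preserves BFS order while scaling to full sections.  Connectivity defaults
to 8 (standard for blob detection), 4 selectable.  Per object we record
area (pixel count), centroid (mean x, mean y), bounding box, and a shape
statistic defined here as the bounding-box aspect ratio (elongation ≥ 1) —
an interpretation, as "shape" has no canonical definition in this context.
Object IDs follow the raster order of each component's first pixel, making
extraction deterministic.

Atlas maps at a different resolution are nearest-neighbor rescaled to the
segmentation grid (preserving integer IDs) before per-pixel lookup.  An
object overlapping N regions is handled by the *splitting* switch:

* **ON** — replaced by N sub-objects, one per overlapped region, each
  carrying that region's pixels.  Pixel counts are conserved; object counts
  are invalidated (objects are cut at region boundaries), and report CSVs
  carry a header comment saying so.
* **OFF** — assigned whole to a single overlapped region: by default
  uniformly at random with a recorded seed (the per-object random stream is
  derived from seed, section and object ID, so results are independent of
  processing order and thread count), or deterministically to the majority
  region with ties to the smaller region ID.

Pixels over atlas ID 0 are tallied to a reserved "outside atlas" row rather
than dropped.  Note that with splitting OFF the full object area is credited
to one region, so a region's `load` (below) can in principle exceed 1 for
objects much larger than their region; with splitting ON or majority
assignment on realistically sized regions this does not occur.

Masks *partition* a section into color-coded territories (e.g. left/right
hemisphere): each territory keeps exactly the pixels whose mask color
matches, quantification runs independently per territory, and region-pixel
denominators are territory-local (mask-excluded atlas pixels are marked with
a −1 sentinel and excluded from every count).  An object cut by a territory
boundary appears as separate partial components in each territory; pixel
totals are conserved.

## Reports, custom regions, point clouds

Per section (and territory) the report has one row per label-table region —
zero-filled when unobserved — plus the outside-atlas row: region pixels,
object count, object pixels, and `load` = object pixels / region pixels.
Custom regions (named ensembles of region IDs; no ID may belong to two) are
appended as rows summing their members column-wise.  Global rows sum section
rows with loads recomputed from the summed numerators and denominators.
All of this is exact integer arithmetic; the algebra (custom additivity,
global additivity, filter monotonicity) is asserted by tests.

The size filter keeps `min_size ≤ area ≤ max_size` with inclusive bounds.

Anchoring is linear: origin `o` plus axis vectors `u` (full image width) and
`v` (full image height), in atlas voxel units.  Pixel `(x, y)` maps to
`o + ((x+0.5)/w)·u + ((y+0.5)/h)·v` — the pixel-center convention; a corner
convention (no +0.5) is available behind a flag for cross-tool comparison.
If segmentation and anchoring resolutions differ, the fractional position is
taken over the segmentation's own dimensions.  Point clouds take every k-th
object pixel in row-major order (k=1 → every pixel; an object of `a` pixels
yields `ceil(a/k)` points), grouped and colored by atlas region or custom
region, and serialized as JSON groups of flat coordinate triplets (the
layout consumed by atlas point-cloud viewers).

File dialects: atlas maps as 24-bit RGB PNGs with `ID = R + 256·G +
65536·B` or plain integer text grids; label tables in ITK-SNAP label
format; anchorings in a documented JSON file; custom regions as CSV; run
templates as plain `key=value` text.  Section pairing across directories
uses the `_sNNN` file-name token, the same convention the batch renamer
produces.

## Synthetic datasets and what they do (not) show

The fixture generator emits the complete input dialect with planted ground
truth: partition layouts (vertical stripes, concentric frames, seeded
Voronoi), objects shaped as squares, discs or folded bars placed entirely
inside their target region with one pixel of 8-connectivity clearance, and
axis-aligned integer anchorings (`o=(0,0,20s)`, `u=(w,0,0)`, `v=(0,h,0)`) so
pixel `(x, y)` of section `s` sits at exactly `(x+0.5, y+0.5, 20s)`.  The
ground-truth CSV records each planted object's actual pixel count and
centroid; a self-verification pass re-reads the written images and re-derives
that CSV.  A boundary-object generator plants single connected bars with
exact per-region pixel counts for splitting tests, and a salt-noise flag
plants single-pixel objects for size-filter tests.  The default study
dataset used by the end-to-end checks is two 200×150 sections with four
stripe regions and ten planted objects (areas 9–64 px).

These fixtures exercise the bookkeeping exhaustively but are not
histology: they contain no segmentation errors, no texture, no partial
volume effects, and perfectly aligned atlas maps.  Passing them demonstrates
that the pipeline's arithmetic and geometry are correct, not that any
particular segmentation of real tissue is.

## Problem sizes and numerical choices

The test and acceptance workloads use moderate sizes chosen to exercise all
code paths with headroom — images up to 1024² for round-trips, 128² for the
labeling-oracle comparison (hundreds of random draws), 100 straddling
objects, two-section end-to-end datasets.  All comparisons are exact
(integer or byte equality) except the point-cloud coordinates, checked to
1e-9 against the analytic anchoring, and centroids, checked to 1e-12.
Degenerate inputs have defined behaviour: zero-area read windows, striped
TIFFs, all-background autocrops, empty section sets, duplicate or degenerate
anchorings, overlapping custom regions and unpaired sections all raise
typed, named errors before any output is written.
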