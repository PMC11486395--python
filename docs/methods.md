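# Methods

## Coordinate frame and scales

All manipulation happens in *display space*: a y-up Cartesian frame in
which one unit (one display pixel) spans `display_scale` μm. Raw data
coordinates (at `data_scale` μm/px) and the image raster (at
`image_scale` μm/px) are brought to this frame on load by the
μm-conserving rule `new = old × original_scale / display_scale`. The
scales are always user-supplied, never inferred from file metadata. A
rescale during a session is an ordinary logged operation (a uniform
scaling about the display origin by `old_display / new_display`).

Image rasters sit in the same frame with row 0 at the top edge: a
point (x, y) falls on pixel column `floor(x)` and row
`height − 1 − floor(y)`. This mapping is used consistently by the
overlap metric and the synthetic image renderer, so the two are
closed under each other.

## Rigid engine and replay

The rotation/flip pivot is the axis-aligned bounding-box center of the
scaled full point set (visible and invisible points alike), computed
once at load and never recomputed — this makes undo/redo exact
inverses, because replaying a log prefix always starts from the same
pivot. A session may also pin the pivot explicitly (`center=`), which
scripted parameter-recovery workflows use to invert a known map about
its true center.

Angles are degrees, counterclockwise-positive. A flip is three
operations — rotate by −θ (θ = accumulated angle), mirror about the
axis through the pivot, rotate by −θ again — after which the displayed
angle is set to −θ. The composite is an involution on coordinates:
two identical flips at any θ restore every point.

Each committed operation appends one log entry (`rotate Δθ`,
`translate Δx Δy`, one flip, one rescale factor). Live operations and
log replay share the same elementary array updates applied in the same
order, so replay of `entries[0:cursor]` reproduces the live
coordinates *bit-for-bit*, not merely within tolerance; undo/redo are
implemented as cursor moves plus replay. A new operation after undo
discards the redo branch. Linear operations are equivalently a product
of 3×3 homogeneous matrices; the test suite checks random ≤50-op
sequences against an independently implemented matrix oracle at 1e−9.

Only rescaling is applied to the raster during normal registration
(the typical workflow adjusts the data, not the image). An optional
nearest-neighbor raster rotation exists and is logged as an image-only
entry that point replay ignores.

## Elastic deformation

Points carry a three-state click cycle (idle → draggable → locked →
idle). A drag event records the anchor id, the anchor position *at
drag start*, the displacement, the influence threshold T (default
1000 display px) and the set of locked ids. Every unlocked point at
distance D < T from the snapshotted anchor moves by
`(dx·(T−D)/T, dy·(T−D)/T)`; strictly `D < T` receives displacement
(at D = T the factor is zero anyway — documented for bitwise
reproducibility); locked points are bit-identical before and after.
Distances are measured from the anchor snapshot, which makes replay on
the full dataset well-defined; events replay in recorded order (drags
do not commute in general). One anchor per event; there is no per-drag
undo, only a global reset that restores the pure-linear replay and
clears point states.

Drags are only legal after the linear phase is closed
(`begin_elastic()`); this package additionally freezes linear
operations and undo/redo once the elastic phase begins, so a session
is always a linear prefix followed by a drag suffix — the exact shape
the full-data replay assumes.

## Downsampling and full-data export

With annotations, cluster i of size C_i out of T gets quota
`D_i = (C_i/T)·N` rounded by the largest-remainder method (floors,
then +1 to the largest fractional remainders, ties by cluster order),
so ΣD_i = N exactly and |D_i/N − C_i/T| ≤ 1/N. Clusters whose quota
rounds to zero keep zero — proportionality is preserved exactly rather
than guaranteeing representation. Without annotations a uniform sample
without replacement is drawn. Sampling uses an explicit seeded
generator; there is no hidden global randomness. The displayed subset
only governs interaction: export replays scaling, the applied log and
the drag record over every original observation.

## File formats

Coordinates: CSV/XLSX with mandatory `x`, `y`, optional `cluster` and
`id` (row index when absent); AnnData `.h5ad` with coordinates from
`obsm["spatial"]`, annotation from a caller-named `obs` column and
counts from `X` (stored genes × observations internally). The
registered-coordinates CSV (`id,x,y,cluster`) writes shortest-repr
doubles and is read back with round-trip float parsing, so coordinate
round trips are bit-exact. The registration record is a plain-text
`key=value` file (three scales, angle, translation, flip counters,
pivot, image name); the manipulation log and drag record are CSVs. The
drag record carries the seven documented columns plus a trailing
`locked_ids` column (semicolon-joined) — without the lock snapshot a
bundle could not faithfully replay drags that had locked points.
A bundle (record + log + drags) plus the raw inputs reproduces the
registered output with no session state; the at-load display scale is
recovered from the logged rescale factors. Registered images re-encode
as JPEG quality 95.

## Metrics

Bead/gene filtering is strict: beads with total UMI **>** `min_umi`
(default 50; a bead at exactly 50 is removed), then genes detected in
**>** `min_beads` (default 5) of the retained beads, in that order.
Binning uses half-open squares `[x₀+i·s, x₀+(i+1)·s)` (edge points go
to the higher-index bin) with the grid origin at the component-wise
minimum over both sections, so two sections share a grid by
construction; empty bins are absent and binning conserves per-gene
totals exactly. The correlation universe is the intersection of
occupied bins (at least 3 required); matched pairing aligns identical
indices, random pairing applies one seeded permutation of the common
bins. Spearman ρ uses average ranks (scipy); genes with zero variance
in either vector are reported as undefined and excluded from the
median/mean summaries (both are reported, as different platforms are
conventionally summarized by one or the other).

The tissue mask is a deliberately simple reconstruction of an
otherwise unspecified step: grayscale luma, global Otsu threshold,
tissue = darker side (a `dark_tissue=False` flag inverts polarity),
largest connected component, holes filled. Overlap is
`100 × (points on tissue pixels) / (all points)`; points outside the
image bounds count as non-overlapping rather than erroring.

## Synthetic data model

The generator is the package's study-condition source, not a tuning
knob. A section is an ellipse of "tissue" (dark, ~90/255, on a bright
~250/255 background with σ=3 pixel noise) in a 400×400 px image at
1 μm/px; 600 points in 4 clusters are placed as Gaussian blobs
(σ = 0.25·min(axes)) rejection-sampled inside 93% of the ellipse so
that every generated point lies on renderable tissue; 30 genes get
Poisson counts with log-linear rates: a per-gene cluster loading
(σ = 1) plus a per-gene linear spatial gradient (σ = 1.5) over
normalized coordinates. This is the simplest model with the spatial
autocorrelation the matched-vs-random metric needs.

A serial pair maps section A through a known rigid transform (default
θ = 25°, t = (40, −15) μm about the ellipse center) and adds Gaussian
positional jitter (default σ = 5 μm, the scale of section-to-section
tissue differences) and count noise (rates multiplied by log-normal
noise, default σ = 0.3) before re-drawing Poisson counts. The exact
map is returned for recovery tests. Everything is derived from one
seed; identical specs produce byte-identical fixtures.

What passing tests on these fixtures do *not* show: real sections
differ by genuine biology (cell-type composition shifts, tears,
folds), real images carry staining variation and illumination
gradients that can defeat a global threshold, and real platforms have
capture-efficiency structure none of which is modeled. The metrics'
*mechanics* are validated here; their field performance depends on the
data.

## Problem sizes and numerical choices

Tests and the acceptance script run at deliberately small scales —
sections of 600–5,000 points, 15–30 genes, 100-simulation contrasts,
one 10,000-point replay — chosen so the whole suite completes in well
under a minute while every property is still exercised at
non-trivial n. All coordinates are float64; engine-vs-oracle
comparisons use 1e−9 absolute, CSV round trips 1e−12 (bit-exact in
practice), replay bit-equality where stated. Image resizing uses
bilinear resampling with output sizes rounded to the nearest pixel
(physical extent conserved within half an output pixel); raster
rotation, when requested, is nearest-neighbor.

## Known limitations

- No automatic registration, landmark detection, or spline/thin-plate
  warping — the elastic field is the piecewise-linear radial form only.
- One anchor per drag event; simultaneous multi-point drags are not
  modeled.
- The Otsu tissue mask assumes bimodal intensity with tissue darker
  (or uniformly inverted); faint or heterogeneous staining needs a
  hand-tuned mask upstream.
- `.h5ad` inputs must carry coordinates in `obsm["spatial"]`; other
  slot conventions require renaming upstream.
- Bins occupied in only one section are dropped from the correlation
  universe (zero-filling them is a defensible alternative that would
  lower ρ for sparsely overlapping sections).
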