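# Methods

This note documents the models and procedures implemented in `landtrax`, the
assumptions behind them, the parameters that matter, and the choices made
where the design was genuinely open.

## Conversion detection

### Binary consolidation

Every legend code is assigned to one of three groups: `crop` (cultivated
row, closely grown, and horticultural crops, including cultivated fallow and
alfalfa), `noncrop`, or `excluded` (codes such as open water that never
participate in the analysis). The assignment is data: a legend CSV with
`code,name,group` columns; `default_legend()` provides a compact CDL-like
legend for synthetic work. Consolidating before change detection trades
thematic detail for the much higher accuracy of the broad crop/noncrop
distinction; specific covers are re-identified afterwards during
attribution.

### Trajectory encoding and the majority filter

The per-pixel sequence of binary labels over all years is encoded as a
single integer code (one code per distinct sequence, invertible code book).
The spatial filter operates on this composite: a pixel's code is replaced by
code v when v differs from the center and occupies at least
⌈valid_neighbors/2⌉ of the valid 8-neighborhood. Choices the filter
definition leaves open, and the defaults here:

- **Tie-break** between two qualifying values: the smaller code wins
  (deterministic).
- **Edges**: only in-grid neighbors count; the half threshold is relative to
  the count of valid neighbors.
- **Excluded pixels** pass through unchanged and never vote.
- **Passes**: one, by default. Iteration to convergence is exposed as
  `majority_filter(traj, passes=n)` but is not part of the standard
  procedure.

Filtering the multiyear composite rather than each year separately is load
bearing: a pixel mislabeled in one year differs from its neighbors over the
whole trajectory, so a single spatial pass repairs space–time anomalies that
per-year filtering would handle inconsistently.

### Transition classification

With n annual years (n ≥ 4, default 10) and sparse-epoch products, each
trajectory reduces to one of five classes. Single-switch trajectories become
conversions only if the switch index k has two annual years on each side
(2 ≤ k ≤ n − 2) and the two most recent epoch products strictly before the
switch year agree with the prior group. Decisions where the procedure is
underdetermined:

- **One prior epoch only**: that epoch must agree, and the pixel is flagged
  in a QA band (`qa_single_epoch`). No prior epoch: the candidate fails.
- **Failed candidates** (window or epoch disagreement) fall back to
  intermittent when they meet the ≥2-crop-year rule, else to the stable
  class of their majority group — conservative toward non-conversion, which
  matches the overall bias of the procedure toward map confidence over
  complete capture.
- **Calendar semantics**: a switch between years y−1 and y is dated y, the
  first growing season showing the new group.

Attribution reads the *original* legend series: `pre_cover` is the modal
code over the two years preceding the switch with ties to the most recent
year (for a two-year window this resolves to year k−1), `post_cover` is the
first post-switch code (the first planting). Refinement rules then discard
conversions among {cultivated fallow, alfalfa} × {non-alfalfa hay,
grassland/pasture} in both directions and developed→cropland, reassigning
those pixels to the stable class of their final-year group and clearing
attribution; reassignment counts are logged. Perennial tree crops and rice
enter only as configurable extra code lists (`special_class_codes`), not as
bespoke logic.

### Minimum mapping unit

`pixel_threshold(mmu_acres, pixel_size_m)` returns the smallest n with
n × pixel_area ≥ mmu_acres (1 acre = 4046.8564224 m²; 5 acres at 30 m gives
23 px). Patches are 8-connected components of equal transition class
(consistent with the 8-neighbor filter; 4-connectivity is available). All
sub-threshold patches are removed simultaneously, then voids are filled from
the geometrically nearest surviving pixel via a Euclidean distance
transform, copying conversion attributes with the class. Distance ties are
resolved by the transform's fixed scan order, which is deterministic across
runs and platforms. The remove-and-fill pass repeats until no patch is below
threshold — almost always one pass; iterating closes the rare case where two
fill fronts meet and mint a sub-threshold sliver, and makes the operation
idempotent by construction. A scene containing a single patch is returned
unchanged (it is trivially nearest to itself). The MMU applies to the
composite transition classes, never per year: mixed-year salt-and-pepper
conversions survive composite enforcement but would be fragmented and lost
under per-year enforcement (tested).

## Yield modeling

Training rows are zone × crop × year records: the zonal mean (or sum, min,
max — per covariate) of each covariate grid within the crop's planted extent
in that zone-year, joined to the zonal yield average. NaN cells within a
mask are excluded; rows with finite coverage below 50% of the mask are
dropped. The regressor is a random forest with 250 trees, 21 candidate
variables per split, and minimum node size 5 — clamped with a warning when
fewer covariates exist, since small synthetic runs use 3–5 covariates. The
30% holdout is drawn with a seeded permutation so that |holdout| =
round(0.30·n) exactly, and the validation report echoes the full parameter
set plus holdout RMSE and R². Predictions are deterministic given the seed,
bounded by the training-yield range (a property of regression forests), and
interpreted only relatively. The model intentionally carries no dynamic
inputs — no weather anomalies, no management, no genetic trend — and does
not differentiate irrigation status or wheat varieties; its predictions are
representative multiyear expected yields as a function of the static
biophysical setting.

## Yield differentials

y_nat is the frequency-weighted mean prediction over stable cropland of the
focal crop; weights default to one per qualifying pixel when per-year
frequency rasters are not supplied. diff_nat = (y_gc − y_nat)/y_nat on
new-cropland pixels. The local differential uses fixed, non-overlapping
blocks anchored at the raster origin (the "encompassing" neighborhood read
as a tiling rather than a moving window; whether the operational grid is
origin-anchored is not specified, and a tiling keeps every pixel's
neighborhood unambiguous). y_neigh excludes new-crop pixels — the comparison
is against *existing* cropland — and blocks lacking existing crop yield
nodata. The national summary of diff_loc weights each block's mean by its
new-cropland pixel count. Two identities hold by construction and are
tested: the weighted mean of diff_nat over the reference mask is zero, and
both differentials are invariant under global rescaling of the yield
surface. The default neighborhood is 10 km; the demo pipeline uses 1.5 km
blocks because its scenes are 6 km across.

## Habitat accounting

Milkweed losses multiply per-stratum stem densities (cover type × CRP
status, from an editable CSV of synthetic example densities — shipped values
are placeholders, not field estimates) by converted acres, summed over
strata; the SE treats strata (cover × CRP × zone) as independent and adds
(acres × se) contributions in quadrature. The converted-land mean density is
compared with the mean over remaining natural (stable noncrop) land using a
standing-cover raster attached by the caller. Breeding-pair categories take
their range midpoints; the single open-top category takes a constant
(default 110 pairs/sq mi). Because the areal normalization of "total nesting
opportunities" is convention-dependent, totals are reported both as
density × area and per-pixel. Long-term habitat is the complement of
ever-cultivated across all epoch rasters (default cultivated codes 81/82;
configurable), so adding epochs can only shrink the mask. CRP status is an
input mask; no enrollment-database processing is attempted.

## Synthetic scenes: what they emulate, and what they do not

The generator plants a lattice of axis-aligned rectangular fields (row
bands × column bands, sides ≥ 3 px) and assigns each a role: stable crop,
stable noncrop, single-transition conversion or abandonment (switch year
uniform over the admissible window), or intermittent cropland (alternating
pattern, >1 switch, ≥2 crop years). Defaults — 200 × 200 px at 30 m, ten
annual years (2008–17), epoch years sampled from the first two series
years, 36 fields, role fractions 0.25/0.10/0.10, noise 0 — mirror the input
structure the detection rule assumes at desk scale. Label noise flips a
pixel-year to a random class of the opposite binary group with independent
probability `noise_rate`; speckle injects persistent 2×2–4×4 opposite-group
patches below the MMU. All randomness derives from one seeded generator
through named substreams, so scenes are bit-reproducible.

Sequences are placed so that no two diagonally adjacent lattice cells share
a binary trajectory (stable families and intermittent phases stripe by
column parity; conversion switch years are deconflicted against diagonal
neighbors). At every junction of a lattice no single alternative code can
then reach half of a corner pixel's neighborhood, so a clean scene is a
fixed point of the majority filter and noiseless detection recovers truth
exactly — the basis of the exact-recovery test.

What the generator does *not* emulate, and hence what passing tests do not
show about real data: spatially or temporally autocorrelated classification
error (CDL confusion is strongly class- and context-dependent), irregular
field geometry, class frequencies of any real landscape, mixed pixels at
field edges, and registration error between the annual and epoch products.
The independent per-pixel noise model is a modeling choice, not a claim
about CDL error structure.

## Numerical and interface choices

- Unit constants: 1 acre = 4046.8564224 m², 1 sq mi = 640 acres.
- Rasters are single-band TIFFs with a JSON sidecar (origin, pixel size,
  nodata); transition maps are 4-band TIFFs (class, year, pre, post). All
  inputs must be pre-aligned; misalignment raises, reprojection is out of
  scope. A bilinear resampling utility is provided for coarse covariates.
- The superclass-accuracy table accepts a nullable year column: rows with a
  year match exactly, rows without pool across years.
- Problem sizes in the test and acceptance suites (200 × 200 scenes, 2,000
  training records, 100 random 12 × 12 grids, five noise seeds) are chosen
  as the smallest scales at which each property is meaningfully exercised.

## Known limitations

Headline national quantities (total converted acres, national yield
differentials per crop, absolute stem losses) depend on continental input
archives and are out of scope; the pipeline validates structure — rules,
identities, recovery, sign behavior — not national magnitudes. Vector
(polygon) MMU enforcement, distributed tiling of continental rasters, and
estimation of superclass accuracies from reference data are likewise not
implemented.
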