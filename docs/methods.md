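# Methods

## Scope and model

`octamorph` measures the pathologic vessel network of a macular
neovascularization (MNV) in a 2-D en-face OCT-angiography projection and
compares the resulting per-lesion parameters across MNV types. The analysis
treats the angiogram as a scalar flow-signal raster on a known physical
grid; it does not model axial (depth) flow, projection artifacts, or the
device's signal chain. Lesion delineation is an input: the package accepts a
binary mask and never segments the lesion itself.

### Scan geometry

A scan is square: `field_of_view_mm` (default 6.0) over `grid_px`
(default 500) pixels per side, giving a derived pitch of
`1000·fov/grid` µm/px — 12 µm/px by default, computed with exact rational
arithmetic. Pixels are treated as area elements, so lesion area is exactly
`count × pitch²`. Both geometry fields are configurable (3 × 3 mm scans
use the same code path); the pitch is always derived, never stored.

## Vessel extraction

1. **Tubularity filter.** Per scale *s*, Gaussian-derivative Hessian
   eigenvalues `|λ1| ≤ |λ2|`, normalised by *s²*, are combined into the
   Frangi bright-ridge measure with β = 0.5 and the second-order-structure
   scale *c* set to half the maximum Frobenius norm at that scale. The
   response is the maximum over scales, zero outside the mask. Default
   scales {1, 2} px target the 1–2.5 px calibers that dominate published MNV
   caliber quartiles at 12 µm/px; larger scales systematically widen the
   response of thin vessels, inflating downstream caliber and junction
   estimates (measured on phantoms: about +1 px caliber bias with a 4 px
   scale in the set), so they are opt-in rather than default. Borders use
   reflection so a constant image yields an exactly zero response.

2. **Binarization.** Otsu's threshold computed from in-mask response values
   only (the empty background would otherwise dominate the histogram), or a
   fixed threshold. Cleanup, each step configurable and disabled at 0:
   closing with a 1 px disk (bridges single-pixel gaps the ridge filter
   leaves at crossings), filling of interior holes ≤ 4 px (dark speckle
   punched through a vessel; each such hole otherwise becomes a spurious
   skeleton loop with two junctions), removal of connected components
   < 5 px (speckle islands). The raw intensity can be thresholded instead
   of the vesselness (`binarize_source="intensity"`).

3. **Thinning.** `skimage` topology-preserving thinning, followed by removal
   of fully-set 2 × 2 blocks (deterministic raster order, only deletable
   pixels) and iterative pruning of terminal spurs shorter than
   `prune_spur_px` (default 3 px ≈ 36 µm — thinning artifacts at tube
   boundaries are 1–2 px; true terminal branches at this resolution are
   longer). Thinning + cleanup is run to a fixpoint before and after
   pruning, which makes skeletonization idempotent and removes the corner
   pixels pruning exposes. Pruning never removes a chain that ends at
   another endpoint, so connected components are preserved.

4. **Calibers.** `diameter(p) = 2 × EDT(p) × pitch` at each centerline
   pixel, where EDT is the Euclidean distance to the nearest non-vessel
   pixel. On a discrete tube of width *w* px this reads ≈ *w* + 1 px
   axis-aligned (a 1 px line reads 24 µm at 12 µm/px — the resolution
   floor); averaged over orientations the bias is under one pitch, which is
   the accuracy claimed for `avgW`.

## Centerline graph

Junction pixels are skeleton pixels with ≥ 3 skeleton 8-neighbors; endpoint
pixels have exactly 1. Junction pixels are merged into one node when their
clusters fall within a 1-px dilation of each other (centres ≲ 3 px apart):
thinning regularly renders one anatomical fork as two or three nearby
degree-3 pixels, and the published node densities depend directly on this
convention, so it is explicit, configurable (`junction_merge_px = 0`
restores strict 8-adjacency) and tested. Both the merged node count and the
raw junction-pixel count are exposed.

Segments are maximal chains whose interior pixels have degree 2; steps weigh
1 pitch (edge) or √2 pitch (diagonal). Every skeleton adjacency belongs to
exactly one segment — adjacencies between two junction pixels of one merged
cluster are kept as one-step `internal` segments — so Σ segment lengths
equals the skeleton's total path length exactly (tested against a
brute-force adjacency sum). Junction-free closed loops (anastomoses) are
retained as node-less segments. Note the 8-connected step convention
overestimates the Euclidean length of oblique straight lines by up to ~8 %
(exact on axis-aligned and 45° lines); this digitization bias is part of the
`sumL` definition, not corrected.

Aggregates: `numN_per_mm2` = junction nodes / lesion area (endpoints are not
nodes — nodes are where vessels fork); `sumL_mm` = Σ segment lengths;
`avgW_um` = length-weighted mean of per-segment mean calibers (robust to how
finely segmentation splits the network).

## Fractal dimension

Box counting on the skeleton (not the filled vessel map — skeleton counting
is the variant consistent with reported MNV values reaching below 1.2), with
box sides 2, 4, …, 2^k tiling the skeleton's bounding box anchored at its
top-left corner, k maximal with 2^k ≤ short-side/4 and at least three sizes
required (smaller lesions raise an error naming the stage). fd is −slope of
the OLS fit of log N(s) on log s, clipped to [0, 2]. A single anchored grid
keeps the estimate deterministic; `multi_offset=True` averages over all s²
grid offsets. An explicit counting-field override exists for degenerate
shapes whose own bounding box cannot host three box sizes (used by the
exact line/point references in the tests). Exactness anchors: an
axis-aligned line gives 1.0 and a filled square 2.0 to machine precision.

## Group statistics

Per parameter across types 1/2/3: classic mean-centered Levene (the named
test, not the Brown–Forsythe median variant; switchable) and Shapiro–Wilk on
pooled groupwise-centered residuals (the residuals of the one-way model).
If either p < α (default 0.05) the omnibus is Kruskal–Wallis with mid-rank
tie correction and χ²(k−1) p-value, followed by Dunn's z tests

    z_ij = (R̄_i − R̄_j) / sqrt[(N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/n_i + 1/n_j)]

two-sided, Bonferroni-adjusted by the 3 pairs per parameter (no
cross-parameter adjustment). Otherwise one-way ANOVA with pooled-variance
pairwise t tests, same adjustment. Degenerate inputs (all values identical)
return statistic 0, p = 1 with a warning instead of NaN. Kruskal–Wallis and
Dunn are implemented in-package (the tie conventions are the result-bearing
part) and cross-checked against `scipy.stats.kruskal` and a brute-force
rank oracle in the tests; Levene, Shapiro–Wilk, ANOVA and t are delegated
to scipy behind the module's interface. Both precondition p-values are
always reported rather than asserting which one failed.

## Synthetic data

### Population generator

For each of the 18 parameter × type cells the printed mean m and SD s are
moment-matched: area, sumL and avgW — whose printed means sit far above
their medians — use a log-normal with σ² = ln(1+(s/m)²), μ = ln m − σ²/2
(analytic mean and SD equal the printed values exactly, by construction);
fd, numN and flow (mean ≈ median) use a normal truncated at 0 by resampling
(the sub-zero mass is negligible for every cell, so moments are effectively
unchanged). Printed quartiles are retained for reporting but not enforced —
moment calibration takes precedence so that mean-convergence checks are
well-posed. Parameters are sampled independently within type: the published
table gives marginals only, and the real area–sumL correlation is unknown;
significance-pattern results therefore rest on marginals alone (a
documented limitation). Cohorts default to the study's 39/32/19 group
sizes.

### Image-level phantom generator

A stochastic branching network grown inside a random elliptical mask of the
target area: tips advance 3 px per step with 12° Gaussian heading jitter,
bifurcate with probability 0.12/step into daughters at ±27.5° whose
calibers shrink by 0.85, and stop at the mask boundary, below 1 px caliber,
or when a step would bring the tube within 2.3 px of unrelated vasculature
(collision avoidance keeps branch spacing above the ~2 px needed for
junctions to be individually resolvable; freshly spawned siblings get a
3-step grace near their spawn point). Roots start at 30 µm caliber
(tapering reproduces the ~20–26 µm published caliber range); when a tree
dies out before the network reaches a target centerline density
(8 mm/mm²; the published type-1 mean corresponds to ~12 mm/mm², near the
packing limit the spacing constraint allows) additional roots sprout at
clear locations, mimicking multiple ingrowth sites. Centerlines are
rasterized as tubes (pixels within caliber/2 of the path) and degraded with
unit-mean gamma speckle (SD 0.2) over a 0.15 background.

Ground truth is recorded from the generated geometry: mask area exactly,
Σ step lengths for sumL, length-weighted nominal caliber for avgW. For the
node count, a bifurcation is recorded as a ground-truth junction only when
both daughters draw more than `1 + r_parent/sin(θ/2) + r_daughter` px —
a daughter's centerline runs inside the parent tube for about
`r_parent/sin(θ/2)` before emerging, and a shorter nub leaves no fork in
the rasterized image (it is absorbed by thinning or spur pruning), so
counting such events would misstate what the image contains. This
first-order visibility model agrees with junction censuses of noise-free
rasterizations to about ±2 on mid-size lesions.

### What the phantoms do and do not show

The phantoms share the real data's geometry (pitch, lesion scale, caliber
range, branching topology, speckle) but not its physics: no projection
artifacts, no RPE shadowing, no choroidal background flow, no
flow-dependent signal. Passing recovery tests therefore demonstrates that
the measurement chain is unbiased on resolvable tubular networks at this
resolution — not that it is robust to device-specific artifacts. Recovery
on 20 seeded mid-size phantoms (the problem size used throughout) is
assessed as the median over phantoms: area exact, |sumL error| ≤ 10 % (each
phantom individually), median |numN error| ≤ 2 junctions, |avgW error|
within one pixel pitch.

## Numerical and design choices

- All pipeline stages are deterministic; ties in thinning cleanup resolve
  in raster order; stochastic operations take explicit seeds.
- `flow` uses the lesion mask as denominator (a per-lesion vascularization
  proportion); with an adaptive threshold it is invariant under intensity
  rescaling.
- Config (`RunConfig`) serializes to JSON; a sha256 hash of the canonical
  form is embedded in every output, and equal config + seed implies
  byte-identical outputs.
- Simulation sizes: generator-mean checks use 100 000 draws; the
  significance pattern uses 200 cohorts of 90; recovery uses 20 phantoms.

## Known limitations

- numN is convention-bound: different junction-merging radii change the
  absolute density (both counts are exported). The very high published
  densities (~440–500 /mm²) are not reproducible from any plausible
  skeleton at 12 µm/px with the merged-node convention; the per-type
  *pattern* is what the calibrated population generator reproduces.
- sumL inherits the 8-connected length convention's orientation-dependent
  bias (≤ 8 % on oblique straight vessels).
- avgW is floored at 2 pitch by the distance transform; sub-pixel calibers
  are not measurable.
- The flow denominator and the FD target set (skeleton vs filled map) are
  interpretations of ambiguous reporting conventions; both are switchable
  in config.
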