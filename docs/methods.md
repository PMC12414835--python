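# Methods

This note documents the model behind `confor`, the conventions every
number in its reports depends on, and the synthetic landscape used for
desk-scale runs — including what that landscape does *not* emulate.

## The analysis

The pipeline takes four co-registered square-pixel rasters (default 100 m
pixels, so one pixel is exactly 1 ha): a conservation-value probability
surface p ∈ [0, 1], a categorical land-cover raster, a binary baseline mask
of the confirmed conservation network, and a region partition. All areas
are pixel counts times pixel area; there is no vector geometry, no
reprojection and no CRS handling (inputs must already share a grid, and
`assert_aligned` enforces it).

Stages, in order:

1. **Land-cover semantics.** Five forest-type codes (spruce, pine,
   deciduous, mixed coniferous, mixed deciduous–coniferous) plus
   non-forest codes. Baseline pixels on non-forest are excluded up front
   and the excluded area reported.
2. **CF extraction.** CF = forest ∧ ¬baseline ∧ p ≥ τ_min, divided into
   nested classes at thresholds 0.9 … τ_min (step 0.1). Scenarios
   S(τ) = baseline ∪ CF(τ).
3. **Area accounting.** Per (region, forest type, class): area in ha, share
   of the type's total forest area in the region, and increase relative to
   the region's all-forest baseline area. Mixed types are reallocated into
   pure types by fixed fractions before reporting — this path never double
   counts, and reallocation conserves total area exactly.
4. **GI density.** D(x) = 100 · Σ_{o∈W} w(x+o)/|W| for a circular window W.
   Membership weights w: pure stands of the requested type 1, mixed stands
   0.5, everything else 0; for per-type analyses a mixed-coniferous pixel
   counts toward *both* spruce and pine (repetitive assignment — here the
   double counting is intentional and confined to the density pathway).
5. **Functional habitat & hotspots.** Functional = D ≥ 20%. For each
   insertion step τ (descending), CF pixels of class ≥ τ lying inside the
   buffered (3 km) functional zone of S(τ) are collected; the union over
   steps, labeled with 8-connectivity and filtered at ≥ 1 ha, is the
   hotspot set. The pipeline verifies that inserting the hotspots onto the
   baseline never shrinks functional habitat (guaranteed by membership
   monotonicity of the density operator).

## Parameters that matter

| parameter | default | unit | why |
|---|---|---|---|
| τ_min (CF threshold) | 0.4 | – | reported minimum model probability of formally/voluntarily protected forest |
| class step | 0.1 | – | six nested ambition levels 0.9…0.4 |
| window radii | 3000, 1000 | m | national GI-density analysis practice; headline statistics use 3 km |
| outer analysis rim | 5000 | m | keeps edge windows fully supported (no spatial shrinkage) |
| functionality threshold | 20 | % | rule-of-thumb habitat-functionality density |
| hotspot buffer | 3000 | m | CF within one window radius can change any focal area's density |
| minimum hotspot patch | 1 | ha | one pixel at native resolution; only bites at finer grids |
| mixed-stand weight | 0.5 | – | mixed stands provide lower habitat quality than pure stands |
| reallocation fractions | mixed conifer → ½ spruce, ½ pine; mixed decid.–conifer → ½ deciduous, ¼ spruce, ¼ pine | – | symmetric, conservative; fully config-overridable |

All of these live in `PipelineConfig` / the YAML config; nothing is
hard-coded.

## Numerical conventions

* **Inclusive thresholds everywhere**: p ≥ τ, D ≥ 20%, window distance
  ≤ r, buffer distance ≤ width. A pixel exactly at a class boundary belongs
  to the higher class.
* **Window discretization**: a window of radius r contains every integer
  offset (di, dj) with (di² + dj²)·pixel² ≤ r²; distances are measured
  between pixel centers. At 100 m pixels the 1-km window has 317 cells and
  the 3-km window 2,821 (lattice-point counts). Focal-statistics kernels
  differ between GIS tools; this is the convention all numbers here use.
* **Density denominator** is always the full window size, with cells
  outside the data extent contributing zero weight. The analysis frame is
  extended by the outer rim so no study pixel loses support; statistics are
  reported over the interior study extent only (frame minus rim).
  Windows thus measure density against *all* land, not forest only.
* **Distribution statistics**: quartiles by linear interpolation; whiskers
  at the most extreme values within 1.5×IQR; zeros included (network gaps
  are part of the distribution). Median increases are relative to the
  baseline-scenario median of the same region/type/radius; a zero baseline
  median is flagged undefined, not infinity.
* **Patch statistics**: 8-connected labeling; AAr uses the sample standard
  deviation (n−1), 0 for a single patch; a patch straddling regions is
  assigned to the region holding most of its pixels, ties to the lower
  region code.
* **Degenerate inputs**: empty masks give zero areas and flagged (not
  raised) quantile rows; regions without baseline get undefined increase
  columns; a probability surface uniformly below 0.4 makes baseline
  generation fail with a diagnostic rather than silently producing a
  baseline the threshold logic cannot interpret.
* **Display rounding** (summary only; CSVs keep full precision): "–" for
  an absent class, "0" for areas below 0.5 ha, whole hectares otherwise.

## Design choices where the design was open

* **Hotspot reference state.** Functional zones can be read as fixed at the
  pre-insertion baseline or as recomputed at each insertion step. Default
  is per-step recomputation (`hotspot_reference: per_step`), which treats
  every ambition level as a planning state of its own; `baseline_only` is
  available in config.
* **Mixed-stand weighting scope.** The 0.5 weight applies to mixed pixels
  in both baseline and CF membership by default; `mixed_weight_scope:
  cf_only` restricts it to CF.
* **Per-type membership of mixed deciduous–coniferous** feeds deciduous
  and both conifer types (at weight 0.5); only mixed coniferous has a
  prescribed repetitive assignment, so this is config-overridable.
* **Hotspot identification uses the all-forest density**, not per-type
  densities.

## The synthetic landscape

The generator produces the statistical structure the analysis assumes, at
desk scale (default: a 300×360 frame of 1-ha pixels whose interior after
the 5-km rim is a ~52,000-ha study area):

* **Probability surface**: Gaussian white noise smoothed at a 3-km
  correlation length, blended (weight 0.35, via normal scores) with a
  deterministic north–south gradient — the mountain-like band carries
  systematically higher conservation value, as intact subalpine forest
  does — then rank-mapped to a right-skewed Beta(1.5, 3.5) marginal (most
  managed forest has low predicted value; the marginal is config).
* **Land cover**: forest (~60% of land) and forest types assigned by
  thresholding independent smoothed latent fields at empirical quantiles,
  per region — so realized shares track targets within fractions of a
  percent and types form clumps, not speckle. The mountain-like band is
  deciduous/spruce-rich, the inland/coastal bands pine-dominated.
* **Baseline**: patches grown greedily from local maxima of a *survey
  field* — the probability surface blended with an independent
  autocorrelated field at weight 0.35 (`survey_noise`). The noise encodes
  that the confirmed network was mapped by decades of unsystematic field
  surveys and is incomplete: the baseline preferentially sits on
  high-probability forest but misses part of it, which is precisely why a
  substantial CF remains outside (without this component the baseline
  swallows nearly all p ≥ 0.4 forest and CF collapses). Region bands hold
  baseline fractions 0.45 / 0.10 / 0.05 of their forest (≈ 20% overall).
* **Regions**: contiguous horizontal bands.

Across seeds this yields: median probability inside the baseline ≈
0.48–0.59 (> 0.4), ≥ 75% of non-baseline forest below 0.4, CF ≈ 12–15% of
forest, and non-degenerate functional areas and hotspot sets — the
structure the 0.4 threshold and the 20% functionality rule operate on.
Everything is deterministic given one master seed; per-generator sub-seeds
derive from it via `SeedSequence`.

**What it does not emulate:** real geography (elevation, hydrology,
municipal region borders), true land-cover class geometry, the spatial
error structure of a fitted habitat model, forest-type-dependent
probability distributions, and the actual patch-size distribution of the
national conservation network. Passing tests therefore demonstrate the
correctness and invariances of the *computation* on realistically
structured inputs — not calibration of any real landscape's numbers.

## Problem sizes

Unit and property tests run on toy grids (≤ 64×64) where brute-force
oracles (double-loop convolution, BFS flood fill, exhaustive distance
checks, per-pixel area counts) are exact and fast; generator contracts are
checked on 100×120 to 500×500 grids and, for the quantile structure, on
the full default frame across 10 seeds. The acceptance script runs the
complete pipeline once on the default 300×360 frame. The whole test suite
and the script each finish in well under a minute on one CPU.

## Known limitations

* Single CRS-less grid model: inputs must be pre-aligned single-band
  GeoTIFFs with square pixels.
* GI density is a structural metric; it ignores matrix resistance and
  dispersal behavior (no current-flow or graph connectivity).
* The 0.4 and 20% thresholds are planning conventions, not ecological
  constants; both are config, and conclusions can be threshold-sensitive.
* Mixed-stand handling necessarily differs between the area-accounting
  path (reallocation, conservative) and the density path (repetitive
  assignment, double counts by design); per-type areas from the two paths
  differ slightly and deliberately.
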