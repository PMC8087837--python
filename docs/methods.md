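# Methods

## The classification model

A taxon is represented by a *filter set*: inclusive `[min, max]` gates on
a handful of per-particle morphological properties, combined by
conjunction.  A particle is *selected* by a class's filter when every
gate passes; per-class filters act independently (a particle may be
selected by several classes, or none).  For abundance aggregation an
*exclusive* mode assigns each particle to the first selecting class in a
configurable priority order, falling back to `unclassified`.

Filters are built exactly as an instrument operator would build them:

1. **Training pool.** Up to 150 representative particles per class; 25
   or 50 of them are drawn without replacement as the training subset
   (deterministic per seed).  Training rows are excluded from all test
   evaluation downstream.
2. **Range fitting.** Each candidate feature is gated at the subset's
   minimum and maximum.
3. **Reduction.** Greedy backward elimination: at each step the gate
   whose removal yields the highest overall accuracy
   `(TN + TP) / total` is dropped, while the post-removal accuracy stays
   above the threshold (0.75 by default).  The procedure stops when any
   further removal would cross the threshold, so the returned gate set
   is minimal under single removals.  Accuracy ties are broken by
   dropping the feature that comes last in the canonical property order
   (Average Blue, Diameter (ABD), Edge gradient, Intensity, Length,
   Perimeter, Ratio red/blue, Ratio red/green, Roughness, Sigma
   intensity), which keeps earlier-listed features preferentially and
   makes the procedure deterministic.  Reduction is evaluated on the
   union of all classes' training subsets, never on held-out data.
4. **Intersection.** The "25" and "50" filters narrow to their overlap:
   per shared feature, highest min and lowest max; features present in
   only one parent are carried over unchanged (the published reference
   tables show identical feature lists in both columns, so the
   carried-over case is unobserved there; carrying over is the
   conservative choice).  An empty overlap is an error, not a silent
   impossible gate.

Design choices that were genuinely open: "systematic selection" of
features is operationalised as the greedy elimination above (cheap,
deterministic, and cross-checked against exhaustive subset search on
small instances in the test suite); "accuracy deviating significantly"
is operationalised solely as the printed 0.75 threshold, with no
significance test implied; gate bounds are inclusive because the
published intersection columns reuse boundary values, which would
self-exclude under open intervals.  Whether the instrument applies
per-class filters independently or sequentially is not documented; both
modes are provided (`perclass` for confusion-matrix evaluation,
`exclusive` for abundance series).

## Particle properties

Segmentation thresholds the grey image (unweighted mean of R, G, B) at a
global dark-object threshold (default 200/255), keeps the largest
8-connected component and preserves interior holes.  Properties and
their conventions:

| Property | Definition | Convention fixed here |
|---|---|---|
| Intensity / Sigma intensity | mean / sd of particle grey values | grey = mean(R,G,B); population (n) denominator |
| Average Blue, ratios | channel means over the mask | zero-denominator ratios raise, never return inf |
| Diameter (ABD) | `2·sqrt(area/π)·px` | area = pixel count incl. nothing outside mask |
| Length | max of 36 Feret measurements | caliper on pixel-corner points, 0°–175° in 5° steps |
| Perimeter | total edge length incl. hole edges | crack boundary: count of exposed unit pixel edges |
| Roughness | perimeter / convex perimeter | hull over pixel corners; ≥ 1 by construction |
| Edge gradient | mean Sobel magnitude on the outside border | unnormalised [1,2,1]×[−1,0,1] kernels; per-pixel magnitude clamped to [0,255]; border = 8-connected dilation minus mask |

The crack-boundary convention makes "roughness = 1 for a filled convex
shape" exact for axis-aligned rectangles and keeps hole edges countable;
its cost is a digitisation bias on smooth shapes (a rasterised disk
reads ≈ 4/π ≈ 1.27).  The instrument's grey conversion and Sobel
normalisation are proprietary, so absolute signal values are
convention-dependent; everything inside the pipeline is self-consistent,
and tests pin the conventions (step edge of height h → border response
4h; 10×20 rectangle → perimeter 60 µm at 1 µm/px, roughness exactly 1).

## Validation metrics

Counts are the canonical inputs; each metric normalises where its
definition does.  Per classifier: precision `TP/(TP+FP)`, false
discovery rate `FP/(TP+FP)` (their sum is 1 whenever anything is
selected), balanced accuracy `(TPR+TNR)/2` (robust to the imbalanced
test sets this workflow produces).  Between binned compositions:

* **Hellinger distance** `(1/√2)·sqrt(Σ_k (√(X_k/X) − √(T_k/T))²)`,
  averaged over filter sets; the 1/√2 rescales the disjoint-support
  maximum from √2 to 1.  For several filter sets the totals `X`, `T` in
  the denominator are the grand dataset totals, exactly as the
  definition is written; with a single filter set this is the ordinary
  normalised Hellinger distance.  Used as the train/test dataset-shift
  indicator: per classifier, the true-class composition of its selected
  set in training vs test.
* **SMAPE** per class: mean over filter sets of `|X − X'|/(X + X')`,
  reported ×100 as a percentage in [0, 100]; 0/0 terms contribute 0.
* **Bray–Curtis** `Σ|X_k − X'_k| / Σ(X_k + X'_k)` and
  **Kullback–Leibler divergence** `Σ p_k (log p_k − log q_k)` on the
  normalised compositions (natural log by default, base configurable;
  zero-actual bins contribute 0; a zero-forecast bin with positive
  actual is infinite unless a pseudo-count is configured — the pipeline
  report uses 0.5 only when a class's selected count is zero).

Every metric is verified against an independently coded brute-force
evaluation of its definition on random count tables (tolerance 1e−12).

## The synthetic generator

The generator emulates what the classifier consumes, not what a
microscope sees.  A colony is a union of `n_cells` filled disks of
radius `cell_radius_um` jittered inside a disk of radius
`colony_spread_um`; a fraction `hole_fraction` of cells becomes interior
holes (placed with a minimum mutual separation so they perforate rather
than shred the colony); `halo_strength` sets the pixel width of a linear
intensity ramp from the particle colour to the background (the
"semi-transparent sheath" that raises the edge gradient); `base_color`
sets the channel means and `intensity_sd` the per-pixel luminance noise.
Background is RGB (230, 230, 230) with Gaussian noise sd 3, so the
default threshold segments trivially.  A particle that would come
within two pixels of the frame edge raises an error rather than being
cropped.  Pixel calibration defaults to 0.554 µm/px (a 10× objective);
the default frame is 512 px so the largest calibrated colonies fit.

Each default profile carries a `feature_envelopes` table: the published
reference gate range per gated feature (where several ranges are printed
for a class/feature, their common intersection).  Profiles whose class
gates a size feature rescale each rendered layout so that feature lands
on a target drawn uniformly from a sub-interval of the envelope
(uniform, because the published ranges are min/max envelopes rather than
distributions).  The remaining profile parameters were calibrated once,
by Monte-Carlo sweep, so that ≥ 95% of renderings fall inside every
envelope at `overlap_scale = 0`; the shipped defaults achieve 95–100%
containment per (class, feature) at n = 60.

*Table mode* skips rendering: each feature is drawn independently from a
truncated normal centred mid-envelope with sd = width/5, truncated at
the envelope (ungated features use nominal centres matched to the image
renderer's output).  `overlap_scale` multiplies the sd and the
truncation half-width by `1 + overlap_scale`, subject to hard validity
bounds; 1.0 is the package's bloom-heterogeneity setting, chosen to
make within-genus classes overlap the way a heterogeneous seasonal
bloom does.  Table mode draws features independently, so it does not
reproduce the cross-feature correlations (size–perimeter, colour–ratio)
that image mode produces naturally — a known limitation: passing
classifier tests on table-mode data demonstrates the gate machinery, not
robustness to correlated real-world features.  Other features real data
has and the generator does not: out-of-focus frames, debris and multi-
particle frames, uneven illumination, and colony geometries beyond
disk unions.

Seasonal series draw per-(tank, date) class mixtures from a multinomial
over configurable date-varying weights (12 tanks, 13 dates); zeroing a
class's weight over a window produces the disappearance/re-appearance
pattern the abundance table must be able to represent.

## Problem sizes and statistical checks

The default study condition is 7 classes × 150 particles per class with
50-image training subsets; held-out evaluation therefore sees 100
particles per class.  The expected true-positive rate of a k-gate
min/max filter fitted on n training points is bounded by
`1 − 2k/(n+1)` for any continuous feature distribution (a new point
falls outside a sample range with probability `2/(n+1)` per feature), so
a 2-gate filter at n = 50 tops out near TPR ≈ 0.92 and balanced accuracy
≈ 0.96 even with perfect class separation.  Because one 100-particle
draw of that rate has ≈ 2.5 pp Monte-Carlo sd, the accuracy assertions
average over five replicate seasons (fixed seeds) at identical
conditions rather than widening any threshold.  Image-mode checks use
40–200 renderings per class, which keeps the full test suite within a
few minutes on one CPU.

## Known limitations

* Filter gates are descriptive (min/max envelopes), not optimised
  decision boundaries; accuracy is capped by the sample-range coverage
  effect above.
* The generator is calibrated to published gate ranges, not to measured
  colony geometry; morphology beyond those ranges is invented.
* Absolute values of signal features (intensity, edge gradient) depend
  on the grey/Sobel conventions documented here and are not comparable
  across instruments without re-calibration.
* The triage of colony remnants ("Membrane") and dispersed cells
  ("Undefined") is represented only as a label-exclusion rule in the
  abundance aggregation, not as an image classifier.
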