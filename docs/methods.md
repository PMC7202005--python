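# Methods

## The measurement model

A fixed Prometaphase I oocyte is represented as a single-channel confocal
stack (Z leading, 0-based, intensities in arbitrary units) with two
physical scales: the XY pixel size (default 0.054 µm, the standardized
confocal zoom of the protocol this package automates) and the Z section
thickness (default 0.5 µm — the protocol's source never states its step,
so a typical confocal value for whole-oocyte karyosomes is used and both
scales are configurable everywhere).

The protocol proceeds on the maximum-intensity projection:

1. **Background** — the median of the lowest-decile pixels. On an oocyte
   field chromosomes occupy a small fraction of the frame, so the bottom
   decile is essentially pure off-chromosome signal. When a stack is
   available the estimate is taken over stack voxels rather than the
   projection: the per-pixel maximum over many sections raises the floor
   of pure-background pixels (extreme-value shift ≈ 2σ for ~20 sections)
   but not of in-focus structure pixels, and a floor estimated from the
   projection would push every half-max contour inward.
2. **Segmentation** — connected components above
   `background + 0.25 × (max − background)`, then each component's member
   pixel set is re-cut at its *local* half-max
   (`background + 0.5 × (peak − background)`). The rationale: a symmetric
   blur leaves the half-maximum contour of an object at the object's true
   edge, so FWHM cutting recovers drawn areas and outer edges accurately
   and makes dim and bright structures comparable; the lower component
   threshold merely decides connectivity (an "out" dot's valley is below
   50% of its peak by definition, so out dots always separate). Otsu and
   absolute thresholds remain available as policies; Otsu's threshold
   depends on the background/foreground pixel ratio and biases blob
   sizes, which is why it is not the default. Blobs smaller than 25% of
   the largest blob's area are dot candidates.
3. **Out classification** — a line profile from the dot centroid to the
   main-mass centroid. The dot is *out* if some interior sample's
   background-subtracted intensity falls to ≤ 50% of the background-
   subtracted reference peak, where the reference is the lower of the two
   flanking maxima (a dip relative to the dimmer structure guarantees a
   dip relative to both); exactly 50% counts as out. Flanking maxima
   below 10% of the profile's global maximum are not considered peaks;
   profiles without two detectable peaks are unclassifiable and the
   oocyte is triaged abnormal. Note the rule's monotonicities: deepening
   the valley can only keep or create an "out" call, and *raising* the
   background does the same, because (valley−b)/(peak−b) is
   non-increasing in b.
4. **Geometry** — the XY separation is outer-edge to outer-edge: the
   farthest-apart pair of member pixels of the two dot blobs projected on
   their centroid–centroid line, plus one pixel per side of edge extent.
   The Z offset is the number of sections between the blobs' light-cone
   centers (the section maximizing summed intensity over the blob's
   footprint), and the 3D separation is `√(d² + z²)`. Area is pixel
   count × pixel size².
5. **Triage** — oocytes with both dots out on opposite sides, or one dot
   out and the other locatable, are distance-eligible; both dots on the
   same pole side, extra nonexchange chromosomes, and abnormal figures
   are excluded from distance but still count toward the proportion out.
   When only one dot segments as a separate blob, a partner merged with
   the main mass is sought as a displaced local intensity maximum within
   the mass component; its position is a one-pixel pseudo-blob, so
   one-out distances carry an approximate inner edge. A genuinely absent
   partner in a figure that happens to show such a maximum would be
   mislabeled — in practice such figures are triaged by eye, and the
   generator produces none.

The proportion out is the exact quotient of oocytes with any chromosome
out over all post-Prophase oocytes.

## The synthetic generator

Stacks emulate the geometry the protocol measures, not the optics that
produced it: a metaphase-plate-like mass (solid ellipsoid, projected area
8 µm² by default, elongated across the spindle axis) at the stack center,
and 0–2 dot foci (solid, Z-flattened superellipsoids) displaced along the
spindle axis, all convolved with an anisotropic Gaussian (σ 0.08 µm XY,
0.3 µm Z) and placed over a constant background (20) with peak intensity
200 and optional additive Gaussian noise. There is no PSF model, no
photon statistics, no multichannel content.

Ground truth follows the measurement convention: `true_separation_3d` is
the outer-edge XY distance combined with the whole-section Z offset, and
dot centers are placed at `d_xy − 2·r_dot − 1 px` apart so that the
protocol's outer-edge reading of a noiseless stack equals the requested
value. This mirrors the hybrid convention of the real protocol (edge-
based in XY, center-based in Z) and makes "parameter recovery" a
statement about the quantity actually reported. Configuration flags
(`both_same_side`, `extra_nonexchange`, `n_dots_out` ∈ {0,1,2}) exercise
every triage branch; not-out dots sit a sub-resolution gap off the mass
edge, which blurs into a shallow (<50%) dip — locatable but not out.

Identical parameters and seed give bit-identical stacks (single
`numpy.random.Generator`). Stacks are written as multi-page 16-bit
grayscale TIFF with the physical scales in JSON metadata.

The tabular sampler draws per-oocyte rows for a species: out flags are
Bernoulli(probability out); out rows carry a 3D distance (normal
truncated at 0, decomposed into XY and 0–4 whole sections of Z) and two
area draws (truncated normal). The published tables give no per-oocyte
variance, so the default spreads (distance SD 2 µm, area SD 0.15 µm²)
are free choices of plausible within-species scatter, not calibrated
values — tests against these defaults validate sampling machinery, not
biology.

What passing recovery tests shows: the implementation measures its own
stated conventions to sub-voxel accuracy under moderate noise. What it
does not show: robustness to real-micrograph nuisances (uneven
illumination, touching bystander nuclei, focal drift, non-Gaussian
detector noise, operator framing).

## Statistics

* **Species summaries** — mean distance over distance-eligible rows,
  proportion out over all rows, mean area over all measured dots; the
  survey targets (≥30 eligible oocytes, ≥20 areas) produce warnings, not
  errors.
* **Pairwise contrasts** — Δ = mean(polymorphic) − mean(monomorphic),
  reported at 2 significant figures. The t-test flavor is Welch
  (unequal variance), two-sided: per-species oocyte counts differ up to
  4-fold, and the `P < 2.2 × 10⁻¹⁶` floor in the published values is the
  default-R fingerprint consistent with Welch output. Published
  per-oocyte samples are not available, so with summary tables the
  published p-values can be supplied verbatim for the FDR step.
* **FDR** — ranks by ascending p (ties in stable input order), cutoff
  `(i/m)·Q` with `Q = 1/(2m)` by default (so `i/(2m²)`); the rule is
  step-up with strict inequality: the largest rank with `p < cutoff`
  and everything below it is significant. Note two published cutoffs
  (0.027, 0.041) are truncations of 2/72 = 0.0278 and 3/72 = 0.0417; the
  implementation reports exact values.
* **Group comparison** — unweighted means of species means per inversion
  group, Welch two-sided t on the species means. From the bundled
  (2-decimal) species means the monomorphic mean is 6.814 → 6.81, while
  the published 6.82 reflects unrounded means; all comparisons on
  bundled values therefore carry a ±0.02 input-rounding allowance.
* **Correlations** — Pearson r with the regression transform
  `t = r√(n−2)/√(1−r²)`, two-sided; missing values (no distance or area
  for the species without a free dot; five species without
  heterochromatin estimates) drop pairwise, giving the n = 9 and n = 14
  analyses. Pair-averaging replaces each close species pair by the
  midpoint of its two means (singletons kept), a blunt control for
  phylogenetic non-independence; no tree-based method is attempted.

## Numerical choices and limitations

* Distances are computed at full precision and rounded only for reports
  (2 decimals for distances, 2 significant figures for Δ).
* Overlapping blobs yield XY distance 0 with a warning; zero-variance
  correlation inputs and empty groups raise.
* Recovery test scale: 50 stacks of 16×192×192 voxels per condition —
  large enough that every separation in the surveyed range fits with
  margin, small enough to keep the suite quick; accuracy is limited by
  discretization (sub-pixel XY, whole-section Z), not stack size.
* Residual area bias ≈ −3% for the smallest dots comes from edge
  curvature under blur (the half-max contour of a blurred disk sits
  ≈ σ²/2r inside the true edge); it is left uncorrected as the same
  softness affects the manual protocol being emulated.
* The bundled species table is transcribed at its printed precision; one
  published row (D. virilis) prints a proportion inconsistent with its
  own counts (38/280 → 0.14 vs printed 0.15) and is kept as printed.
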