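# Methods

## Model of the measurement

`paindraw` treats a pain drawing as a pure raster annotation: the patient
drawing is the reference body map with chromatic pixels substituted where
the stylus passed. Under that model, pain extent is a set cardinality —
the painted in-body pixel set divided by the body pixel set — and every
operation in the pipeline is a set operation on boolean rasters. Three
assumptions are load-bearing:

- the drawing has exactly the reference's pixel dimensions (no resampling
  is ever performed, because resampling silently changes pixel counts);
- the reference uses only black outlines on white, with minimal
  antialiasing, so "background" is recognizable as near-white;
- the pen is neither black nor white, so "painted" is recognizable as
  chromatic difference from the reference.

## Body mask

Background is the set of pixels with all channels ≥ `255 − gray_tolerance`
that are 4-connected to the image border; body is the complement. Choices:

- **`gray_tolerance` = 10** (0–255 scale, configurable): absorbs residual
  gray tones of nominally non-antialiased artwork while keeping mid-grays
  out of the background.
- **4-connectivity** for the background fill: an 8-connected fill could
  leak diagonally through a 1-px outline; 4-connectivity cannot.
- **Outline pixels count as body.** The method reports a single whole-body
  area, and including the closed outline makes that area independent of
  stroke-thickness conventions. The convention is a genuine coin toss for
  any externally produced artwork; it is isolated in `build_body_mask`
  and documented here rather than hidden.
- **Front/back split** by component centroid against the vertical midline
  (overridable with an explicit `split_x`): the standard layout places
  the two figures side by side, and nothing in the raster labels them. A
  single centered figure degenerates to all-front with a logged warning
  rather than an error.

## Pen detection

A pixel is painted iff it differs from the reference pixel at the same
position *and* is chromatic: channel spread `max−min > value_window` (30)
or HSV saturation `> saturation_min` (0.15); pixels with max channel < 40
(near-black) or min channel > 215 (near-white) never count. The
difference-from-reference requirement exists because tablet apps blend
stroke edges: an antialiased fringe over a black outline can be mildly
chromatic, but if it equals the reference it was never drawn. All four
thresholds are configurable; the defaults accept every saturated stylus
color while rejecting black, white, and grays. The pen color reported for
the overlay is the modal painted RGB triple — when a patient used several
colors, one complement is still used for the whole overlay, keeping the
verification image two-toned.

Multi-color drawings are counted as a single painted set; the tool does
not attempt per-color separation.

## Gap filling ("smart" mode)

Binary hole filling on the full raster: every 4-connected unpainted
region that does not touch the image border is added, then the result is
re-clipped to the body. This is global (not per-stroke), order-independent,
monotone and idempotent. An open C-shaped stroke is *not* filled — its gap
connects to the border-reachable unpainted region — which matches the
intent of recovering only areas the patient fully enclosed.

## CS classification and cohort statistics

A drawing is CS-flagged when its ratio is strictly greater than the
user-supplied threshold ("over" the threshold); `cs_inclusive` switches to
≥ for users who read the boundary differently. There is deliberately no
default threshold: it is a clinical choice (published examples use 16%),
not a software constant.

Cohort statistics are computed on full-precision ratios; rounding to two
decimals (halves away from zero) happens only at export. Standard
deviations are sample SDs (n−1). A subgroup of size 0 has no mean, of
size < 2 no SD; both print as `n/a` rather than a fabricated 0.

The frequency ("probe") map accumulates per-pixel counts of how many
drawings painted each location. The footer summary `m/n` is interpreted
as *maximum per-pixel overlap count / subset size* — the only reading
consistent with a fully concordant subset printing `k/k` — and is
isolated in `freq_summary` so it can be swapped if a different convention
is ever preferred. The rendered probe grid tiles the raster into
`cell_px` (default 8) square cells, colors each cell's in-body pixels by
the cell *mean* count over `n_images` through a named matplotlib colormap
(default `viridis`, perceptually uniform), and leaves out-of-body pixels
showing the reference.

## Report dialect

Tab-separated row block (`#  Filename  Ratio (%)  CS`), then twelve fixed
footer lines (threshold, counts, means, SDs, frequency summaries). UTF-8,
LF line endings. Numbers are rounded to two decimals with trailing zeros
and a bare decimal point trimmed, so `18.5`, `21.2` and `12.71` coexist;
booleans print `True`/`False`. The parser reads the same dialect back
(`n/a` → undefined) and writing is a fixed point of parse-then-write,
which the tests exercise on random reports.

## Synthetic fixtures

The generator stands in for the hand-drawn reference artwork and for
patients; it emulates the properties the pipeline relies on, not anatomy:

- **Reference**: two genderless figures (elliptical head, rectangular
  neck/trunk/arms/legs) with closed 1-px black outlines on white, only
  pure black/white pixels (no antialiasing by construction). The right
  figure is the pixel-exact mirror of the left, so front and back areas
  are exactly equal — the same guarantee the real artwork advertises. The
  regional proportions loosely follow the Rule-of-Nines burn chart
  (exposed as metadata in `RULE_OF_NINES_GUIDE`), but no exact 9% areas
  are enforced: that is a property of artwork, not of an algorithm.
  Canvases must be at least 64×64 for the silhouettes to fit.
- **Drawings**: seeded breadth-first region growing paints exactly
  `round(target_fraction · N)` in-body pixels — connected, stroke-like
  blobs with an exact count, which is what makes ground-truth recovery
  testable to full floating-point precision. Optional leak pixels grow
  from the image corner (out-of-body by construction); optional hole
  rectangles are carved back to the reference and validated to be
  strictly enclosed by paint. The default pen (220, 30, 30) is checked
  against the detection rule at simulation time.
- **Cohorts**: per-drawing fractions come from a caller-supplied sampler;
  `stratified_fraction_sampler` produces a shuffled sequence with a
  prescribed number of above-threshold fractions, keeping both strata
  clear of the threshold so whole-pixel quantization cannot flip a
  classification.

What passing on synthetic data does **not** show: robustness to real
tablet-app export quirks (JPEG artifacts, heavy antialiasing, pressure
transparency), to drawings saved at the wrong resolution (rejected, by
design), or to artwork whose outlines are not closed. Those need real
images.

## Numerical and degenerate-input choices

- Ratios and statistics are IEEE doubles end to end; the only rounding is
  the export rule above (implemented with decimal arithmetic, since
  binary floats make "round half up" ambiguous otherwise).
- An empty painted set is a valid measurement (ratio 0), not an error;
  an empty body mask is an error everywhere (the denominator is
  undefined).
- Ties in the modal pen color resolve to the numerically smallest packed
  RGB value (deterministic).
- Problem sizes in the test suite and acceptance script (references of
  160×120 to 320×240, cohorts of up to 51, oracle sweeps on rasters up to
  32×32) were chosen so the full suite completes in seconds while still
  exercising multi-component masks, quantization, and every degenerate
  branch; all pipeline-recovery checks are exact, so size buys breadth,
  not tolerance.

## Known limitations

- Location and extent only: no pain intensity, depth, or quality is
  captured or encoded.
- The front/back split assumes a side-by-side two-figure layout.
- The frequency-summary convention (`max overlap / subset size`) is an
  interpretation; alternatives (e.g. count of pixels above a prevalence
  cut) would need a different `freq_summary`.
- No attempt is made to reproduce any specific published artwork or its
  exact pixel count; the mask convention is validated on synthetic
  references instead.
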