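# Methods

## Problem and overall model

Maize leaves reorient under crowding: in strongly rectangular sowing
patterns (wide rows, tight in-row spacing) a growing fraction of leaves
turns perpendicular to the row to reach the inter-row light gap.  In a nadir
RGB image of such a canopy the leaf midrib is a bright, elongated line on a
darker blade.  The package estimates the azimuth of every visible midrib and
analyses how the resulting orientation distributions vary with genotype (G),
environment/site (E) and sowing pattern (management, M).

The detection chain treats a midrib as a *bright ridge*: a curve along which
image intensity is locally maximal in the transverse direction.  For a
Gaussian-smoothed image f, the 2x2 Hessian

    H = [[f_xx, f_xy], [f_xy, f_yy]]

has signed-ascending eigenvalues lam1 <= lam2.  On a bright ridge lam1 is
strongly negative (downward curvature across the ridge) and lam2 is near
zero (flat along it).  Each ridge component is then reduced to its convex
hull and minimum-area enclosing rectangle; the rectangle's long side is the
midrib azimuth.  Because the smallest enclosing rectangle of a convex set
has a side collinear with a hull edge, scanning the hull edges (rotating
calipers) finds it exactly.  Averaging orientation over the whole rectangle
integrates along the full midrib length and tolerates mild blade twisting.

Orientations are axial (180-degree periodic).  Folding against the row
direction, `rel = min(d, 180 - d)` with `d = |azimuth - row| mod 180`,
maps every leaf into [0, 90]: 0 = parallel to the rows, 90 = perpendicular.

## Pipeline stages and parameters

1. **FOV crop** (`preprocess.crop_fov`).  Pinhole model: the retained
   half-width is `(W/2) tan(a) / tan(fov_h/2)` for a crop half-angle `a`
   (default 10 degrees) about nadir; similarly for height with the vertical
   FOV.  Keeping only the near-nadir cone prevents perspective from biasing
   apparent azimuths.  Defaults (70 x 50 degree FOV) describe a compact
   rigid-lens camera; the projection choice is recorded in provenance.
2. **Enhancement** (`preprocess.enhance`).  Default is a deterministic
   per-channel percentile stretch (2nd-98th percentile to full range);
   adaptive histogram equalisation of the luminance channel is available as
   `method="clahe"`.  A constant image is returned unchanged with a warning.
3. **Green segmentation** (`preprocess.segment_green`).  Excess-green index
   ExG = 2g - r - b on chromaticity-normalised channels, thresholded by
   Otsu's method with a small absolute floor (`min_exg`, default 0.05) so an
   image without vegetation yields an empty mask rather than an arbitrary
   split of the soil histogram.  Components under `min_area` (64 px) are
   dropped.  The mask is computed on the *unenhanced* image: chromaticity is
   exactly invariant to brightness there, whereas the per-channel stretch
   can saturate single channels and corrupt hue precisely on the brightest
   vegetation — the midribs.  The mask gates the ridge mask; it does not
   modify the grayscale input.
4. **Grayscale** (`preprocess.to_grayscale`): channel average rescaled to
   [0, 1].  Fixing this scale gives the eigenvalue threshold below a defined
   intensity unit.
5. **Ridge detection** (`ridge`).  Gaussian smoothing at scale `sigma`
   (reflective boundaries), second derivatives by central finite differences
   of the smoothed image (Gaussian-derivative kernels are a config switch),
   multiplied by `sigma^2` (scale normalisation, on by default) so responses
   are comparable across scales.  A pixel is classified ridge iff
   `lam1 <= -eig_threshold` (default 0.125), `|lam2| < 0.5 |lam1|`
   (anisotropy gate suppressing blob responses), and it lies in the green
   mask; 8-connected components under `min_component_px` (50) are removed.
   A fixed threshold is used rather than Otsu on the eigenvalue histogram,
   which is unstable under non-uniform illumination; a config switch exposes
   tile-wise Otsu for experimentation.
6. **Orientation** (`geometry`).  8-connected components -> monotone-chain
   convex hull (degenerate single-point and collinear components are
   flagged, not fatal) -> edge-scan minimum-area rectangle -> long-side
   angle in [0, 180) -> row-relative azimuth in [0, 90].
7. **Rectangle denoising** (`geometry.filter_rectangles`).  Hessian
   artifacts produce compact or extreme-area rectangles.  A record is kept
   iff aspect ratio >= 3 (zero width counts as infinitely elongated) and its
   log-area lies within the Tukey fence (1.5 IQR) of the per-image log-area
   distribution; with fewer than four rectangles the fence is skipped.
   Records are flagged, never deleted.  Square-ish components fail the
   aspect rule, so the long side of every kept rectangle is unambiguous.

### Choosing sigma

`sigma` is the only parameter that must track the data: it should match the
midrib half-width in pixels.  For field imagery at ~0.5 mm/pixel the
shipped stage lookup is 8 / 12 / 16 px at 220 / 430 / 650 growing degree
days (4-, 8-, 12-leaf stages), reflecting midrib widening with development.
The synthetic scenes below are rendered at reduced scale with ~3 px midribs,
for which the matched scale is `sigma = 2`; the classic scale-space property
(response of a line of half-width w peaks near `sigma = w`) is verified
empirically in the test suite.

The 0.125 threshold applies to sigma^2-normalised eigenvalues of a [0, 1]
grayscale image.  With that convention the peak normalised response of a
boxcar line of contrast c is ~0.48 c at matched scale, so the default
threshold fires on post-enhancement midrib contrasts above ~0.26 — the
regime the percentile stretch produces for visible midribs — while leaf
edges (one-sided responses of ~0.24 c_step) stay below it.

## Synthetic canopies

`synthetic.render_scene` draws each leaf as a lens-shaped polygon (width
profile `w(t) = (W/2) sin(pi t)` along the axis) in blade green over brown
soil (base colour + Gaussian-smoothed low-frequency mottling + per-pixel
speckle + a multiplicative horizontal illumination ramp), with a 3-px
midrib rectangle along the major axis at `midrib_gain` (default 1.4) times
the blade brightness.  Rendering is bit-deterministic given the scene seed.
Ground truth records every leaf's absolute and row-relative azimuth plus an
`occluded` flag (set when later leaves cover > 10% of its midrib pixels) so
recovery metrics can be restricted to visible midribs.

`synthetic.random_scene` places non-overlapping leaves by capsule rejection
sampling; azimuths follow a perpendicular-biased mixture: with probability
`perpendicular_fraction` (default 0.7 in the recovery experiments) a normal
around row + 90 degrees with sd 10 degrees, otherwise uniform on [0, 180).
This mimics canopies in which a fraction of leaves has reoriented across the
inter-row gap while the rest remain isotropic.

What the renderer does **not** emulate: 3-D architecture and perspective,
leaf curvature/inclination (blades are flat strips), specular soil or leaf
highlights, heavy mutual occlusion, wind blur.  Passing the synthetic
recovery tests therefore demonstrates correctness of the algorithmic chain
on its own assumptions (elongated green blades with brighter midribs),
not field-level accuracy, which depends on canopy structure and imaging
conditions the renderer abstracts away.

Problem sizes: recovery experiments use ten 768x768 scenes of 20 leaves
(~130 px long).  At this scale the whole simulate-detect-measure loop runs
in seconds, and detection achieves >= 90% recall with row-relative RMSE
well under 5 degrees and zero spurious kept components.

## Statistics layer

* **fp** — fraction of leaves with relative azimuth strictly above a
  threshold (60 degrees where field sampling is dense; 45 degrees for
  sparser annotation).  Ties at the threshold count as parallel
  (config-switchable); strictness matters only on exactly-binned data.
* **KS tests** — one-sample against Uniform(0, 90) (exact p for n <= 25,
  asymptotic Kolmogorov otherwise) and two-sample with asymptotic p.  The
  tests act on [0, 90] directly and ignore the circular nature of the
  underlying angles; a circular-uniformity test (e.g. Rayleigh on doubled
  angles) would weight departures differently and is out of scope.
* **AMMI** — `Y_ij = mu + G_i + R_j + sum_k lambda_k b_ik z_jk + eps_ij`,
  fitted on cell means: marginal deviations for the main effects, SVD of
  the double-centered residual for the multiplicative axes.  Degrees of
  freedom follow Gollob: `g + e - 1 - 2k` for axis k; the residual takes
  the remainder of `(g-1)(e-1)`.  Main effects are tested against the
  interaction mean square; each axis against the residual mean square after
  the retained axes — the convention consistent with the printed F ratios
  of two-way G x R tables in this literature.  Genotypes are conceptually a
  random sample, but the decomposition itself is fixed-effects; the caveat
  lives here, not in the estimator.  With balanced replicates, sums of
  squares are scaled to the observation level (cell-mean SS x r) and a
  pooled error row is appended; missing cells are an error (no imputation),
  and unbalanced replication is rejected.  Full-rank reconstruction returns
  the cell-mean table to machine precision, and `sum(lambda_k^2)` equals the
  interaction SS (x r under replication) — both are asserted in the tests.
* **RDPI** — `(1/n) sum |X_ij - X_i'j| / (X_ij + X_i'j)` over environment
  pairs, per genotype, on strictly positive phenotypes (here mean relative
  azimuth).  Defaults to all unordered pairs; `HEADLINE_PAIRS` provides the
  R1-R8 / R2-R8 contrasts.  Genotype-level means are used, not
  replicate-level pairs.
* **Validation metrics** — RMSE, squared Pearson correlation and its
  two-sided test p-value for paired estimated vs observed fp.

### Recovery test conditions

The AMMI recovery experiments plant a rank-1 interaction with
`lambda = 0.45` under cell noise sd 0.02 and 3 replicates (a 3-block field
design).  The choice is driven by an identifiability bound, not tuning: the
recovered interaction equals planted + double-centered noise with per-cell
sd `sigma * sqrt((g-1)(e-1)/(ge r))`, so the planted/recovered correlation
is ~ `RMS / sqrt(RMS^2 + sd^2)` for *any* estimator.  Requiring >= 0.99
correlation at sigma = 0.02 therefore needs a per-cell interaction RMS of
~7x the residual sd, which an unreplicated table of realistic fp magnitude
cannot supply; the replicated design with lambda = 0.45 sits comfortably
above the bound (predicted correlation ~0.996) while keeping all cells
inside (0, 1).

## Numerical choices and degenerate inputs

* Eigenvalues are computed in closed form for the symmetric 2x2 Hessian;
  ordering is by signed value (lam1 <= lam2), so "bright ridge" is always a
  condition on a negative lam1.
* `min_area_rect` scans all hull edges vectorised; for a 2-vertex
  (collinear) hull it returns a zero-width rectangle along the segment, and
  a single-point hull raises (no orientation exists).  Exact ties between
  edge orientations resolve to the first minimal edge — such clouds are
  square-ish and removed by the aspect filter anyway.
* Zero-area rectangles pass the aspect rule (infinite aspect) but fall
  outside any finite log-area fence when four or more rectangles are
  present.
* The fp threshold comparison is strict; `fraction_perpendicular` rejects
  empty samples and values outside [0, 90].
* Scene rendering draws leaves in list order; the occlusion flag is
  computed from the final ownership of midrib pixels.

## Known limitations

* Single-scale detection: one sigma per image.  Canopies mixing very
  different midrib widths would need multi-scale fusion.
* Overlapping midribs merge into one component; the rectangle then reports
  a mixture orientation.  The non-overlap guarantee in the synthetic
  recovery scenes isolates the orientation error of the geometric chain
  from the (real) occlusion problem.
* The green segmentation is a generic ExG + Otsu baseline; species- or
  sensor-specific indices can be swapped in via config.
* AMMI F tests are approximate under the fixed-effects convention; no
  mixed-model alternative is provided.
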