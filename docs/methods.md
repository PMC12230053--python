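# Methods

This note documents the models implemented in `leafshape`, the defaults and
their rationale, what the synthetic generator does and does not emulate, and
the numerical choices that affect results.

## Leaf-shape function

Relative blade width at relative tip distance *l* is
`w(l) = sin(π·l/(2a))^α` with shape factor α > 0 and ratio factor
0.5 < a ≤ 1. The argument is `π·l/(2a)` — not `π·l·a/2` or other readings a
typeset formula might suggest — because the function must attain its
maximum (w = 1) exactly at l = a, the defining property of the ratio
factor. With a > 0.5 the argument stays below π on l ∈ [0, 1], so w ≥ 0
everywhere and the blade closes to zero width at the base only in the
limit a → 0.5.

Fitting uses bounded trust-region least squares (`scipy.optimize.
least_squares`, method `trf`) inside the box α ∈ (0, 5], a ∈ (0.5, 1],
starting from the classical maize values (0.85, 0.70) and retrying from the
four box corners if the first start fails. The tip sample is never
force-weighted. Goodness of fit reports the adjusted R² of the ordinary
least-squares regression of observed on estimated widths with intercept
(equivalently the squared Pearson correlation; a zero-variance estimate
scores 0) together with the direct root-mean-square residual; n_params = 2.

## Leaf-area coefficient and width adjustment

`c` is the average of w over 100 equal steps at l = 0.01 … 1.00 (a
right-node Riemann sum; the trapezoidal rule and adaptive quadrature are
available as options and agree within 0.005 over the parameter range of
interest). For (α, a) = (0.85, 0.70), c = 0.7526 → 0.75. The width
adjustment `W_adj = L·(1/LWRatio)·(0.75/c)` makes blade area
`A = L·W_adj·c = 0.75·L²/LWRatio` an exact algebraic invariant across
shapes, which is what lets the canopy experiment isolate shape from area.
The coefficient also varies during leaf expansion; that expansion-dependent
form is not modelled here.

## Synthetic data

The generator emulates the belt-fed measurement setting: a flattened leaf
silhouette drawn from the shape family (the analytic width at every pixel
column is the ground truth), a leading round marker of known diameter
(2.47 cm) placed low in the frame so a bottom-to-top scan finds it first,
uniform gray background, and a constant belt speed. Frames are produced
lazily from a pre-composed world strip, so a 30 s/60 fps recording (1800
frames) never has to be materialized. Optional interior holes ("defects")
change the silhouette but never the outer-width ground truth; optional
Gaussian edge jitter and intensity noise are seeded per artifact.

Not emulated: perspective and lens distortion, specular highlights, texture,
uneven lighting, leaf overlap or curling, belt-speed jitter. Passing the
round-trip tests therefore demonstrates the correctness of the measurement
logic (stitching, calibration, contour widths) rather than robustness to
real-world imaging artifacts, which the configurable thresholds are meant to
absorb.

Weather series are constant or sinusoidal (tmin, tmax) day lists; the
simulation default is a constant 12/20 °C regime = 8 °Cd/day above the 8 °C
base, a plain mid-season rate under which all 17 leaf ranks have appeared
and essentially completed expansion by day 81.

## Camera method

Frame-to-frame displacement is estimated by zero-mean normalized
cross-correlation of per-column foreground counts (plain correlation
degenerates to the zero lag once a smooth, wide leaf fills the view). The
belt runs at constant speed, so the median of the per-pair estimates is
applied to every interval; this also bridges frames that show only
background, and signed displacements make reversed frame order transparent.
A known belt speed can override estimation.

Calibration divides the marker's area-equivalent diameter (sub-pixel
accurate for a rasterized disk, unlike a bounding box) by 2.47 cm; marker
candidates need circularity 4πA/P² ≥ 0.85 and the marker hue, scanning
bottom-to-top. Leaf segmentation is a hue/saturation threshold followed by
hole filling — the outer contour only, so fissures and pest damage never
change widths — with optional Gaussian blur and Canny edge detection as the
classical preprocessing path. Width per segment is the count of foreground
pixels along the perpendicular at the segment's center column (robust to
serrated edges), converted by the calibration metric; positions are
reported from the tip, which is auto-detected as the narrower end.

## Canopy simulation

Development: daily growing degree days `max(0, (tmin+tmax)/2 − 8)`
accumulate; leaf rank n appears when the sum reaches n × 30 °Cd (up to 17
ranks); organs then expand along `1/(1 + exp(−0.05·(t − 40)))` in thermal
age t, scaling length and width together.

Geometry: each blade is 100 parallelogram panels whose widths follow w at
the same nodes as the area coefficient, so mesh area is exactly
0.75·L²/LWRatio for every shape. Per-rank final lengths rise from 0.25 m
(rank 1) to 0.95 m (rank 12) and ease to 0.80 m (rank 17), LWRatio 10 —
a generic maize profile standing in for measured per-rank tables, and the
main fidelity gap for absolute comparisons. The midrib leaves the
insertion at 40° above horizontal and its inclination tapers linearly to
horizontal at the tip (a parabolic-like droop); successive leaves are
rotated 160°; internodes are absorbing cylinders (0.10 m × 0.01 m radius)
stacked into the stem. All plants are identical; 6 rows × 14 plants at
0.75 m × 0.15 m.

Radiation: hourly direct-sun directions for the site latitude (48.714°) on
day of year 180 from the standard declination/hour-angle formulas, weighted
by sin(elevation) and scaled to 0.8 of the total; a uniform-radiance
diffuse sky of 6 elevation rings × 12 azimuths (72 sources) carries the
remaining 0.2. Rays are launched from a horizontal rectangle covering the
planted footprint above the canopy — incoming radiation is the flux through
the stand's top plane; the surrounding field is dark. Side faces are open
(escaping rays are tallied), the soil absorbs fully, and summary statistics
use only the central 2 × 4 plants to keep border effects out.

Transport: at a leaf hit a ray reflects with probability 0.0923 or
transmits with 0.0127 (both Lambertian, cosine-sampled on the respective
side of the panel), else it is absorbed. Paths stop after the configured
reflection depth; a ray stopped by the cap goes to a separate "truncated"
tally rather than being counted absorbed, which keeps the energy balance
exact (absorbed + soil + escaped + truncated = emitted to float precision)
and absorbed energy monotone in depth. At the default optics the truncated
share is ~10⁻⁵ at depth 5. Intersection uses a median-split BVH over one
plant's panels plus per-instance AABB tests (plants are translated
instances); a brute-force path is kept and must produce identical tallies.

Canopy interception is the energy absorbed by the reporting plants' leaves
divided by the light incoming on their ground area (daily, all sources of
one day). For interior plants under oblique illumination this per-area
ratio can in principle exceed 1 (they absorb light that entered over their
neighbours); under the study sky it stays well inside [0, 1].

Desk-scale defaults are 2×10⁵ rays and reflection depth 5 per run, with
each grid cell run twice to estimate Monte-Carlo standard errors
(~0.01 on a cell, ~0.007 on the two-run mean); the reference setting of
2×10⁸ rays and depth 30 is reachable through the same configuration. The
6×6 grid spans α, a ∈ {0.5 … 1.0 step 0.1}; a = 0.5 sits on the open
model bound and is evaluated at 0.5 + 1e−9, closing the blade at the base.
The reported quantity is the day-81 daily interception fraction (a season
sum is a straightforward loop over days but is not the default).

## Design choices that were genuinely open

- Leaf pose (insertion angle, droop), per-rank length/LWRatio tables and
  internode dimensions are not biologically calibrated; they were fixed
  a priori at the values above and are configurable. Relative, shape-only
  comparisons are the intended use.
- Direct-beam hourly weighting ∝ sin(elevation) and uniform-radiance
  diffuse rings are conventional but not unique choices.
- One leading marker per recording; count and placement on the belt are a
  convention of the generator.
- Profile normalization divides by the maxima; a tie in the maximum is
  resolved by value, so it is deterministic.

## Known limitations

- The extended shape family with a second (beta) shape factor is not
  implemented.
- MP4 decoding/encoding is not part of the package; recordings are
  exchanged as PNG frame sequences or in-memory arrays.
- The vision pipeline assumes one leaf per recording and hue-separable
  leaf/marker/background classes.
- Absolute interception values depend on the stand-in architecture; only
  relative comparisons across shapes should be interpreted.
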