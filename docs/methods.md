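# Methods

## Display model

All photometry is grounded in a `DisplayCalibration`: luminances of the
three primaries at full drive (defaults 69, 197, 53 cd/m² — a measured
laptop panel whose R:G:B luminance ratio is close to the generic 3:6:1),
CIE xy chromaticities of the primaries (default ITU-R BT.709 / sRGB, since
the measured chromaticities of the original panel are not available), the
white point (D65) and the transfer function. The transfer is a *pure power
law* with exponent 2.2 by default; the piecewise sRGB curve is available via
`transfer="srgb"` but is not used anywhere in the analyses. The RGB→XYZ
matrix is built from the primary chromaticities scaled so that RGB (1,1,1)
maps to the white point with unit Y; L\*a\*b\* is computed against that
white. Note the two halves of the calibration are independent measurements:
the luminance vector is used for photometric quantities, the chromaticity
matrix for colorimetric ones, and they need not be mutually consistent.

Colours are exchanged as display-encoded triples in [0,1]³. The six cardinal
colours are the full-intensity chromatic corners of the cube, indexed
cyclically Y=0, G=1, C=2, B=3, M=4, R=5; fractional hue indices interpolate
the single channel that differs between flanking cardinals, linearly in
encoded coordinates (consistent with the "raw coordinates" spirit of the
cube distance).

## Transition structure

For an ordered cardinal pair, each RGB channel is classified as a
*transition* (ON↔OFF, with polarity = sign(right − left)), a *veil* (ON on
both sides) or *absent* (OFF on both sides). A channel dark on both sides is
deliberately not counted as a veil: veils are coloured light that washes
over the partition; absence contributes nothing. The transition count N_t ∈
{1,2,3} equals the colour-circle step distance; N_v ∈ {0,1,2}. Distinctiveness
is summarised by the linear model D = a0 + a_t·N_t + a_v·N_v with default
coefficients (0.406, 0.025, −0.083), and fitted by OLS with one row per
(normalised) response. An optional extended design adds per-channel
transition and per-veil-colour indicators; it is off by default because the
added structure is small relative to the response spread, and with it the
shared coefficients lose their clean interpretation.

## Stimulus synthesis

Dot locations are uniform in the union of the two squares. The Voronoi
tessellation is computed after reflecting the point set across all four
region edges, which makes every original cell bounded and exactly equal to
its clip against the region; the dot centre is the clipped cell's area
centroid, and its radius is the minimum centroid-to-vertex distance times a
common factor. The factor is found by bisection on the rasterised uncovered
fraction (overlaps counted once) to a tolerance of 0.02. Hard edges assign a
dot by the side of its centre; soft edges draw the side from a Bernoulli
whose P(right) ramps linearly across a boundary strip (designation only —
the colour statistics of a dot depend on its designated side, not on its
position).

Gamut samplers:

- *achromatic*: grey level ~ N(mean, 0.20²) on the full black–white scale,
  clipped (not re-drawn) to [0,1]. Clipping preserves the stated SD away
  from the bounds and is the simplest rule to document; at mid-grey the
  censoring at ±2.5σ shrinks the realised SD by under 2%.
- *monochromatic*: Ostwald coefficients (c, w, k), c + w + k = 1 exactly
  (the simplex is closed as k = 1 − c − w), sampled as three uniforms with
  the first multiplied by a skew factor of 4 and normalised — favouring
  saturated colour over weak tints and shades. Mixing is additive in linear
  light (the display adds light linearly); an encoded-domain option exists
  for ablation.
- *polychromatic*: hue drawn from a symmetric triangular density centred on
  the side's cardinal hue, extending one step along the colour circle each
  side (analogous colours), wrapped mod 6; the full colour for that hue is
  then tinted/shaded with the same CWK sampler.

Rendering paints hard disks in layout order with no overlap resolution
(the radius rule permits slight cell overspill); pixel coordinates are
0-based, top-left origin, half-open; a pixel belongs to a dot when its
centre lies within the radius. Everything is reproducible from the stimulus
spec's seed. Package defaults — 256 px squares, 1200 dots over both squares,
uncovered fraction 0.25, boundary width 0.2 of the square side, light-grey
(0.8) background — are plausible reconstructions chosen once; the original
layout table is not available, and all of them are configuration.

## Synthetic observers

The response datum is the Michelson contrast of an achromatic bipartition
set to match a chromatic one. A `GroundTruth` picks the latent model
(rgb_cube, luminance_contrast, ciede2000, colour_circle, or the linear
N_t/N_v model) and maps its raw pair values affinely into contrast;
`GroundTruth.calibrated` places the 15 values onto [0.32, 0.52], the band
typical of pooled settings from analogous to complementary pairs. Observer i
reports clip(offset_i + gain_i·latent + ε, 0, 1), ε ~ N(0, noise_sd²),
optionally quantised (step 0.10 mirrors the coarse adjustment control;
default off, since pooled settings are finer-grained).

Defaults: 5 observers, offsets ~ N(0, 0.02) re-centred to zero panel mean,
log-gains ~ N(0, 0.05) re-centred to zero (unit geometric mean), noise_sd
0.05, 4 conditions × 15 pairs × 4 replicates = 240 responses per observer.
The centring expresses that matching data cannot identify an absolute
offset or scale — only idiosyncrasies relative to the panel consensus — and
the spreads are modest because inter-observer concordance in this task is
high. Replicate count 4 is bookkeeping reconstruction: it reproduces the
240-per-observer session size, but the true repetition structure is a free
parameter. Response times, when emitted, are log-normal with median drawn
from 7–12 s and exist only for interface completeness.

What the generator does *not* emulate: sequential and adaptation effects,
learning across trials, lapses, any dependence of the latent value on the
edge type or gamut (conditions share one latent per pair), and the
dither-statistics sensitivity that makes real observers see "zero
distinctiveness" transitions. Passing tests therefore show that the
analysis chain recovers what it assumes — not that human data obey the
linear model.

## Analysis chain

Normalisation regresses each observer's responses on the cross-observer
median of the matching (condition, pair) cell — once, medians not
recomputed — and inverts the fitted line. Re-normalising is exactly the
identity for affine observers; with noise the anchor shifts slightly, and
errors-in-variables attenuation leaves re-fitted slopes a few percent below
one. Concordance is Kendall tau-b (ties are certain with quantised
settings) on per-observer cell medians, with entries masked at the
two-sided 5% level by the normal approximation. Pair summaries are
quartiles; array plots map off-diagonal values affinely onto the full grey
scale per panel (min→black, max→white, diagonal black). Model comparison
correlates per-pair medians with each model's predictions on the *nominal*
(undithered, full-intensity) cardinal colours — all candidate models see
only patch means — per condition and pooled; computing patch means from
rendered stimuli instead is available through the stimulus metadata.

The triangle-inequality Monte Carlo samples triples uniformly in the
encoded cube. The default count is the ordered-path reading: for a triple
(A, B, C), is the direct route longer than the detour, ΔE00(A,C) >
ΔE00(A,B) + ΔE00(B,C)? Under the default calibration this lands near 3.5%
of 100,000 triples (binomial SE ≈ 0.06 pp). The any-side count — some
side exceeds the sum of the other two — is roughly three times larger
(≈10.4%), since at most one side of a triangle can violate; both counts are
exposed, the path count being the one quoted as the headline rate.

## Numerical choices

- CIEDE2000 is implemented in full (lightness, chroma, hue and rotation
  terms, parametric factors kL = kC = kH = 1) and verified against the
  standard published verification pairs and an independent implementation
  to 1e-10.
- OLS fits use `numpy.linalg.lstsq`; rank-deficient designs (< 3 distinct
  (N_t, N_v) combinations) raise.
- Fill bisection runs on [0, 2] with 40 iterations and a 0.02 tolerance;
  an unreachable target raises rather than returning the boundary.
- 8-bit image quantisation rounds half to even; PNG/PPM round-trip
  bit-exactly.
- The hue-diameter tone mapping projects a pixel's position in the
  chromatic hexagon (the cube projected perpendicular to the grey axis)
  orthogonally onto the diameter through the chosen hue, mapping [−1, 1] to
  [0, 1]; off-diameter colours project orthogonally, and the accents choice
  flips the scale.

## Problem sizes

Test-suite simulations use 200 replicates for coefficient recovery and 100
for model identifiability; the Monte Carlo uses 100,000 triangles (seconds,
vectorised) and stimulus tests use 96–128 px squares with 120–300 dots.
These sizes give comfortable statistical margins for every asserted bound
while keeping the suite quick.

## Known limitations

Transition structure is defined only for cardinal endpoint pairs (no
white/black patches, no desaturated endpoints). The simulator does not
reproduce the live experiment's quarter-second left/right swapping or
interactive adjustment. No discrimination model is offered for
equal-mean ("zero distinctiveness") texture transitions, though the
simulator can generate them. The concordance breakdown by category is
reported but has no external reference values to compare against.
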