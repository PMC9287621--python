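# Methods

## The trajectory model

A retinal nerve fiber bundle leaving the optic nerve head (ONH) at an
initial angle φ₀ follows, in plain polar coordinates (r, φ) about the
ONH center,

    φ(φ₀, r) = φ₀ + b(φ₀) · (r − r₀)^{c(φ₀)}

with sector-specific auxiliary functions

    c_Sup(φ₀) = 1.9 + 1.4 tanh((φ₀ − 121) / 14)          60° ≤ φ₀ ≤ 180°
    c_Inf(φ₀) = 1.0 + 0.5 tanh((−φ₀ − 90) / 25)          −180° < φ₀ ≤ −60°
    b_Sup(φ₀) = exp(β_Sup + 3.9 tanh(−(φ₀ − 121) / 14))
    b_Inf(φ₀) = −exp(β_Inf + 1.5 tanh(−(−φ₀ − 90) / 25))

φ₀ is measured from the nasal horizontal ray of the ONH,
counterclockwise positive in the right-eye frame, so superior bundles
(b_Sup > 0) curl counterclockwise toward the temporal raphe and inferior
bundles (b_Inf < 0) curl clockwise.  The curvature-magnitude parameters
carry empirical ranges β_Sup ∈ [−2.5, −1.3] and β_Inf ∈ [0.1, 1.3] with
population means −1.90 and 0.70; `beta_grid` exposes each range as 11
evenly spaced values ordered from −1.3 (resp. 1.3).  Nasal bundles
(−60° < φ₀ < 60°) are approximated as straight rays perpendicular to the
circle b-scan — the full nasal extension of the original model is out of
scope.  Inferior initial angles are reported externally in [180°, 300°]
(so the overall φ₀ range reads 60°–300°) but computed internally in
(−180°, −60°], the branch the equations require.

### Mapping the model onto a scan

Trajectories are computed in a model frame (fovea at the origin, ONH
center at (15°, 2°), fovea–disc (FD) angle −7.59°) and mapped onto an
individual acquisition in four steps:

1. the path starts on the circle b-scan, r₀ = r_c (the recorded circle
   radius, default 6.0° ≈ 1.75 mm at 0.291 mm/deg), and is sampled
   outward in steps of `r_step_deg` (default 0.05°, sub-pixel for
   0.25°/px rasters) up to `r_max_deg` (default 25°);
2. all points are rotated about the fovea by the *relative FD angle*
   (recorded minus assumed), correcting head tilt / eye rotation;
3. the rotated assumed ONH is translated onto the recorded BMO center;
4. the path is truncated at its first crossing of the fovea-latitude
   line (rotated with the frame): the temporal raphe boundary where the
   crossing is temporal to the fovea, the FD line otherwise.  The
   crossing point itself is added by linear interpolation.  An optional
   fovea-centered clipping box can additionally truncate the outward
   tail; it is off by default because the disc sits at the nasal edge of
   the macula-centered raster, so the circle scan itself extends past a
   30°-wide box.

Rotation is applied about the fovea because the FD angle is defined
there.  Left-eye (OS) data are mirrored across the vertical axis into
the right-eye frame (x → −x, FD angle negated) before any modelling;
mirroring twice is the identity.

## Border extraction from probability maps

Probability maps are rasters of percentile categories
{normal, ≤5 %, ≤1 %, outside-field} over a 30° × 25° macula-centered
field (default 0.25°/px, 121 × 101 pixels; row 0 superior).  Extraction
of an arcuate defect's two border curves proceeds as:

1. **binarize** — ≤1 % → 1, everything else → 0;
2. **select** — keep one 8-connected component: the seeded one, or the
   largest whose angular extent about the BMO center exceeds 20°,
   preferring components that reach within 1.5° of the circle scan
   (arcuates emanate from the disc; detached fragments near the raphe
   are field-truncated continuations);
3. **perimeter** — keep pixels with a zero 4-neighbor (or on the raster
   edge); standard morphological perimeter;
4. **split** — convert perimeter pixels to polar about the BMO center
   and, per radial bin (width = the fitting quantization, 0.25°), assign
   the maximum-angle pixel to the *upper* border and the minimum-angle
   pixel to the *lower* border.

Where the original procedure relied on manual curation, the split
applies documented trimming rules instead; all of them remove outline
segments that are *boundaries of the measurement*, not of the defect:

- perimeter pixels on the raster edge, or adjacent to outside-field
  pixels (field truncation);
- pixels within 1.5 px of the rotated fovea-latitude line (raphe / FD
  termination);
- the first bin ring at the circle edge (the defect's start cap along
  the circle arc, where pixel quantization on a thin annulus is poor);
- bins whose two angular extremes lie within one pixel of each other
  (radial end caps, locally single-pixel-wide arcs);
- bins after the first radial gap wider than 4 bins (1°): the arcuate
  border is radially contiguous from the circle, so a large gap means
  the pattern left the scanned field and re-entered elsewhere.

An explicit region-of-interest mask can be intersected with the
binarized map to reproduce hand curation exactly.  Borders crossing the
temporal meridian are handled by unwrapping angles onto a
hemifield-specific branch (superior: (−90°, 270°]; inferior:
(−270°, 90°]).

## Normalized-RMS fitting

For one border and one β, candidate initial angles are scanned
exhaustively in 0.25° steps over 60°–180° (superior) or 180.25°–300°
(inferior; 180° itself belongs to the superior sector and −180° is
excluded by the open interval).  Border and trajectory are each reduced
to their mean angle per radial bin (bin k covers [k·w, (k+1)·w), w =
0.25°); over bins present in both, the RMS of the circular angular
difference (degrees) is minimized, ties going to the smaller φ₀.  The
angular metric is used rather than the Euclidean chord ≈ r·Δφ, which
would overweight peripheral bins; the binning keeps border and fit
geometry consistent.  Bins where the clipped trajectory has ended are
simply unmatched; the matched fraction of border bins is reported as
`coverage` and fits with coverage < 0.5 are flagged.

The 11 per-β minima of one border are normalized within the arcuate —
z-scores with the sample (n−1) standard deviation mapped through the
standard normal CDF to percentiles (all 50 when the spread is zero) — so
arcuates of different sizes pool; cohort summaries report the empirical
2.5th / 50th / 97.5th percentiles per β across arcuates
(linear-interpolation quantiles).  The normal-CDF percentile mapping is
a documented choice; the transform could equally use empirical ranks,
and percentiles are invariant to scale and shift of the RMS values
either way.

## Circumpapillary prediction

The circle scan is unwrapped into a TSNIT profile (temporal at 0°,
superior 90°, nasal 180°, inferior 270°; default 0.5°/position) with a
per-position normative Gaussian: a position is ≤1 % abnormal when its
thickness falls below mean + z(0.01)·SD, and ≤5 % analogously, so ≤1 %
positions are a subset of ≤5 % positions.  The two best-fit initial
angles of an arcuate's borders map to TSNIT positions (t = (180 − φ₀)
mod 360) and bound the trajectory-determined arc, taken within the
arcuate's hemifield (the complementary arc through the opposite
hemifield is anatomically meaningless).  The statistic is the fraction
of the arc's positions, equally weighted, abnormal at each level —
angular measure, not rendered plot area.  Clock-hour positions
(θ_c = ((90 − φ₀)/30) mod 12, superior = 12) are reported alongside for
clinical reading.

## Synthetic data

No public dataset of georeferenced probability maps exists, so the
generator builds eyes whose ground truth is known exactly: the ≤1 %
region is the band between two model trajectories (a chosen β and a φ₀
pair), rasterized by mapping each pixel into the model frame and testing
it against the two unclipped angle curves, the circle (r ≥ r_c) and the
raphe side condition — the defect is bounded only by the circle, the
raphe and the scanned field, as real arcuates are.  A two-pixel
dilation ring becomes the ≤5 % halo.  The matching cpRNFL profile uses a
smooth double-hump normative mean, m(t) = 50 + 45·exp(−((t−90)/45)²) +
50·exp(−((t−270)/45)²) µm with constant 10 µm SD, and depresses
thickness 3.5 SD below the mean over the leading designed fraction of
the trajectory-determined arc.

Noise is deliberately simple and fully seeded: independent ≤1 %↔normal
pixel flips, plus a smooth angular jitter of each border (Gaussian knots
at 7 radii, linearly interpolated, SD in degrees).  Analytic
(non-rasterized) borders — the bounding trajectories' own samples — are
exposed separately for exact-recovery experiments: against them the fit
recovers the generating (β, φ₀) with zero residual, whereas rasterized
borders are quantized to pixel centers, which biases single-border fits
by up to about two grid steps in β; recovery through the raster is
therefore a *cohort-level* property (the median normalized-RMS curve
attains its minimum at, or one grid step from, the generating β), which
matches how the method is used — one β for all eyes.  Default cohorts
draw the near-horizontal bound uniformly from 85°–110° off the nasal ray
(mirrored for the inferior retina) and widths of 25°–40°: mid-arcuate
defects well inside the scanned field.

What the generator does **not** emulate: OCT speckle, vessel shadows,
segmentation failures, spatially correlated normative variation, or
artifact arcuates of healthy eyes.  Passing tests therefore show the
pipeline's correctness and its behavior under pixel quantization and
smooth border perturbation — not robustness to instrument artifacts.

## Numerical choices and degenerate inputs

- Angles are stored in degrees; wrapped angles live in (−180°, 180°].
- β values outside the empirical ranges are rejected unless explicitly
  overridden (they are empirical, not mathematical, bounds).
- A trajectory whose start point lies exactly on the fovea-latitude
  line, or that clips to an empty polyline, raises a degenerate-result
  error; r_c ≥ r_max is rejected.
- Borders need ≥ 5 usable radial bins; a single-pixel-wide arc is
  degenerate by the end-cap rule.
- Zero RMS spread across the 11 β values maps to all-50 percentiles.
- Coincident upper/lower fits bound no circumpapillary region and raise.
- Problem sizes were chosen to keep the full validation desk-scale: the
  default test suite runs 25 analytic-recovery sweeps, a 20-eye jittered
  raster cohort, and a handful of raster fidelity checks in about two
  minutes on one CPU.

## Known limitations

- The original formulation defines its trajectories in a "modified"
  polar system whose definition this implementation does not reproduce;
  plain polar about the assumed ONH center is used, with r₀ = r_c
  constant around the circle.  Bit-level replication of the original
  model would require consulting its source definition.
- Single-eye, single-border β estimates from rasters carry the
  quantization bias described above; only cohort medians are unbiased in
  the tested conditions.
- No discrimination between glaucomatous arcuates and arcuate-like
  artifacts of healthy eyes is attempted.
- The clinical cohort statistics reported for the original 31-eye
  dataset (mean 68 % of the trajectory-determined arc below the ≤5 %
  threshold, 37 % below ≤1 %) require that undistributed dataset and are
  not reproduced here; the synthetic full-region fixtures verify the
  statistic's mechanics instead.
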