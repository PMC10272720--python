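# Methods

## The measurement model

The quantity estimated is the transit speed of a contrast bolus between
two positions on a vessel centerline, observed in a 2D cine angiography
sequence.  The signal model is deliberately minimal:

- Contrast arrival *decreases* image intensity.  The analysis never
  assumes a particular intensity scale or offset — every peak-based step
  is invariant under monotone affine intensity maps — only the polarity
  convention is fixed.
- The bolus arrives as a train of concentration peaks, one per cardiac
  cycle.  Each peak registers in the area-averaged TIC of an ROI as a
  relative minimum; the frame index of that minimum is the arrival time at
  the ROI, and the k-th peak at the proximal ROI corresponds to the k-th
  peak at the distal ROI.  Ordinal matching is valid because pulsation
  peaks are periodic and strictly ordered; no peak overtakes another.
- Velocity is arc distance over transit time,
  `v = Δx_mm / Δt_frames · fps`, computed per matched peak pair and
  summarized as mean ± population SD (SD = 0 with a single usable pair).

### Error budget

`Δt` is an integer frame count, so a single velocity estimate carries a
relative quantization uncertainty of about `1/(2Δt)`; halving the frame
rate doubles it.  This dominates every other error source at realistic
noise levels, which has two practical consequences: the ROIs should be
placed as far apart as the usable TIC signal allows, and reported per-peak
`Δt` values are logged so the quantization floor of any estimate is
auditable.  An optional parabolic sub-frame refinement of peak locations
exists (`subframe=True`) but is off by default: the standard estimate is
defined on frame counts, and sub-frame interpolation on noisy clinical
TICs can move peaks by more than it gains.

The ROI edge (20 px) trades noise suppression against temporal blurring:
averaging over the box widens each TIC dip by roughly the time the bolus
needs to cross the box, but does not shift a symmetric dip's minimum.

## Pipeline conventions

- **Segmentation** scores each pixel by its temporal intensity range
  (max − min over frames; alternatively temporal median − minimum), keeps
  pixels above a fraction (default 0.5) of the image-wide maximum score,
  and retains the largest connected component.
- **Centerline**: `skeletonize` thinning; branch spurs are removed by
  keeping the longest endpoint-to-endpoint geodesic (the analyzed carotid
  segment is unbranched, so side spurs are segmentation artifacts); points
  are ordered from a configurable inflow image border (default left).
  Row/col series are Savitzky–Golay smoothed (window 21 px, order 3 —
  large enough to suppress the pixel-lattice staircase that would inflate
  arc length, small enough not to shortcut curvature at these vessel
  scales).  Arc length is the cumulative polyline length of the smoothed
  points.  Skeletons of tubes retract by about one radius at each open
  end; site fractions refer to the extracted centerline, not the full
  anatomical vessel.
- **Diameter** is the full width at half contrast depth (FWHM) of an
  intensity profile sampled perpendicular to the centerline tangent on the
  frame of strongest contrast (lowest mean intensity), with linear
  sub-pixel interpolation at the half-depth crossings.  FWHM is the
  standard angiographic convention and is exactly testable on phantoms,
  where the rendered lumen edge places half depth at the configured
  radius.
- **Peak detection**: relative minima within ±`order` frames
  (default `round(fps/10)`, ≈ 0.1 s) with prominence at least 5% of the
  TIC dynamic range.  Both are configurable; the defaults are chosen so a
  physiological pulse train at 15–30 fps is resolved while single-frame
  noise spikes are not.
- **First-peak exclusion** is an explicit per-run flag (default off).  The
  first pulse of an injection can be too weak at the distal ROI to time
  reliably; whether to drop it is a per-case judgment, so it is recorded
  in the analysis config rather than automated.
- **Automatic ROI placement** scans candidate ROIs along the centerline:
  the proximal ROI is the first (from inflow) whose best peak prominence
  reaches 20% of the best candidate anywhere, the distal ROI the last
  still above 10% — i.e. the point where the TIC peak begins to fade.
  Manual index placement is always available and is what a careful
  analysis of clinical data should use.
- **Reports** round velocities to 0.1 mm/s and diameters to 1 µm, then
  derive retention and expansion from the rounded values, so every
  report is internally recomputable; each report embeds the resolved
  configuration and its hash.

## The phantom generator

The generator emulates exactly the statistical structure the analysis
relies on, with ground truth for every recoverable quantity:

- Intensity inside the rasterized vessel is
  `background − depth · C(s, t) · w(d) + noise`, where `C` is a sum of
  Gaussian pulses in arc length `s` advected at the configured velocity
  (`px/frame = v / (resolution · fps)`), and `w(d)` is a 1-px anti-aliased
  lateral profile whose half level sits exactly at the configured radius —
  making the FWHM diameter of the rendering equal the configured lumen
  width by construction.
- The pulse width is parameterized in *time* (`pulse_sigma_s`, default
  0.15 s): a bolus is injected over a duration, so its spatial length
  scales with velocity.  This keeps the temporal dip width at a fixed
  point (~4.5 frames at 30 fps) independent of speed, as in real TICs.
- Defaults model a carotid-like acquisition: 30 fps, 0.2 mm/px, a
  3.2 mm lumen, 300 mm/s bolus, three pulses at 0.8 s period (≈ 75 bpm),
  no noise unless requested.  A helically deformed vessel is rendered as
  its 2D sinusoidal projection, since the analysis operates on projected
  angiograms.
- Leading-edge spreading is a single linear dispersion rate
  (`dispersion_px_per_frame`); there is no flow-field, mixing, or X-ray
  physics simulation.
- `generate_paired_case` shares one path between a "before" and an
  "after" sequence, scaling the radius by separate proximal/middle
  multipliers (constant up to 35% of the arc, blended linearly to the
  middle value at 50%) and the velocity by a single factor.

What passing phantom tests does **not** show: robustness to heart-beat
motion of the vessel itself, mask-subtraction artifacts, overlapping
background anatomy, foreshortening of a truly 3D path, or contrast
recirculation.  Real sequences exhibit all of these; the phantom isolates
the transport signal the estimator is defined on.

## Validation design

- Worked-example arithmetic (retention from velocity pairs, expansion from
  diameter pairs, per-arm means) is checked against published reference
  tables at printed precision.
- Velocity recovery runs the *full* pipeline on a grid of phantoms
  (100–500 mm/s × {15, 30} fps at 0.2 mm/px).  ROI separation is set to
  six times the per-frame bolus advance, so the true transit is an
  integer ≥ 5 frames and the half-frame quantization band is well defined;
  noiseless runs must land inside the band at every grid point, and with
  noise at 5% of bolus depth at least 90% of seeded runs must.
- The peak-shift `Δt` is cross-checked against an independent brute-force
  oracle: the arg-max over all integer lags of the cross-correlation of
  the inverted, mean-subtracted TICs, on single-pulse phantoms whose ROI
  separation makes the true lag integral.
- Geometry accuracy is checked against phantom truth (centerline within
  1.5 px, FWHM within 1 px of the brute-force mask width) and closed
  forms (quarter-circle arc length within 2%).

Problem sizes: grid phantoms are 95 px tall and 260–1160 px wide with
54–104 frames; paired cases use 96 × 1024 px, 111–121 frames.  These sizes
keep the true transit at 6–17 frames, the regime where quantization
analysis is meaningful.

## Known limitations

- No sub-frame transit times: a bolus crossing the whole ROI span in
  under one frame is an error, not an estimate (the generator likewise
  refuses configurations whose bolus crosses the path in < 2 frames).
- Site matching between before/after acquisitions is by arc fraction on
  each sequence's own centerline; there is no image registration, so site
  correspondence inherits any difference in segmented extent.
- The DICOM reader derives fps from the frame-time attribute rounded to
  two decimals (then explicit overrides > frame time > cine rate);
  acquisitions with more exotic frame rates should pass an override.
- Diameters assume a roughly perpendicular, isolated vessel crossing; a
  second vessel inside the profile window would corrupt the half-depth
  search.
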