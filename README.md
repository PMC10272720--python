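# ticvelo

Time-intensity-curve (TIC) velocimetry for cine angiography.

When a contrast bolus passes through a vessel during digital subtraction
angiography (DSA), the image intensity inside the lumen transiently drops.
Tracking that drop at two points along the vessel converts an image
sequence into a blood-flow velocity estimate — a question that matters,
for example, when comparing how straight versus helical-centerline stents
change flow after femoropopliteal or carotid stenting. `ticvelo` implements
the full analysis chain for researchers working with such sequences:

1. **Segmentation** — vessel pixels are those whose intensity changes over
   time as contrast passes (`extract_vessel_mask`).
2. **Centerline** — morphological thinning, pruning to the longest
   endpoint-to-endpoint path, Savitzky–Golay smoothing, cumulative arc
   length (`extract_centerline`, `arc_distance`).
3. **TICs** — 20 × 20 px regions of interest (ROIs) on the centerline,
   averaged per frame to suppress noise (`place_rois`, `compute_tic`).
4. **Velocimetry** — contrast peaks are prominent relative minima of the
   TIC; the k-th proximal peak is matched to the k-th distal peak and each
   pair gives a velocity from the frame shift Δt and the centerline arc
   separation Δx:

   ```
   v (mm/s) = Δx(px) · resolution(mm/px) / Δt(frames) · fps(frame/s)
   ```

   The mean ± SD over peaks is reported (`detect_peaks`,
   `estimate_velocity`).
5. **Before/after comparison** — velocity retention ratio
   `100 · v_after / v_before` (%) and per-site diameter expansion
   `100 · (d_after − d_before)/d_before` (%), with diameters measured as
   the full width at half contrast depth of a perpendicular intensity
   profile (`measure_diameter`, `expansion_percent`, `retention_ratio`,
   `run_case`).

Because the frame shift is an integer number of frames, the velocity is
quantized: its relative uncertainty is about `1/(2Δt)`, which is why ROI
separation and frame rate matter more than image noise.

A synthetic phantom generator (`generate_phantom`, `generate_paired_case`)
renders sequences with a known bolus velocity, pulsatile peak train,
leading-edge dispersion and noise — including paired before/after cases
with configurable lumen expansion and velocity change — so every stage is
testable against ground truth.

## Worked example

`examples/04_before_after_case.py` builds a paired phantom whose "after"
sequence has a 1.185×/1.2× wider lumen (proximal/middle) and a 0.647×
slower bolus, then runs the full pipeline:

```
velocity before: 306.4 ± 0.0 mm/s (truth 309.4)
velocity after:  200.5 ± 0.0 mm/s (truth 200.2)
retention:       65.4% (truth 64.7%)
expansion proximal 3.20 -> 3.79 mm = 18.3%
expansion middle   3.20 -> 3.87 mm = 20.9%
```

The before-velocity is recovered within 1% (the residual is the integer
frame shift: the true transit here is 16.8 frames, measured as 17), the
retention ratio within 0.7 percentage points, and both expansion factors
within the pixel resolution of the FWHM measurement.  The other example
scripts show phantom generation, segmentation/centerline extraction, and
single-sequence velocimetry; each prints the quantities it computes and
what they mean.

A thin CLI mirrors the library for shell use:

```sh
ticvelo phantom scratch/demo --velocity 300 --noise-sd 40
ticvelo run-case scratch/demo scratch/demo --out scratch/out --case-id self
```

## Documentation

The model, its assumptions, parameter defaults, and known limitations are
described in [`docs/methods.md`](docs/methods.md).
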