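# octnad

Three-dimensional tumor-margin delineation from volumetric optical
coherence tomography (OCT), for researchers working with swept-source OCT
volumes of tissue specimens (e.g. glioma models) who need an intuitive,
depth-resolved picture of where tumor ends and normal tissue begins.

## The method

An OCT A-scan decays exponentially with depth,

    I(z) ∝ exp(−2 µ_t z),

where µ_t (mm⁻¹) is the tissue's optical attenuation coefficient (OAC)
and the factor 2 is the round trip of the probe light. Tumor tissue
attenuates more slowly than normal brain, so µ_t separates the two — but
the absolute OAC declines with depth (beam-geometry and sensitivity
effects), which defeats a fixed threshold. The pipeline therefore:

1. **Surface detection** — locate the sample surface per A-line as the
   position of the greatest axial variation of the log-compressed signal,
   then re-index every A-line to depth-below-surface ("flattening").
2. **OAC mapping** — at each depth, average ~20 neighbouring A-lines per
   B-scan (default width 21, log-domain/geometric mean) to suppress
   speckle, then fit an ordinary-least-squares line to ln I over a
   40-pixel (375 µm) window; µ_t = −slope/2. One fit per A-line gives an
   en-face OAC map in mm⁻¹.
3. **Normalization** — min–max normalize each depth's map against a fixed
   tumor region of interest (ROI):
   `NOAC = (OAC − min_ROI) / (max_ROI − min_ROI)`, so the tumor spans
   [0, 1] at every depth regardless of depth-wise OAC loss.
4. **NAD mapping** — Gaussian low-pass in x and y, then nearest-neighbour
   differences ΔNOAC_x and ΔNOAC_y, combined pointwise as
   `NAD = sqrt(ΔNOAC_x² + ΔNOAC_y²)`. NAD is large exactly where
   attenuation changes abruptly — at tissue boundaries. Stacking NAD maps
   over depth yields a volumetric margin map.

A synthetic phantom module (Beer–Lambert forward model, region-dependent
attenuation, unit-mean exponential speckle, analytic ground truth) makes
every stage testable end to end.

Array convention: volumes are indexed `(z, x, y)` with z = 0 the
shallowest sample, x = A-lines within a B-scan, y = B-scan frames;
spacings are stored in micrometres, in tissue.

## Worked example

Simulate a tumor-like phantom (low-attenuation ellipsoid, µ = 1 mm⁻¹, in
a 2 mm⁻¹ background with a thin 4 mm⁻¹ band, speckle on), then run the
full pipeline with a tumor ROI and three evaluation depths:

```
$ octnad simulate --preset glioma --seed 7 --out phantom.tiff
INFO wrote glioma volume (160, 96, 96) to phantom.tiff

$ octnad run --input phantom.tiff --roi 30,33,50,53 \
             --depth 405 --depth 450 --depth 495 --out nad_out
INFO surface: 100.0% A-lines valid, median index 17
INFO depth 403 µm: roi min/max 0.4991/1.5683 mm^-1, masked 0.0%
INFO depth 450 µm: roi min/max 0.5839/1.5390 mm^-1, masked 0.0%
INFO depth 497 µm: roi min/max 0.4305/1.6494 mm^-1, masked 0.0%
INFO wrote 3 NAD maps to nad_out
```

Reading the log: the surface was found on every A-line (median 17 axial
pixels ≈ 160 µm, matching the phantom's surface). Requested depths are
rounded to the 9.375 µm axial grid (405 → 403 µm). The per-depth ROI
min/max are the normalization constants in mm⁻¹ — the ROI straddles
speckle-perturbed tumor values around the true 1 mm⁻¹. `nad_out/`
contains one lossless CSV plus a PNG render per depth
(`nad_0403um.csv`, ...), the detected surface, and `provenance.json`
with the config hash and normalization constants. In the NAD maps the
high-NAD ridge traces the tumor boundary, and its radius shrinks with
depth as the ellipsoid narrows.

The same stages are available as a library:

```python
import octnad as on

spec = on.glioma_preset(seed=7)
vol = on.render_volume(spec)
flat = on.flatten(vol, on.detect_surface(vol))
stack = on.nad_volume(flat, on.EnfaceROI(x0=30, x1=50, y0=33, y1=53),
                      [405.0, 450.0, 495.0])
```

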