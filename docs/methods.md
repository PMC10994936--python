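# Methods

## Signal model

The pipeline assumes single-scattering Beer–Lambert decay of the OCT
intensity along each A-line below the sample surface:

    I(z) = I₀ · exp(−2 ∫₀^z µ_t(z') dz'),

with µ_t the total attenuation coefficient (mm⁻¹) and the factor 2 the
round-trip path. Taking the natural log turns estimation of µ_t into a
slope problem: over a window in which µ_t is constant, ln I is linear in
depth with slope −2µ_t. The estimator is the ordinary-least-squares slope
over a short axial window; the single-point inversion
µ_t = −ln I(z)/(2z) is provided (`pointwise_oac`) for comparison only —
it is offset-sensitive and far noisier under speckle, so the windowed fit
is what the pipeline uses.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| `fit_window_px` | 40 | axial px | 375 µm at the 9.375 µm axial grid; short enough to resolve depth structure, long enough to average ~40 speckle realizations in the fit |
| `lateral_avg_width` | 21 | A-lines | speckle suppression within a B-scan; 21 is the nearest odd width to the 20-line protocol so the window has a centre and maps stay registered (set 20 for the literal left-biased variant) |
| `lowpass_sigma_px` | 2.0 | en-face px | Gaussian; removes residual pixel-scale NOAC fluctuation before differencing without displacing boundaries (the kernel is symmetric) |
| `axial_presmooth_px` | 3 | axial px | boxcar on the log profile before surface differencing |
| `refractive_index` | 1.0 | — | divisor applied to sidecar (air-path) axial spacing at load; set to the tissue index when the acquisition reports optical path |

Axial spacing is a deliberate input rather than a constant: acquisition
metadata can report optical or geometric path, so `dz` is stored
in-tissue and all depths are geometric micrometres below the detected
surface. The 40-pixel window is anchored at the nominal depth (the window
*starts* there, it is not centred), and the realized, grid-rounded start
depth is recorded on every map.

## Surface detection

The surface index per A-line is the argmax of the first forward
difference of the smoothed log-compressed profile, ties broken by the
shallowest index (the physical surface is the first large rise).
Intensities are normalized by the volume mean before `log1p`; since the
mean is scale-equivariant, detection is exactly invariant to a global
positive rescaling of the data, and unlike a max-normalization the
compression still dampens bright speckle outliers. Per-A-line detection
alone is unreliable under fully developed speckle — the surface step
competes with speckle differences of the same magnitude — so the detector
also smooths the log profile laterally (3×3 boxcar by default), the same
neighbour-averaging idea the OAC stage uses; with it, detection on
speckled flat phantoms is within ±1 pixel everywhere. An A-line is
declared invalid when its best difference is below 5× its own median
absolute axial difference (a scale-free prominence test); invalid A-lines
are masked, never interpolated. A 3×3 median filter regularizes the
height map. Flattening shifts each A-line so its surface sits at index 0,
padding with NaN — a pure permutation-with-padding, no resampling.

## Lateral averaging domain

A-lines are averaged in the **log domain** (a geometric mean, i.e.
averaging the log-scaled B-scan image). Two reasons. First, under
multiplicative speckle `I = s·X` the log separates into `ln s + ln X`,
so the speckle term contributes a constant offset (mean ≈ −γ for
unit-mean exponential X) that cancels in the slope — the OAC estimate is
unbiased without any correction. Second, at an inclusion boundary the
geometric mean mixes the *slopes* of neighbouring A-lines linearly, so
the OAC transition stays centred on the true edge; an arithmetic mean of
intensities is instead dominated at depth by the brighter
(low-attenuation) side as soon as the window touches it, dragging the
apparent boundary outward by up to half the averaging window (measured
≈ 7 px on a noiseless cylinder phantom before this choice).

Windows that overrun an A-line's contiguous valid run (the NaN tail left
by flattening) are masked outright; interior gaps (non-positive samples,
which have no logarithm) are merely excluded from the fit, which needs at
least 3 valid samples. Negative fitted OACs occur under speckle and are
retained — clipping would bias the downstream min–max normalization —
but their fraction is logged per map as a QC figure.

## Normalization and NAD

Each depth's OAC map is normalized against one fixed en-face ROI placed
in the tumor: `NOAC = (OAC − min_ROI)/(max_ROI − min_ROI)`. Within the
ROI the unmasked values span exactly [0, 1] at every depth; outside the
ROI values may leave that range and are **not clipped** — clipping would
erase the gradients at bright normal structures (e.g. a white-matter
band) that the difference map should highlight. A degenerate ROI
(min = max, or fewer than 4 unmasked pixels) is a hard error. The ROI is
an explicit input: no automatic placement is attempted.

Low-pass filtering is a separable Gaussian applied after normalization
(the two orders are equivalent up to the affine map since no clipping is
done); masked pixels are excluded via normalized convolution and stay
masked. The directional differences
`ΔNOAC_x(i,j) = NOAC(i+1,j) − NOAC(i,j)` (and analogously in y) live on
staggered half-pixel grids; NAD is assembled on the shared
(nx−1)×(ny−1) corner grid by pairing Δx(i,j) with Δy(i,j), so NAD pixel
(i,j) sits at en-face position (i+½, j+½) — the ridge-extraction code
accounts for this half-pixel offset. `NAD = sqrt(Δx² + Δy²)` is
non-negative and zero only where both differences vanish. NAD highlights
*all* attenuation discontinuities, tumor or not; it is a contrast map,
not a classifier.

The volumetric stack evaluates every window-start depth from the surface
down to the last depth where at least half the map is unmasked (or an
explicit depth list), recording the normalization constants and a config
hash per run. `extract_boundary` (quantile threshold or per-ray ridge
argmax from a seed point) is a convenience for downstream consumers, not
a validated segmentation; the ridge radius estimate uses the median over
rays, which is robust to single rays locking onto residual speckle blobs.

## The phantom generator

Phantoms emulate the structure of a sectioned-specimen SS-OCT volume: a
smooth surface (constant, tilted plane or Gaussian bump), a homogeneous
background attenuation of 2 mm⁻¹ (brain-like), inclusions with their own
µ_t — an ellipsoidal low-µ "tumor" (1 mm⁻¹, so it attenuates more
slowly), a thin high-µ slab emulating a white-matter band (4 mm⁻¹), or a
cylinder for constant-radius oracles — and noise. Inclusions are placed
at depths measured from the local surface, so en-face cross sections at
constant depth-below-surface match the analytic geometry
(`radius(d) = a·sqrt(1 − ((d − z_c)/c)²)` for an ellipsoid). The optical
path is an exact per-voxel cumulative sum with the current voxel
excluded, so the first in-tissue voxel carries I₀ and a windowed OLS fit
recovers µ_t to machine precision on noiseless homogeneous segments.

Speckle is modelled as independent per-voxel multiplicative unit-mean
exponential factors — fully developed speckle after square-law
detection — plus an optional additive exponential noise floor. Real OCT
speckle is spatially correlated at the PSF scale and the instrument adds
confocal/sensitivity roll-off with depth; neither is modelled (roll-off
is left as a forward-model hook), so passing tests demonstrate the
pipeline's correctness under the stated model, not calibrated performance
on instrument data. No noise magnitudes are published for the motivating
system; the defaults were chosen once for test stability.

Default grids are kept small (96³–200×160² voxels, dz = 9.375 µm so a
40-pixel window spans 375 µm; lateral pitch 20–40 µm) — large enough
that the fit window, the averaging window and the inclusions coexist
with margin, small enough that the full suite runs in seconds. The
ellipsoid preset is sized so the boundary radius shrinks by several
lateral pixels per 100 µm of depth over its lower hemisphere, well above
the ridge-localization noise.

## Numerical choices and degenerate inputs

- NaN is the single missing-value marker end to end; linear-domain
  volumes are otherwise non-negative.
- Depth-to-index conversion rounds to nearest; realized depths are
  recorded.
- The OLS fit is the closed-form masked slope (no iterative solver);
  windows with a zero-variance depth axis return NaN.
- `lateral_average` truncates its window at B-scan edges (mean over
  available neighbours) and excludes NaN; even widths lean left.
- Surface detection on a featureless (constant) volume raises a
  detection error rather than returning arbitrary indices; flattening
  refuses a surface map that is invalid on more than half the A-lines.
- Determinism: all randomness flows through one `numpy` generator seeded
  from the phantom spec; identical seeds reproduce volumes bit-for-bit,
  and the CLI writes CSVs with full precision (`%.17g`) so repeated runs
  are byte-identical.

## Known limitations

- Single-scattering model only; no depth-resolved (cumulative) OAC
  estimators, no confocal-function correction.
- The NAD ridge localizes boundaries to roughly the low-pass filter's
  support; sub-pixel accuracy is not attempted.
- The ROI must be supplied by the user; a poorly placed ROI (e.g. in
  homogeneous background) degrades the normalization and may be
  degenerate.
- En-face maps assume isotropic lateral spacing for ridge radii.
- Performance is adequate for volumes up to a few hundred voxels per
  axis; the per-B-scan averaging loop is the main cost at full
  acquisition scale (500×500 A-lines).
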