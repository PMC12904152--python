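# Methods

## Measurement model

Optical palpation treats a compliant reference layer as an optical stress
sensor. The pipeline assumes:

- the applied stress is uniaxial, uniform in depth, and equal in the layer
  and the tissue (`σ = E₁ε₁ = E₂ε₂`);
- layer and tissue are each homogeneous along the compression axis, so the
  stack behaves as two linear springs in series;
- preload and compressed volumes are laterally registered (the stage moves
  only axially); no image registration is performed;
- friction between glass, layer, and tissue is negligible.

Layer thickness is measured per A-scan as the pixel distance between the
two highest local intensity maxima whose prominence exceeds a configurable
fraction of the A-scan's intensity range (default 0.05) — the Fresnel
reflections bounding the layer. Peaks are localized at integer pixels, so
a single thickness measurement is quantized to the depth pixel size `dz`
(3.50 µm by default); the strain of a ~600 µm layer therefore carries a
per-pixel quantization error of at most `2·dz/L₀ ≈ 0.012`. Equal-height
maxima are disambiguated by higher prominence, then smaller depth, so
degenerate profiles resolve deterministically. Sub-pixel refinement is
deliberately not applied: downstream smoothing addresses quantization
explicitly, and integer peaks keep the thickness estimator unbiased and
easy to reason about.

The preload state — "firm contact established" — is operationalized on the
volume-mean thickness curve as the earliest increment whose thickness drops
by at least `min_drop_um` (default 20 µm) to the next increment and whose
four-point linear fit (that increment plus three) has negative slope and
R² ≥ 0.95. The compressed state is fixed at three increments (300 µm of
stage travel) past the preload. Strain uses per-pixel thicknesses at those
two increments; negative per-pixel strains (apparent thickening, from
noise) are retained in the strain map but flagged, and are excluded from
stress lookup — silently clamping them to zero would bias mean stress
upward.

## Calibration

Stress on the calibration disk is force divided by the area computed from
the per-increment measured compressed diameter (a fixed-initial-area
variant exists behind `use_initial_area` for sensitivity checks); strain is
thickness change relative to the first increment. Replicates are aligned by
increment index (stage steps are uniform), truncated to the shortest with a
warning, and averaged pointwise. The modulus is the slope of an ordinary
least-squares fit over points with ε ≤ `linear_region_max_strain` (default
0.25) with a **free intercept**: contact offsets shift the curve, and only
the slope is mechanical. Strain-to-stress lookup uses `σ = E₁ε` inside the
linear region and piecewise-linear interpolation of the measured curve
above it; strains beyond the calibrated range raise rather than
extrapolate.

## Stress-map smoothing

1. Masked Gaussian blur, σ = 3 pixels, as normalized convolution: invalid
   pixels contribute no weight and stay invalid. Constant maps pass
   through unchanged to numerical precision.
2. Adaptive Fourier band-stop for the depth-quantization stripe artifact.
   The strongest non-DC bin of the 2D power spectrum is treated as a
   stripe only when it exceeds `peak_factor` (default 50) times the median
   power of its own radial annulus (±10%) and that annulus holds at least
   8 bins. Comparing against the annulus rather than the global spectrum
   is essential: a global-median rule flags the low-frequency energy of
   genuine structure (e.g. a stiff inclusion) as the dominant "peak" and
   the notch then erases the very contrast the method exists to measure,
   while a stripe concentrates power in one or two bins of an otherwise
   quiet annulus. When a peak qualifies, an annulus of relative width ±10%
   around its radial frequency is zeroed; otherwise the step is a no-op.
3. The valid mask never grows: in-painting (mean fill) is used only to
   give the FFT a complete field, and invalid pixels are restored to NaN.

Mean stress per field of view is the arithmetic mean of the smoothed map
over valid pixels. Group summaries report, per diagnosis label, the mean
and population SD of per-FOV means; labeling each FOV with its sample's
most severe diagnosis is the caller's responsibility.

## The phantom generator

The generator emulates the statistical and mechanical structure the
analysis assumes, not the physics of OCT:

- **Mechanics.** Two linear springs in series sharing one stress. Stage
  displacement beyond the dead zone partitions as
  `δ₁ = d·(L₀/E₁)/(L₀/E₁ + H/E₂)` per lateral pixel. The first `k` stage
  increments transmit zero stress (dead zone, switching abruptly): the
  simplest model reproducing the flat-then-linear thickness curve seen in
  practice, attributable to incomplete contact or interfacial fluid. An
  optional sub-pixel thickness jitter (≤ 1 depth pixel) mimics fluid at
  the interface during the dead zone.
- **Rendering.** Bright peaks at the glass/layer and layer/tissue
  interfaces (amplitudes 6 and 5 on a 0.12 baseline), tissue below the
  layer as an exponentially attenuating mean profile (default
  0.002 µm⁻¹, i.e. 2 mm⁻¹, typical of soft tissue) with multiplicative
  exponential-intensity speckle — first-order fully developed coherent
  speckle at the default contrast of 1 — plus additive Gaussian detector
  noise (sd 0.02). Intensity units are arbitrary (the real system's
  dynamic range is not modeled). Peak amplitudes are set so interface
  peaks exceed the 99.9th percentile of speckle excursions; with mean
  tissue amplitude 0.35, the probability that a speckle sample outshines
  the dimmer interface peak is ~e⁻¹⁴ per pixel, keeping peak detection
  reliable. Tissue is rendered to the bottom of the volume; internal
  tissue architecture (pit structure, layering) is not modeled.
- **Calibration runs.** The bare-layer (no tissue) limit: thickness
  decreases by one stage step per increment, stress follows `E₁ε` with
  quadratic stiffening above `nonlinear_strain_onset` (default 0.25,
  coefficient 300 kPa — any smooth convex stiffening law serves, as only
  the linear region is fitted), the compressed diameter grows to conserve
  disk volume, forces get multiplicative noise, and the series stops
  before the first force exceeding the 4.5 N sensor range. The default
  calibration slab is 1.5 mm thick — thicker than the 600 µm imaging
  layer — so that fixed 100 µm stage steps sample the low-strain region
  with at least four points, which the three-point fit requirement makes
  necessary; a 600 µm slab at 100 µm steps would place only two points at
  ε ≤ 0.25.

What passing tests on phantoms do **not** show about real data: robustness
to lateral tissue motion, friction and lateral stress coupling, layer
curvature over uneven samples, vendor-format quirks, or OCT artifacts
beyond simple bright glare (which the QC artifact flag covers). The
phantom's speckle is spatially uncorrelated, which is harsher on peak
detection than real speckle of finite coherence length but does not probe
structured clutter such as multiple reflections.

## Defaults and units

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| `dz` | 3.50 | µm | depth sampling of the emulated system |
| `dx`, `dy` | 13.67 | µm | lateral sampling of the elastography FOV |
| `L0` | 600 | µm | reference-layer thickness |
| `E1` | 49 | kPa | calibrated modulus of the 1:10:40 PDMS formulation |
| `stage_step` | 100 | µm | stage increment |
| `prominence_tol` | 0.05 | fraction of A-scan range | excludes non-border maxima; the exact field value is unpublished, so it is exposed in config |
| `min_drop_um` | 20 | µm | "distinct" decrease = several depth pixels |
| `linearity_r2` | 0.95 | — | "linear" decrease over four increments |
| `linear_region_max_strain` | 0.25 | — | end of the visually linear calibration regime |
| `blur_sigma_px` | 3 | px | stress-map Gaussian blur |
| `edge_margin_um` | 1000 | µm | exclude sample edges |
| `max_height_variation` | 0.14 | — | surface flatness bound |

Lengths are µm everywhere in configs, forces N, stresses kPa.

## Problem sizes

Validation runs use phantoms between 12×12×224 and 128×128×512 voxels with
5–9 increments; these sizes put every quantity of interest (quantization
bounds, inclusion contrast, preload recovery rates) well past its
asymptotic behavior while keeping the whole suite interactive. The strain
quantization bound is checked at 128×128 A-scans, where the per-pixel
bound is exercised 16k times per volume; inclusion-contrast recovery uses
20 independent seeds at 48×48 with a 14-pixel-radius disk, excluding a
6-pixel boundary band (twice the blur sd) from region means so the
deliberate smoothing at the inclusion edge is not misread as contrast
loss.

## Known limitations

- No viscoelasticity, friction, or finite-element mechanics; stress bleed
  between adjacent stiff/soft regions is absent from both generator and
  model, so real inclusion contrast will be somewhat blurred relative to
  the two-spring prediction.
- The linear-to-interpolated transition of the strain→stress lookup is
  continuous only insofar as the measured curve passes near `E₁ε` at the
  region boundary.
- Preload detection operates on the volume-mean thickness curve (matching
  how the thickness-versus-displacement data are inspected in practice)
  and can mislocate the dead-zone end by one increment when per-step
  thickness drops are near `min_drop_um`.
- The QC thresholds (flatness, edge margin, artifact brightness) are
  configurable stand-ins for qualitative visual assessment.
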