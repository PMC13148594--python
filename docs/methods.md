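# Methods

## Scope and model

`scansaxs` analyses fast-scanning SAXS data: a focused X-ray beam is
raster-scanned over a sample (here: adherent cells), recording one 2-D
detector frame per scan point. Each frame is reduced to real-space maps
of reciprocal-space quantities. The analysis assumes

- elastic small-angle scattering: per-pixel scattering-vector magnitude
  `q = (4π/λ) sin(½ arctan(r/L))` with r the radial distance of the
  pixel from the beam center and L the sample–detector distance. The
  exact form is used rather than the small-angle expansion because
  detector corners can reach 2θ of several degrees; the two agree to
  better than 2×10⁻⁴ below 2θ = 2°.
- point symmetry of the patterns about the beam center, which licenses
  filling beamstop-adjacent masked pixels from their point reflections
  (nearest-integer rounding of `2·center − p`; valid pixels are never
  overwritten; pixels masked on both sides stay masked).
- axial (π-periodic) azimuthal statistics: fibrous structures scatter
  perpendicular to their long axis and the pattern is point-symmetric,
  so orientation is a direction modulo 180°. All circular statistics
  double the azimuth; the resultant length R of the doubled angles is
  reported as the anisotropy and 1 − R is the circular variance.

## Pipeline stages and parameters

**Dark-field images.** Value at a scan point = sum of counts over the
annulus [q_lo, q_hi) of valid pixels. Lower bound q_lo defaults to the
scattering center (0); images are min–max normalized to [0, 1], a
constant image mapping to all zeros.

**q-range optimization.** For upper bounds q_hi on a grid of step
`q_step` (default 0.003 nm⁻¹, covering the valid detector range), the
mean absolute deviation (MD) of a user-chosen featureless rectangle of
the normalized dark-field image is recorded. MD of a normalized image
lies in [0, 0.5] and serves as an inverse signal-to-noise proxy; grid
points whose cumulative annulus holds no valid pixel (inside the
beamstop) carry NaN and are excluded. The curve is smoothed with a
centered moving average truncated at the ends; the window is either
given or chosen by the geometric elbow criterion (maximum perpendicular
distance between the RMS(smoothed − raw)-vs-window curve and its
chord, candidates 1, 3, …). q_opt is the q at the global minimum of the
smoothed curve; ties break toward smaller q, which includes less noise.
Edge truncation can bias a V-shaped curve's minimum toward the ends
when the window approaches the curve length; at realistic
curve-length/window ratios (≈1000/≈40) the effect is negligible.

**Segmentation.** Cells are segmented on the normalized dark-field over
[q_lo, q_opt] by adaptive thresholding: candidate thresholds are 64
quantiles of the image between the 50th and 99.5th percentile (hence
invariance under affine intensity rescaling); each binarization is
cleaned by closing (disk r = 2), hole filling and an area filter
(minimum cell area `A_min`, default 500 scan px for 0.5 µm steps,
exposed in config); the minimum threshold attaining the maximum ROI
count wins. Binarizations whose cleaned foreground exceeds half the
area are treated as degenerate (threshold at or below the background
level) and skipped. A local refinement pass repeats the selection in
each ROI's padded bounding box; because a box holding a single
segmented cell yields one ROI at *every* threshold — which would drive
the minimum-threshold rule to the background level and flood the box —
a local result contributes only when it finds strictly more ROIs than
the global mask already has there, and only its components disjoint
from the global mask are added. The local pass therefore recovers
additional weak cells, not halos around found ones.

**Background mask and row-wise correction.** Bright non-cell pixels are
flagged when they deviate more than 3σ̂ from the moment-fit Gaussian of
the non-cell intensities (a moment fit is equivalent to a histogram fit
for the 3σ rule and deterministic). The union of cell and outlier masks
is dilated by a disk (radius 3 scan px) and its complement is the
background. Per raster line, the mean detector frame over that line's
background points is subtracted from all frames of the line (lines
without background points fall back to the global mean and are
flagged); this removes slow source drift and line-correlated offsets.
Corrected counts may be negative.

**Azimuthal profiles and maps.** Per scan point the corrected frame is
completed by point symmetry, pixels with q in [q₂, q_opt) are binned
into `n_bins` equal azimuth bins (default 72, i.e. 5°; the bin
statistic is the *mean*, making the resultant insensitive to unequal
pixel counts per bin near the beamstop). q₂ is the circumscribed-circle
q of the region that completion cannot fill (the central disk), so the
profile covers the full azimuth. Negative weights are clipped to zero —
weights must be non-negative; clipping is the least-informative choice.
The resultant R and mean axis give the anisotropy and (after the 90°
rotation to real space, wrapped to [−90°, 90°)) the orientation; points
with zero total weight are flagged undefined.

*Noise floor of the anisotropy.* After row-wise subtraction, background
residuals are zero-mean; clipping makes roughly half the bins zero and
leaves a resultant that does **not** vanish with more counts (observed
background R ≈ 0.15 median, ≈ 0.4 at the 99th percentile with 72 bins).
This floor is intrinsic to the clipped-weight estimator and motivates
the percentile-threshold selection below; it also means per-pixel
anisotropy values below ≈ 0.4 are not individually trustworthy in the
background.

**Per-cell statistics and damage.** Nuclei are h-maxima domains of the
normalized dark-field inside the cell mask via morphological
reconstruction by dilation of (image − h) under the image (h default
0.2 normalized units; component area ≥ `A_nuc`, default `A_min`/2).
Outside-cell pixels are held at the image maximum during
reconstruction so that only contrast *within* a cell counts — a cell of
flat intensity is then not its own maximum and is flagged; it still
receives a fallback watershed seed at its intensity maximum. Cells are
annotated by marker-controlled watershed on the negative Euclidean
distance transform of the cell mask with nuclei as markers. Per cell,
cytoplasmic pixels (label minus nuclei) with anisotropy strictly above
τ — the 99th percentile (linear interpolation between order statistics)
of the background anisotropy — form the cell's anisotropy distribution;
the **anisotropy decay** is the difference of this distribution's mean
between the first and second scan of the same region (computed between
scans 1 and 2 as the headline statistic; a scan-k generalization is
available through the same functions). The decay can be negative in
noisy data and is reported as-is. Near τ the thresholded mean is a
truncated mean and composition effects can bias it when a cell's
distribution straddles τ; distributions well above τ are unaffected.

**Dose and flow.** `D = (μ/ρ) I₀ hν T / (Δy Δz)` with μ/ρ in cm² g⁻¹
(default 1.60 for cellular material), I₀ the photon flux, hν the photon
energy (CODATA keV→J conversion), T the exposure per point and Δy, Δz
the step sizes; accumulated dose for scan n is n times the single-scan
dose (overhead exposure between lines is not modeled). Mean channel
flow velocity is Q/(w·h) for a rectangular cross-section.

## The synthetic-data generator

`scansaxs.synthetic` emulates the statistical features the pipeline
must survive, with known ground truth:

- expected counts `λ(q, φ) = B (q/q_ref)^{−α} drift(line) + [in cell]
  A (q/q_ref)^{−α} [(1 − a_eff) + a_eff e^{κ cos 2(φ − φ_s)}/I₀(κ)]`,
  with φ_s perpendicular to the real-space fiber orientation; q is
  clamped below `q_floor` (0.05 nm⁻¹; these pixels sit behind the
  beamstop anyway). The von Mises modulation in 2φ is the minimal
  axially symmetric model; its resultant is the Bessel ratio
  R(κ) = I₁(κ)/I₀(κ), so a mixture with anisotropic weight a has
  ground-truth anisotropy a·R(κ).
- Poisson sampling per pixel; one global seed, per-frame substreams
  derived from (seed, scan index, line, column) — bit-reproducible.
- stripe noise: an additive, signal-independent extra count rate
  `s · E(line)` (E exponential, unit mean, drawn per raster line) on
  pixels with q > q_noise, mimicking line-correlated instrumentation
  noise that corrupts only high-q annuli.
- per-line multiplicative drift `1 + d sin(2π·line/n)` of the
  background, removed by the row-wise correction.
- beamstop: central disk (radius 4 px) plus a holder bar downward
  (width 2 px); bar pixels are recoverable by point symmetry, disk
  pixels are not.
- damage: the anisotropic weight of every cell decays as
  `a_eff = a·exp(−(scan_index − 1)·D/D_c)` with D the per-scan dose
  from the scan metadata and `D_c` = 2×10⁷ Gy.

**Reference study conditions** (the generator defaults): 64×64 raster
at 0.5 µm steps and 2 ms exposure; 128×128 detector at 1.89 m and
15 keV with 1.2 mm pixels — a scaled-down detector spanning q ≲ 3 nm⁻¹
so the 0.003 nm⁻¹ MD grid keeps ≈ 1000 points; background
B = 8 counts/pixel at q_ref = 0.3 nm⁻¹ with α = 2.5; three elliptical
cells of a few hundred scan pixels, one nucleus each (nucleus 1.8×
brighter, 10× less ordered), anisotropic fractions 0.85/0.78/0.70 with
κ = 3 and a mild bundle texture (40 % of cytoplasm pixels carry 1.15×
the cell's anisotropic weight, the rest compensated so the mean stays
at a) emulating heterogeneous fiber-bundle networks; stripe amplitude
0.8 counts/pixel above q_noise = 1.0 nm⁻¹; drift amplitude 0.05.
Tests use this scene or a 32×32 version with a 64×64 detector (pixel
size doubled to preserve the q-range); the dose–decay experiment uses
step sizes 0.65/0.45/0.35/0.3 µm, spanning ≈ 2–9 ×10⁶ Gy per scan so
that even the weakest cell's second-scan distribution remains above the
background threshold τ.

**What the simulator does not emulate** — and hence what passing tests
do *not* establish about real data: detector artefacts beyond a simple
beamstop (gaps, hot pixels, aperture edges), flat-field/solid-angle/
polarization effects, sample absorption and multiple scattering,
structured backgrounds (window scattering with its own q-dependence),
non-elliptical cell shapes and overlapping/confluent cultures, q-
dependent (form-factor) anisotropy, and mechanistic damage chemistry
(the exponential decay is phenomenological). Geometry calibration is
taken as input, not refined.

## Numerical choices and degenerate inputs

- Pixel coordinates are 0-based (row, col) with values at pixel
  centers; the beam center may lie off-detector. Azimuth is measured
  from the +y (horizontal, fast) axis, counterclockwise viewed
  downstream, in [0°, 360°).
- Annuli are half-open [q_lo, q_hi), so adjacent annuli partition
  exactly and dark-field images add exactly (integer counts).
- The MD-curve accumulator histograms each frame once into the q-grid
  annuli and cumulates — identical (to float round-off) to recomputing
  each dark-field image from scratch, and verified against it.
- normalize01 of a constant image returns zeros; MD of it is 0.
- Empty azimuthal bins are NaN and excluded from statistics; per-point
  orientation failures are flagged, never fatal for the map.
- Angles are serialized in degrees, q in nm⁻¹, doses in Gy.
- All randomness flows from explicit integer seeds; no global RNG
  state is used.

## Known limitations

- The ROI-count threshold selection inherits the published approach's
  appetite for near-background thresholds; the degenerate-binarization
  guard and the improvement-gated local pass bound, but do not remove,
  the residual halo of a few noise pixels around bright cells.
- The clipped-weight anisotropy floor (≈ 0.4 at the 99th background
  percentile) limits damage quantification to structures whose
  anisotropy stays above it in the second scan; beyond that dose the
  thresholded mean saturates toward τ.
- Accumulated dose ignores inter-line overhead exposure, so repeated-
  scan doses are lower bounds for continuous-scan instruments.
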