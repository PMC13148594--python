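# scansaxs

Analysis pipeline for **fast-scanning small-angle X-ray scattering
(SAXS) of weakly scattering cellular samples** — hydrated cells raster-
scanned through a focused beam at millisecond exposures, one full 2-D
scattering pattern per scan point. At these exposures the signal-to-
noise ratio is low and additive instrumentation noise (stripes along
the fast scan axis) enters at high scattering angles, so the usable
q-range has to be chosen objectively rather than by eye.

The package provides:

- **Dark-field contrast imaging** — per scan point, the summed detector
  counts inside a q-annulus, `q = (4π/λ) sin θ` with 2θ the scattering
  angle.
- **Objective q-range optimization** — dark-field images are computed
  for a ladder of upper bounds q_hi (default step 0.003 nm⁻¹), each
  normalized to [0, 1]; the mean absolute deviation (MD) of a
  featureless background rectangle,
  `MD = (1/ab) Σ |I(y_i, z_i) − Ī|`,
  is the noise metric. The MD-vs-q curve is smoothed with a moving
  average (window chosen by the elbow method) and the minimum gives
  the optimal upper bound q_opt.
- **Segmentation and background correction** — adaptive-threshold cell
  segmentation (global + local threshold ladders, minimum threshold at
  maximum ROI count), a 3σ Gaussian outlier filter, mask dilation, and
  row-wise subtraction of the average background scattering pattern.
- **Orientation and anisotropy maps** — each pattern is completed by
  point symmetry across the beamstop, reduced to an azimuthal profile
  over [q₂, q_opt), and summarized by axial circular statistics: with
  bin centers φ_k and weights w_k,
  `R = |Σ w_k e^{2iφ_k}| / Σ w_k`, mean axis `½ arg Σ w_k e^{2iφ_k}`.
  R ∈ [0, 1] is the anisotropy (circular variance V = 1 − R); the
  real-space fiber orientation is the scattering axis rotated by 90°.
- **Per-cell radiation-damage quantification** — nuclei via
  morphological reconstruction (h-maxima), marker-controlled watershed
  annotation, cytoplasmic anisotropy distributions above the 99th
  percentile of the background anisotropy, and the **anisotropy decay**
  (drop of the per-cell mean between the first and second scan of the
  same region) against the radiation dose
  `D = (μ/ρ) I₀ hν T / (Δy Δz)` in gray.
- **A ground-truth simulator** (`scansaxs.synthetic`) producing raster
  scans with elliptical cells, von Mises azimuthal modulation, Poisson
  counting noise, beamstop masking, stripe noise above a known onset
  q_noise, per-line background drift, and dose-dependent decay of the
  anisotropic signal across repeated scans — used throughout the test
  suite to validate parameter recovery.

## Worked example

```bash
python examples/02_q_range_optimization.py
```

simulates a 32×32 scan with stripe noise injected above 1.0 nm⁻¹ and
prints:

```
MD curve: 1431 upper bounds, elbow-selected smoothing window = 5 samples
stripe-noise onset (injected): 1.000 nm^-1
selected q_opt:                0.984 nm^-1
```

The selected upper bound lands just below the stripe onset: annuli
beyond it add row-correlated noise to the dark-field image faster than
they add signal. `examples/03_orientation_maps.py` then runs the full
chain on the default three-cell scene and prints a median orientation
error of 0.61° against ground truth with per-cell anisotropy means that
rank-order with the injected anisotropic fractions;
`examples/04_radiation_damage.py` scans four dose levels twice each and
prints per-cell anisotropy decays that grow with dose (Spearman
ρ = 0.86). `examples/01_dose_and_flow.py` prints the dose table and
channel flow velocities.

## Command line

A thin CLI wraps the library for shell use:

```bash
scansaxs simulate --seed 1 --scans 2 --out scratch/run
scansaxs qopt scratch/run/scan_01.h5 --region 0,0,10,10 --out scratch/run
scansaxs orient scratch/run/scan_01.h5 --region 0,0,10,10 --a-min 200 --out scratch/run
scansaxs dose --exposure-ms 2 --dy 0.2 --dz 0.2
```

Scans are exchanged as a documented HDF5 container (`/frames`, `/mask`,
`/meta`); maps and masks are written as TIFF, curves and per-cell
tables as CSV.

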