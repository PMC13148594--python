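"""Ground-truth simulator of fast-scanning SAXS datasets of cells.

The forward model emulates, feature by feature, what the analysis
pipeline must handle in real fast-scan data of weakly scattering
hydrated cells:

* a flat isotropic background with a power-law radial decay and a
  slow per-scan-line drift of the incoming intensity;
* inside each (elliptical) cell, an additional scattering amplitude
  whose azimuthal dependence mixes an isotropic part with a von Mises
  modulation in 2φ (period π, the minimal axially symmetric model);
  the modulation axis is perpendicular to the real-space fiber
  orientation, as fibers scatter normal to their long axis;
* Poisson counting noise on the expected counts;
* additive stripe noise along the fast scan axis, entering only above
  a known onset q_noise — a constant extra count rate per raster line
  at high q, independent of the signal;
* a beamstop (disk plus holder bar) invalidating central pixels;
* dose-dependent decay of the anisotropic fraction across repeated
  scans of the same region: a_eff = a · exp(−(scan_index−1) · D/D_c).

The von Mises concentration κ maps to the ground-truth anisotropy via
the Bessel ratio R(κ) = I₁(κ)/I₀(κ); for the isotropic/anisotropic
mixture the resultant is a_eff · R(κ).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import i0 as bessel_i0, i1 as bessel_i1

from .cells import DoseParams, radiation_dose
from .geometry import BeamGeometry, compute_q_map
from .scan_io import ScanStack


@dataclass(frozen=True)
class CellSpec:
    """One synthetic cell: an ellipse with a nucleus ellipse inside.

    ``center`` is (row, col) in scan pixels; ``axes`` are the semi-axes
    in scan pixels, the first along ``angle_deg`` (real-space angle
    from the fast/horizontal axis), the second perpendicular.  ``amplitude`` is the extra expected
    counts per detector pixel at the reference q; ``aniso_fraction`` is
    the anisotropic weight a ∈ [0, 1); ``orientation_rule`` is one of
    "constant" (fibers at ``fiber_angle_deg`` everywhere),
    "tangent" (fibers follow concentric ellipse tangents) or
    "loop" (fibers tangent to circles around the nucleus).
    """

    center: tuple[float, float]
    axes: tuple[float, float]
    angle_deg: float = 0.0
    nucleus_scale: float = 0.35
    amplitude: float = 8.0
    nucleus_amplitude_factor: float = 1.8
    aniso_fraction: float = 0.6
    kappa: float = 3.0
    orientation_rule: str = "constant"
    fiber_angle_deg: float = 30.0
    bundle_fraction: float = 0.4
    bundle_contrast: float = 1.15

    def __post_init__(self) -> None:
        if not 0 <= self.aniso_fraction < 1:
            raise ValueError("aniso_fraction must be in [0, 1)")
        if self.orientation_rule not in ("constant", "tangent", "loop"):
            raise ValueError(f"unknown orientation_rule {self.orientation_rule}")
        if not 0 <= self.bundle_fraction <= 1:
            raise ValueError("bundle_fraction must be in [0, 1]")
        if self.aniso_fraction * self.bundle_contrast >= 1:
            raise ValueError("bundle anisotropic fraction must stay below 1")


@dataclass(frozen=True)
class SceneSpec:
    """Full description of a synthetic repeated-scan experiment.

    Defaults describe the package's reference study conditions: a
    64×64 raster with 0.5 µm steps, a 128×128 detector whose q-range
    reaches ≈3 nm⁻¹, three cells, ~1 count/pixel background at the
    reference q with power-law decay α, stripe noise switching on at
    q_noise = 1.0 nm⁻¹ and a critical damage dose D_c.
    """

    n_rows: int = 64
    n_cols: int = 64
    dy_um: float = 0.5
    dz_um: float = 0.5
    detector_shape: tuple[int, int] = (128, 128)
    beam_center: tuple[float, float] = (63.5, 63.5)
    beamstop_radius: float = 4.0
    beamstop_bar_width: float = 2.0
    energy_kev: float = 15.0
    distance_m: float = 1.89
    pixel_size_m: float = 1.2e-3
    exposure_ms: float = 2.0
    flux: float = 1.09e12
    cells: tuple[CellSpec, ...] | None = None  # None -> default_cells()
    background_amplitude: float = 8.0
    alpha: float = 2.5
    q_ref: float = 0.3          # nm^-1 where amplitudes are quoted
    q_floor: float = 0.05       # nm^-1 clamp against the q→0 divergence
    stripe_amplitude: float = 0.8
    q_noise: float = 1.0        # nm^-1, stripe-noise onset
    drift_amplitude: float = 0.05
    critical_dose: float = 2e7  # Gy, D_c of the damage exponential
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cells is None:
            object.__setattr__(self, "cells", default_cells())
        if self.stripe_amplitude < 0 or self.background_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")

    @property
    def geometry(self) -> BeamGeometry:
        return BeamGeometry(
            photon_energy=self.energy_kev,
            sample_detector_distance=self.distance_m,
            pixel_size=self.pixel_size_m,
            beam_center=self.beam_center,
            detector_shape=self.detector_shape,
        )

    @property
    def dose_per_scan(self) -> float:
        """Accumulated dose of one full scan pass, Gy."""
        return radiation_dose(DoseParams(
            i0=self.flux, photon_energy=self.energy_kev,
            exposure=self.exposure_ms * 1e-3, dy=self.dy_um, dz=self.dz_um,
        ))


@dataclass
class GroundTruth:
    """Ground truth accompanying one simulated scan pass."""

    cell_mask: np.ndarray
    nuclei_mask: np.ndarray
    labels: np.ndarray
    orientation: np.ndarray       # degrees, real-space, NaN outside cells
    anisotropy: np.ndarray        # resultant a_eff·I1(κ)/I0(κ)
    aniso_fraction: np.ndarray    # per-pixel anisotropic weight a_eff
    accumulated_dose: float       # Gy after this scan pass


def default_cells() -> tuple[CellSpec, ...]:
    """Three reference cells with distinct anisotropy and orientation.

    Sized like spread epithelial cells at the default 0.5 µm steps:
    a few hundred scan pixels each (well above the area filter), with
    clearly separated centers and one nucleus apiece.
    """
    return (
        CellSpec(center=(17.0, 16.0), axes=(13.0, 10.0), angle_deg=20.0,
                 aniso_fraction=0.85, orientation_rule="constant",
                 fiber_angle_deg=30.0),
        CellSpec(center=(46.0, 20.0), axes=(11.0, 14.0), angle_deg=-30.0,
                 aniso_fraction=0.78, orientation_rule="constant",
                 fiber_angle_deg=-60.0),
        CellSpec(center=(28.0, 48.0), axes=(14.0, 10.0), angle_deg=70.0,
                 aniso_fraction=0.70, orientation_rule="tangent"),
    )


def vonmises_resultant(kappa: float) -> float:
    """Axial resultant length of a von Mises modulation, I₁(κ)/I₀(κ)."""
    return float(bessel_i1(kappa) / bessel_i0(kappa))


def beamstop_mask(spec: SceneSpec) -> np.ndarray:
    """Valid-pixel mask: False on the beamstop disk and holder bar."""
    n_rows, n_cols = spec.detector_shape
    rows = np.arange(n_rows)[:, None] - spec.beam_center[0]
    cols = np.arange(n_cols)[None, :] - spec.beam_center[1]
    disk = np.hypot(rows, cols) <= spec.beamstop_radius
    # bar from the disk downward (holder arm), half the bar width each side
    bar = (np.abs(np.broadcast_to(cols, disk.shape))
           <= spec.beamstop_bar_width / 2.0) & \
          (np.broadcast_to(rows, disk.shape) >= 0)
    return ~(disk | bar)


def _ellipse_coords(
    shape: tuple[int, int], center: tuple[float, float],
    axes: tuple[float, float], angle_deg: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ellipse-frame coordinates (u, v) and the inside mask.

    Physical coordinates are x = +col, y = −row (y up, matching the
    real-space angle convention); u runs along the semi-axis ``axes[0]``
    at ``angle_deg`` from horizontal, v along the perpendicular
    ``axes[1]``.
    """
    drow = np.arange(shape[0])[:, None] - center[0]
    dcol = np.arange(shape[1])[None, :] - center[1]
    x, y = np.broadcast_arrays(dcol, -drow)
    t = np.radians(angle_deg)
    u = x * np.cos(t) + y * np.sin(t)
    v = -x * np.sin(t) + y * np.cos(t)
    a, b = axes
    return u, v, ((u / a) ** 2 + (v / b) ** 2) <= 1.0


def _cell_orientation_field(cell: CellSpec, shape: tuple[int, int]) -> np.ndarray:
    """Real-space fiber angle (deg, [−90, 90)) at every scan pixel of a cell."""
    if cell.orientation_rule == "constant":
        field_ = np.full(shape, float(cell.fiber_angle_deg))
    elif cell.orientation_rule == "loop":
        rows = np.arange(shape[0])[:, None] - cell.center[0]
        cols = np.arange(shape[1])[None, :] - cell.center[1]
        # tangent to circles around the center: perpendicular to the radius
        radial = np.degrees(np.arctan2(-rows, cols))
        field_ = radial + 90.0
    else:  # tangent to concentric ellipses
        u, v, _ = _ellipse_coords(shape, cell.center, cell.axes,
                                  cell.angle_deg)
        a, b = cell.axes
        du, dv = -a * v / b, b * u / a
        local = np.degrees(np.arctan2(dv, du))
        field_ = local + cell.angle_deg
    return (field_ + 90.0) % 180.0 - 90.0


def _bundle_field(spec: SceneSpec) -> np.ndarray:
    """Deterministic cytoplasmic fiber-bundle indicator on the scan grid.

    Real cytoplasm is not uniformly ordered: keratin-like bundles carry
    most of the anisotropic signal.  The same pixels are bundles in
    every repeated scan pass.
    """
    rng = np.random.default_rng([spec.seed % (2 ** 31), 7919])
    return rng.uniform(size=(spec.n_rows, spec.n_cols))


def scene_ground_truth(spec: SceneSpec, scan_index: int = 1) -> GroundTruth:
    """Masks, labels and fields implied by the scene for one scan pass."""
    shape = (spec.n_rows, spec.n_cols)
    cell_mask = np.zeros(shape, dtype=bool)
    nuclei = np.zeros(shape, dtype=bool)
    labels = np.zeros(shape, dtype=np.int32)
    orientation = np.full(shape, np.nan)
    anisotropy = np.zeros(shape)
    aniso_fraction = np.zeros(shape)
    bundles = _bundle_field(spec)
    decay_factor = np.exp(-(scan_index - 1) * spec.dose_per_scan
                          / spec.critical_dose)
    for k, cell in enumerate(spec.cells, start=1):
        _, _, inside = _ellipse_coords(shape, cell.center, cell.axes,
                                       cell.angle_deg)
        nuc_axes = (cell.axes[0] * cell.nucleus_scale,
                    cell.axes[1] * cell.nucleus_scale)
        _, _, in_nuc = _ellipse_coords(shape, cell.center, nuc_axes,
                                       cell.angle_deg)
        new = inside & ~cell_mask
        cell_mask |= inside
        labels[new] = k
        nuclei |= in_nuc
        orient = _cell_orientation_field(cell, shape)
        orientation[new] = orient[new]
        # bundle texture: multiplier bundle_contrast on bundle pixels,
        # compensated elsewhere so the cytoplasmic mean stays at a
        bf, bc = cell.bundle_fraction, cell.bundle_contrast
        m_lo = (1.0 - bf * bc) / (1.0 - bf) if bf < 1 else 1.0
        mult = np.where(bundles < bf, bc, m_lo)
        a_pix = cell.aniso_fraction * mult * decay_factor
        # nuclei are denser but much less ordered (and untextured)
        a_pix = np.where(in_nuc, 0.1 * cell.aniso_fraction * decay_factor,
                         a_pix)
        aniso_fraction[new] = a_pix[new]
        anisotropy[new] = a_pix[new] * vonmises_resultant(cell.kappa)
    return GroundTruth(
        cell_mask=cell_mask, nuclei_mask=nuclei & cell_mask, labels=labels,
        orientation=orientation, anisotropy=anisotropy,
        aniso_fraction=aniso_fraction,
        accumulated_dose=scan_index * spec.dose_per_scan,
    )


def _stripe_factors(spec: SceneSpec, scan_index: int) -> np.ndarray:
    """Per-raster-line stripe-noise strength, ≥ 0, unit mean."""
    rng = np.random.default_rng([spec.seed % (2 ** 31), 104729, scan_index])
    return rng.exponential(1.0, size=spec.n_rows)


def _drift(spec: SceneSpec, row: int) -> float:
    """Smooth per-line multiplicative drift of the background."""
    return 1.0 + spec.drift_amplitude * np.sin(
        2.0 * np.pi * row / max(spec.n_rows, 1)
    )


def expected_frame(
    spec: SceneSpec, scan_point: tuple[int, int], scan_index: int = 1
) -> np.ndarray:
    """Expected (Poisson-mean) detector counts at one scan point.

    Stripe noise is excluded: it is additive and drawn per raster line,
    see :func:`render_frame`.
    """
    i, j = scan_point
    if not (0 <= i < spec.n_rows and 0 <= j < spec.n_cols):
        raise ValueError(f"scan point {scan_point} outside the grid")
    qmap = compute_q_map(spec.geometry)
    q_eff = np.maximum(qmap.q_magnitude, spec.q_floor)
    radial = (q_eff / spec.q_ref) ** (-spec.alpha)
    lam = spec.background_amplitude * radial * _drift(spec, i)
    gt = scene_ground_truth(spec, scan_index)
    if gt.cell_mask[i, j]:
        k = gt.labels[i, j]
        cell = spec.cells[k - 1]
        a_eff = gt.aniso_fraction[i, j]
        amp = cell.amplitude
        if gt.nuclei_mask[i, j]:
            amp *= cell.nucleus_amplitude_factor
        phi_scatter = gt.orientation[i, j] + 90.0
        dphi = np.radians(qmap.azimuth - phi_scatter)
        modulation = np.exp(cell.kappa * np.cos(2.0 * dphi)) \
            / bessel_i0(cell.kappa)
        lam = lam + amp * radial * ((1.0 - a_eff) + a_eff * modulation)
    return lam


def render_frame(
    spec: SceneSpec, scan_point: tuple[int, int], scan_index: int = 1
) -> np.ndarray:
    """One Poisson-sampled detector frame with stripe noise and beamstop.

    Deterministic for a fixed scene seed: the substream is derived from
    (seed, scan_index, row, col).  Beamstop pixels are zeroed (they are
    invalid in the accompanying mask).
    """
    i, j = scan_point
    lam = expected_frame(spec, scan_point, scan_index)
    qmap = compute_q_map(spec.geometry)
    stripe = _stripe_factors(spec, scan_index)[i]
    lam = lam + spec.stripe_amplitude * stripe * \
        (qmap.q_magnitude > spec.q_noise)
    rng = np.random.default_rng(
        [spec.seed % (2 ** 31), scan_index, i, j]
    )
    frame = rng.poisson(lam).astype(np.uint32)
    frame[~beamstop_mask(spec)] = 0
    return frame


def generate_scan(
    spec: SceneSpec, scan_index: int = 1
) -> tuple[ScanStack, GroundTruth]:
    """Simulate one full raster pass over the scene.

    Repeated passes (``scan_index`` = 1, 2, …) accumulate dose and
    shrink the anisotropic fraction of every cell by
    exp(−(scan_index−1)·D/D_c).  Bit-identical for a fixed seed.
    """
    shape = (spec.n_rows, spec.n_cols)
    det = spec.detector_shape
    valid = beamstop_mask(spec)
    qmap = compute_q_map(spec.geometry)
    q_eff = np.maximum(qmap.q_magnitude, spec.q_floor)
    radial = (q_eff / spec.q_ref) ** (-spec.alpha)
    gt = scene_ground_truth(spec, scan_index)
    stripe = _stripe_factors(spec, scan_index)
    stripe_region = qmap.q_magnitude > spec.q_noise

    frames = np.empty((*shape, *det), dtype=np.uint32)
    base = spec.background_amplitude * radial
    for i in range(spec.n_rows):
        row_bg = base * _drift(spec, i) \
            + spec.stripe_amplitude * stripe[i] * stripe_region
        for j in range(spec.n_cols):
            lam = row_bg
            if gt.cell_mask[i, j]:
                cell = spec.cells[gt.labels[i, j] - 1]
                a_eff = gt.aniso_fraction[i, j]
                amp = cell.amplitude
                if gt.nuclei_mask[i, j]:
                    amp *= cell.nucleus_amplitude_factor
                phi_scatter = gt.orientation[i, j] + 90.0
                dphi = np.radians(qmap.azimuth - phi_scatter)
                modulation = np.exp(cell.kappa * np.cos(2.0 * dphi)) \
                    / bessel_i0(cell.kappa)
                lam = row_bg + amp * radial * ((1.0 - a_eff)
                                               + a_eff * modulation)
            rng = np.random.default_rng(
                [spec.seed % (2 ** 31), scan_index, i, j]
            )
            frame = rng.poisson(lam).astype(np.uint32)
            frame[~valid] = 0
            frames[i, j] = frame
    stack = ScanStack(
        frames=frames, valid_mask=valid, geometry=spec.geometry,
        dy_um=spec.dy_um, dz_um=spec.dz_um, exposure_ms=spec.exposure_ms,
        flux=spec.flux, scan_index=scan_index,
    )
    return stack, gt
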