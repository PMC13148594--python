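"""Detector/beam geometry and q-space maps for scanning SAXS.

The detector records elastic scattering at small angles.  For a pixel at
radial distance *r* from the beam center, the scattering angle is
``2θ = arctan(r / L)`` with *L* the sample–detector distance, and the
scattering-vector magnitude is ``q = (4π/λ) sin θ`` in nm⁻¹.  The exact
``sin(arctan(·)/2)`` form is used rather than the small-angle
approximation, since detector corners can reach 2θ of a few degrees.

Azimuth convention: 0° along the +y (horizontal, fast-scan) axis,
increasing counterclockwise when viewed downstream, i.e. computed from
the pixel offset ``(Δcol, −Δrow)``.  Pixel coordinates are 0-based
(row, col) with the value taken at the pixel center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# hc in keV·nm
HC_KEV_NM = 1.2398419


def wavelength_from_energy(energy_kev: float) -> float:
    """X-ray wavelength in nm for a photon energy in keV.

    Parameters
    ----------
    energy_kev : photon energy, keV; must be positive.
    """
    if not energy_kev > 0:
        raise ValueError(f"photon energy must be positive, got {energy_kev}")
    return HC_KEV_NM / energy_kev


@dataclass(frozen=True)
class BeamGeometry:
    """Beam/detector geometry of a scanning-SAXS setup.

    Attributes
    ----------
    photon_energy : keV
    sample_detector_distance : m
    pixel_size : m, square pixels
    beam_center : (row, col) in fractional pixel units, 0-based; may lie
        outside the detector area.
    detector_shape : (n_rows, n_cols)
    """

    photon_energy: float
    sample_detector_distance: float
    pixel_size: float
    beam_center: tuple[float, float]
    detector_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.photon_energy > 0:
            raise ValueError("photon_energy must be > 0 keV")
        if not self.sample_detector_distance > 0:
            raise ValueError("sample_detector_distance must be > 0 m")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0 m")
        if len(self.detector_shape) != 2 or any(s < 1 for s in self.detector_shape):
            raise ValueError("detector_shape must be a positive (n_rows, n_cols)")

    @property
    def wavelength(self) -> float:
        """Wavelength in nm, derived from the photon energy."""
        return wavelength_from_energy(self.photon_energy)


@dataclass
class QMap:
    """Per-detector-pixel scattering-vector magnitude and azimuth.

    ``q_magnitude`` is in nm⁻¹; ``azimuth`` in degrees in [0, 360);
    ``valid_mask`` is False on beamstop/artefact pixels.
    """

    q_magnitude: np.ndarray
    azimuth: np.ndarray
    valid_mask: np.ndarray
    geometry: BeamGeometry | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.q_magnitude.shape


@dataclass(frozen=True)
class QRangeLandmarks:
    """Named q-range landmarks (all nm⁻¹), ordered q0 ≤ … ≤ q5.

    q0: scattering center (lower bound for dark-field sums); q1: minimum
    radius with scattering signal; q2: circumscribed circle of the
    beamstop; q3: minimum of the MD curve (the optimal upper bound);
    q4: maximum circle inscribed in the detector; q5: whole detector.
    """

    q0: float
    q1: float
    q2: float
    q3: float
    q4: float
    q5: float

    def __post_init__(self) -> None:
        vals = (self.q0, self.q1, self.q2, self.q3, self.q4, self.q5)
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError(f"q landmarks must be non-decreasing, got {vals}")


def compute_q_map(
    geometry: BeamGeometry, valid_mask: np.ndarray | None = None
) -> QMap:
    """Compute the per-pixel q magnitude and azimuth for a geometry.

    q uses the exact form ``(4π/λ) sin(arctan(r/L) / 2)``.  Azimuth is
    measured from the +y (horizontal) axis, counterclockwise viewed
    downstream, from the offset ``(Δcol, −Δrow)``.
    """
    n_rows, n_cols = geometry.detector_shape
    rows = np.arange(n_rows, dtype=float)[:, None]
    cols = np.arange(n_cols, dtype=float)[None, :]
    drow = rows - geometry.beam_center[0]
    dcol = cols - geometry.beam_center[1]
    r = np.hypot(drow, dcol) * geometry.pixel_size
    two_theta = np.arctan2(r, geometry.sample_detector_distance)
    q = (4.0 * np.pi / geometry.wavelength) * np.sin(0.5 * two_theta)
    azimuth = np.degrees(np.arctan2(-np.broadcast_to(drow, q.shape),
                                    np.broadcast_to(dcol, q.shape))) % 360.0
    if valid_mask is None:
        valid_mask = np.ones(q.shape, dtype=bool)
    else:
        valid_mask = np.asarray(valid_mask, dtype=bool)
        if valid_mask.shape != q.shape:
            raise ValueError(
                f"valid_mask shape {valid_mask.shape} != detector {q.shape}"
            )
        valid_mask = valid_mask.copy()
    return QMap(q_magnitude=q, azimuth=azimuth, valid_mask=valid_mask,
                geometry=geometry)


def annular_selection(qmap: QMap, q_lo: float, q_hi: float) -> np.ndarray:
    """Boolean selection of valid pixels with q in the half-open [q_lo, q_hi)."""
    if not (0 <= q_lo < q_hi):
        raise ValueError(f"need 0 <= q_lo < q_hi, got q_lo={q_lo}, q_hi={q_hi}")
    q = qmap.q_magnitude
    return qmap.valid_mask & (q >= q_lo) & (q < q_hi)


def reflect_indices(
    shape: tuple[int, int], beam_center: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Point-reflection pixel indices through the beam center.

    Returns (mirror_rows, mirror_cols, in_bounds); the mirror of pixel p
    is ``round(2·center − p)`` per axis.
    """
    n_rows, n_cols = shape
    rows = np.arange(n_rows)[:, None]
    cols = np.arange(n_cols)[None, :]
    mrow = np.rint(2.0 * beam_center[0] - rows).astype(int)
    mcol = np.rint(2.0 * beam_center[1] - cols).astype(int)
    mrow, mcol = np.broadcast_arrays(mrow, mcol)
    in_bounds = (mrow >= 0) & (mrow < n_rows) & (mcol >= 0) & (mcol < n_cols)
    return mrow, mcol, in_bounds


def complete_point_symmetry(
    pattern: np.ndarray,
    valid_mask: np.ndarray,
    beam_center: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Fill masked pixels from their point-reflected counterparts.

    SAXS patterns are point-symmetric about the beam center, so an
    invalid pixel (e.g. behind the beamstop bar) whose reflection lands
    on a valid pixel can take that pixel's value.  Valid pixels are
    never overwritten; pixels invalid on both sides stay invalid.

    Returns (completed_pattern, completed_mask); inputs are not modified.
    """
    pattern = np.asarray(pattern)
    valid_mask = np.asarray(valid_mask, dtype=bool)
    if pattern.shape != valid_mask.shape:
        raise ValueError("pattern and valid_mask must share the detector shape")
    mrow, mcol, in_bounds = reflect_indices(pattern.shape, beam_center)
    fillable = ~valid_mask & in_bounds
    # mirror must itself be a valid pixel
    safe_r = np.where(in_bounds, mrow, 0)
    safe_c = np.where(in_bounds, mcol, 0)
    mirror_valid = np.zeros_like(valid_mask)
    mirror_valid[fillable] = valid_mask[safe_r[fillable], safe_c[fillable]]
    fillable &= mirror_valid
    out = pattern.astype(float, copy=True)
    out[fillable] = pattern[safe_r[fillable], safe_c[fillable]]
    out_mask = valid_mask | fillable
    return out, out_mask
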