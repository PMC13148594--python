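"""Per-scan-point orientation and anisotropy from azimuthal statistics.

Each background-subtracted scattering pattern is completed by point
symmetry, reduced to an azimuthal intensity profile over the annulus
[q2, q_opt), and summarized by axial circular statistics: with bin
centers φ_k and non-negative weights w_k, the first trigonometric
moment of the doubled angles gives the resultant length
R = |Σ w_k e^{2iφ_k}| / Σ w_k and the mean axis ½·arg(Σ w_k e^{2iφ_k}).
R ∈ [0, 1] is the anisotropy (1 − R is the circular variance); the
real-space fiber orientation is perpendicular to the scattering axis,
so 90° is added modulo 180°.  Angle doubling makes the statistics
axial (period 180°), matching the point symmetry of SAXS patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import QMap, annular_selection, complete_point_symmetry
from .scan_io import ScanStack


@dataclass
class AzimuthalProfile:
    """Mean intensity per azimuthal bin over a q-annulus.

    ``intensity`` is NaN for bins without contributing pixels;
    ``coverage`` is the fraction of bins with at least one pixel.
    """

    bin_centers: np.ndarray
    intensity: np.ndarray
    q_range: tuple[float, float]
    coverage: float


@dataclass
class OrientationMaps:
    """Per-scan-point real-space orientation (deg, [−90, 90)) and anisotropy.

    Scan points where the total azimuthal weight is zero (no signal)
    carry NaN orientation and are True in ``undefined``.
    """

    orientation: np.ndarray
    anisotropy: np.ndarray
    undefined: np.ndarray
    q_range: tuple[float, float]


def azimuthal_profile(
    frame: np.ndarray,
    qmap: QMap,
    q_lo: float,
    q_hi: float,
    n_bins: int = 72,
    valid_mask: np.ndarray | None = None,
) -> AzimuthalProfile:
    """Azimuthal intensity profile of a completed detector frame.

    Bin b collects valid pixels with azimuth in [b·Δφ, (b+1)·Δφ) and q
    in [q_lo, q_hi); the bin statistic is the mean, which makes the
    downstream resultant insensitive to unequal pixel counts per bin
    near the beamstop.
    """
    if n_bins < 8:
        raise ValueError("n_bins must be >= 8")
    mask = qmap.valid_mask if valid_mask is None else np.asarray(valid_mask, bool)
    sel = annular_selection(
        QMap(qmap.q_magnitude, qmap.azimuth, mask), q_lo, q_hi
    )
    if not sel.any():
        raise ValueError(
            f"no valid pixel contributes in q-range [{q_lo}, {q_hi})"
        )
    width = 360.0 / n_bins
    bins = np.minimum((qmap.azimuth[sel] / width).astype(int), n_bins - 1)
    weights = np.asarray(frame, dtype=float)[sel]
    sums = np.bincount(bins, weights=weights, minlength=n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    intensity = np.full(n_bins, np.nan)
    np.divide(sums, counts, out=intensity, where=counts > 0)
    centers = (np.arange(n_bins) + 0.5) * width
    return AzimuthalProfile(
        bin_centers=centers, intensity=intensity, q_range=(q_lo, q_hi),
        coverage=float((counts > 0).mean()),
    )


def circular_stats_axial(
    profile: AzimuthalProfile,
) -> tuple[float, float]:
    """Axial circular mean and resultant length of an azimuthal profile.

    Negative intensities (possible after background subtraction) are
    clipped to zero for the weights.  Returns
    ``(mean_axis_deg, R)``; ``mean_axis_deg`` is NaN when the total
    weight is zero (isotropic/undefined, flagged by the caller).
    """
    finite = np.isfinite(profile.intensity)
    w = np.clip(profile.intensity[finite], 0.0, None)
    total = w.sum()
    if total <= 0:
        return float("nan"), 0.0
    phi2 = np.radians(2.0 * profile.bin_centers[finite])
    c = float(np.sum(w * np.cos(phi2)))
    s = float(np.sum(w * np.sin(phi2)))
    r = float(np.hypot(c, s) / total)
    mean_axis = 0.5 * np.degrees(np.arctan2(s, c))
    mean_axis = (mean_axis + 90.0) % 180.0 - 90.0
    return float(mean_axis), r


def to_real_space(mean_axis_scattering: float) -> float:
    """Real-space fiber axis from a scattering-space axis (+90° mod 180°).

    Fibers scatter perpendicular to their long axis, so the real-space
    orientation is the scattering axis rotated by 90°, wrapped to
    [−90, 90).
    """
    return (mean_axis_scattering + 90.0 + 90.0) % 180.0 - 90.0


def orientation_maps(
    stack: ScanStack,
    qmap: QMap,
    q_lo: float,
    q_hi: float,
    n_bins: int = 72,
) -> OrientationMaps:
    """Orientation and anisotropy maps from a background-subtracted stack.

    Per scan point the pattern is completed by point symmetry, the
    azimuthal profile over [q_lo, q_hi) is computed, and the axial
    circular statistics give the anisotropy R and the real-space
    orientation.  Point-level failures (no contributing weight) are
    flagged, not fatal.
    """
    n_rows, n_cols = stack.grid_shape
    orient = np.full((n_rows, n_cols), np.nan)
    anis = np.zeros((n_rows, n_cols))
    undefined = np.zeros((n_rows, n_cols), dtype=bool)
    center = stack.geometry.beam_center

    # The completed validity mask is frame-independent, so precompute
    # bin membership once on a completed-mask QMap.
    probe = np.zeros(qmap.shape)
    _, completed_mask = complete_point_symmetry(probe, qmap.valid_mask, center)
    for i in range(n_rows):
        for j in range(n_cols):
            completed, _ = complete_point_symmetry(
                stack.frames[i, j], qmap.valid_mask, center
            )
            try:
                prof = azimuthal_profile(
                    completed, qmap, q_lo, q_hi, n_bins=n_bins,
                    valid_mask=completed_mask,
                )
            except ValueError:
                undefined[i, j] = True
                continue
            axis, r = circular_stats_axial(prof)
            anis[i, j] = r
            if np.isnan(axis):
                undefined[i, j] = True
            else:
                orient[i, j] = to_real_space(axis)
    return OrientationMaps(orientation=orient, anisotropy=anis,
                           undefined=undefined, q_range=(q_lo, q_hi))
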