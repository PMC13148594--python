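"""Foreground/background segmentation and row-wise background correction.

Cells are segmented from the normalized dark-field image by adaptive
thresholding in the spirit of ACSAT: a ladder of candidate thresholds is
scanned, each binarization is morphologically cleaned and
area-filtered, and the minimum threshold attaining the maximum ROI
count wins; the same selection is then repeated locally inside every
global ROI's padded bounding box.  Remaining bright background pixels
are removed with a 3σ Gaussian outlier filter, the union of cell and
outlier masks is dilated, and the complement defines the background.
The per-scan-row average background pattern corrects for beam drift and
row-dependent offsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology
from skimage.measure import label, regionprops

from .darkfield import DarkFieldImage
from .scan_io import ScanStack


@dataclass
class RegionMasks:
    """Cell / outlier / background masks on the scan grid."""

    cell_mask: np.ndarray
    outlier_mask: np.ndarray
    background_mask: np.ndarray
    a_min: int


@dataclass
class RowBackground:
    """Per-scan-row average background detector pattern.

    ``patterns`` has shape (n_rows, det_rows, det_cols); ``counts[i]`` is the
    number of background scan pixels contributing to row i, and
    ``fallback_rows`` flags rows that had none and received the global
    mean instead.
    """

    patterns: np.ndarray
    counts: np.ndarray
    fallback_rows: np.ndarray


def _clean_binary(binary: np.ndarray, a_min: int) -> np.ndarray:
    """Closing (disk r=2) + hole fill + minimum-area filter."""
    footprint = morphology.disk(2)
    out = morphology.erosion(morphology.dilation(binary, footprint), footprint)
    out = ndimage.binary_fill_holes(out)
    # keep components with area >= a_min
    labeled, _ = ndimage.label(out)
    areas = np.bincount(labeled.ravel())
    areas[0] = 0
    return (areas >= a_min)[labeled]


def _best_threshold_mask(
    image: np.ndarray, a_min: int, n_thresholds: int
) -> tuple[np.ndarray, int]:
    """Minimum threshold attaining the maximum ROI count.

    Candidate thresholds are quantiles of the image intensity between
    the 50th and 99.5th percentile, making the selection invariant
    under affine intensity rescaling.  Degenerate binarizations whose
    cleaned foreground covers more than half the area — thresholds at
    or below the background level — are skipped: cells occupy a
    minority of the field of view.
    """
    qs = np.linspace(0.50, 0.995, n_thresholds)
    thresholds = np.unique(np.quantile(image, qs))
    best_mask = np.zeros(image.shape, dtype=bool)
    best_count = 0
    # ascending thresholds: strict '>' keeps the first (smallest) winner
    for t in thresholds:
        cleaned = _clean_binary(image >= t, a_min)
        if cleaned.mean() > 0.5:
            continue
        n = label(cleaned, connectivity=2).max()
        if n > best_count:
            best_count = int(n)
            best_mask = cleaned
    return best_mask, best_count


def acsat_segment(
    image: DarkFieldImage,
    a_min: int,
    n_thresholds: int = 64,
    local_pad: int = 5,
) -> np.ndarray:
    """Adaptive-threshold cell segmentation of a normalized dark-field image.

    Global stage: scan candidate thresholds over the whole image and
    keep the minimum threshold with the maximum number of surviving
    ROIs.  Local stage: within each global ROI's bounding box (padded by
    ``local_pad``), repeat the selection and union the result — this
    recovers weak-contrast cells near bright ones that the global
    threshold misses.  A local result contributes only when it finds
    strictly more ROIs in the box than the global mask already has
    there, and only its components disjoint from the global mask are
    unioned: for a box holding a single segmented cell every threshold
    yields one ROI and the minimum-threshold rule would otherwise
    degenerate to the background level and flood the box.

    Returns the boolean cell mask; empty (with a warning) if no
    component of area ≥ ``a_min`` survives at any threshold.
    """
    if a_min < 1:
        raise ValueError("a_min must be >= 1")
    img = np.asarray(image.values, dtype=float)
    global_mask, n_rois = _best_threshold_mask(img, a_min, n_thresholds)
    if n_rois == 0:
        import warnings

        warnings.warn("acsat_segment: no component survived at any threshold",
                      stacklevel=2)
        return global_mask
    mask = global_mask.copy()
    for region in regionprops(label(global_mask, connectivity=2)):
        r0, c0, r1, c1 = region.bbox
        r0 = max(0, r0 - local_pad)
        c0 = max(0, c0 - local_pad)
        r1 = min(img.shape[0], r1 + local_pad)
        c1 = min(img.shape[1], c1 + local_pad)
        local, n_local = _best_threshold_mask(img[r0:r1, c0:c1], a_min,
                                              n_thresholds)
        n_global_here = int(label(global_mask[r0:r1, c0:c1],
                                  connectivity=2).max())
        if n_local > n_global_here:
            local_labels = label(local, connectivity=2)
            box_global = global_mask[r0:r1, c0:c1]
            for lreg in regionprops(local_labels):
                coords = tuple(lreg.coords.T)
                if not box_global[coords].any():
                    mask[r0:r1, c0:c1][local_labels == lreg.label] = True
    return mask


def gaussian_outlier_filter(
    image: DarkFieldImage | np.ndarray,
    candidate_background: np.ndarray,
    k: float = 3.0,
) -> np.ndarray:
    """Flag candidate-background pixels deviating more than k·σ̂.

    μ̂ and σ̂ are the moments of the intensities over
    ``candidate_background``; if σ̂ = 0 nothing is flagged.
    """
    img = image.values if isinstance(image, DarkFieldImage) else np.asarray(image)
    candidate_background = np.asarray(candidate_background, dtype=bool)
    if not candidate_background.any():
        raise ValueError("candidate_background is empty")
    vals = img[candidate_background]
    mu, sigma = float(vals.mean()), float(vals.std())
    out = np.zeros_like(candidate_background)
    if sigma == 0:
        return out
    out[candidate_background] = np.abs(img[candidate_background] - mu) > k * sigma
    return out


def background_mask(
    cell_mask: np.ndarray,
    outlier_mask: np.ndarray,
    dilation_radius: int = 3,
) -> np.ndarray:
    """Complement of the dilated union of cell and outlier masks."""
    if cell_mask.shape != outlier_mask.shape:
        raise ValueError("masks must share the scan-grid shape")
    union = cell_mask | outlier_mask
    dilated = morphology.dilation(union, morphology.disk(dilation_radius))
    bg = ~dilated
    if not bg.any():
        raise ValueError("background mask is empty after dilation")
    return bg


def rowwise_background(
    stack: ScanStack, bg_mask: np.ndarray
) -> RowBackground:
    """Average background scattering pattern per scan row.

    Rows with no background scan pixel fall back to the global mean
    background pattern and are flagged.
    """
    if bg_mask.shape != stack.grid_shape:
        raise ValueError("background mask must match the scan grid")
    if not bg_mask.any():
        raise ValueError("background mask is globally empty")
    n_rows = stack.n_rows
    det_shape = stack.frames.shape[2:]
    patterns = np.zeros((n_rows, *det_shape))
    counts = bg_mask.sum(axis=1).astype(int)
    global_mean = stack.frames[bg_mask].mean(axis=0, dtype=np.float64)
    fallback = counts == 0
    for i in range(n_rows):
        if counts[i] > 0:
            patterns[i] = stack.frames[i][bg_mask[i]].mean(axis=0,
                                                           dtype=np.float64)
        else:
            patterns[i] = global_mean
    return RowBackground(patterns=patterns, counts=counts,
                         fallback_rows=fallback)


def subtract_background(stack: ScanStack, row_bg: RowBackground) -> ScanStack:
    """Subtract each scan row's background pattern from its frames.

    The result is floating-point and may be negative; invalid detector
    pixels are left untouched.
    """
    if row_bg.patterns.shape[0] != stack.n_rows:
        raise ValueError("row background does not match the scan grid")
    corrected = stack.frames.astype(np.float64) - row_bg.patterns[:, None]
    invalid = ~stack.valid_mask
    corrected[..., invalid] = stack.frames[..., invalid]
    return ScanStack(
        frames=corrected, valid_mask=stack.valid_mask,
        geometry=stack.geometry, dy_um=stack.dy_um, dz_um=stack.dz_um,
        exposure_ms=stack.exposure_ms, flux=stack.flux,
        scan_index=stack.scan_index,
    )
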