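"""End-to-end orchestration of the scanning-SAXS analysis stages.

Chains the individual stages on a loaded scan:

1. q-map from the stack geometry; dark-field over [q_lo, q_opt] with the
   optimal upper bound selected on the MD curve of a featureless region;
2. ACSAT segmentation + 3σ outlier filter + dilation → background mask;
3. row-wise background subtraction of the raw patterns;
4. point-symmetry completion, azimuthal profiles, orientation and
   anisotropy maps over [q2, q_opt);
5. nuclei detection, watershed cell annotation and per-cell cytoplasmic
   anisotropy distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import background as bg
from . import cells as cellmod
from . import darkfield as df
from .geometry import QMap, complete_point_symmetry, compute_q_map
from .orientation import OrientationMaps, orientation_maps
from .scan_io import PipelineConfig, ScanStack


@dataclass
class ScanAnalysis:
    """Results of one full pipeline pass over a single scan."""

    qmap: QMap
    md_curve: df.MDCurve
    q_opt: float
    darkfield_norm: df.DarkFieldImage
    masks: bg.RegionMasks
    maps: OrientationMaps
    cell_labels: cellmod.CellLabels
    cell_anisotropy: list[cellmod.CellAnisotropy]


def select_q_opt(
    stack: ScanStack,
    qmap: QMap,
    region: df.BackgroundRegion,
    config: PipelineConfig,
) -> tuple[df.MDCurve, float]:
    """MD-curve computation and smoothed-minimum selection of q_opt."""
    curve = df.md_curve(stack, qmap, region, q_lo=config.q_lo,
                        q_step=config.q_step)
    curve = df.smooth_and_select(curve, window=config.smoothing_window)
    return curve, float(curve.q_opt)


def q2_from_mask(qmap: QMap) -> float:
    """Circumscribed-circle q of the region point symmetry cannot fill.

    Artefacts like the beamstop holder bar are recovered by
    point-symmetry completion; only the central disk (its own mirror
    image) stays missing.  q2 is the smallest q that clears every such
    unrecoverable pixel, used as the lower bound of the orientation
    analysis so that azimuthal profiles cover the full circle.
    """
    if qmap.geometry is None:
        raise ValueError("qmap carries no geometry (beam center unknown)")
    probe = np.zeros(qmap.shape)
    _, completed = complete_point_symmetry(
        probe, qmap.valid_mask, qmap.geometry.beam_center
    )
    if completed.all():
        return 0.0
    return float(qmap.q_magnitude[~completed].max())


def analyze_scan(
    stack: ScanStack,
    region: df.BackgroundRegion,
    config: PipelineConfig | None = None,
) -> ScanAnalysis:
    """Run the full analysis chain on one scan."""
    config = config or PipelineConfig()
    qmap = compute_q_map(stack.geometry, stack.valid_mask)
    curve, q_opt = select_q_opt(stack, qmap, region, config)

    field = df.darkfield_image(stack, qmap, config.q_lo, q_opt)
    field_norm = df.normalize01(field)
    cell_mask = bg.acsat_segment(field_norm, a_min=config.a_min,
                                 n_thresholds=config.n_thresholds,
                                 local_pad=config.local_pad)
    outliers = bg.gaussian_outlier_filter(field_norm, ~cell_mask)
    bg_mask = bg.background_mask(cell_mask, outliers,
                                 dilation_radius=config.dilation_radius)
    masks = bg.RegionMasks(cell_mask=cell_mask, outlier_mask=outliers,
                           background_mask=bg_mask, a_min=config.a_min)

    row_bg = bg.rowwise_background(stack, bg_mask)
    corrected = bg.subtract_background(stack, row_bg)

    q2 = config.q2 if config.q2 is not None else q2_from_mask(qmap)
    maps = orientation_maps(corrected, qmap, q2, q_opt,
                            n_bins=config.n_bins)

    nuclei, _ = cellmod.nuclei_mask(field_norm.values, cell_mask,
                                    h=config.nucleus_h, a_nuc=config.a_nuc)
    labels = cellmod.annotate_cells(cell_mask, nuclei, field_norm.values)
    cell_anis = cellmod.cyto_anisotropy(labels, maps.anisotropy, bg_mask,
                                        percentile=config.percentile)
    return ScanAnalysis(
        qmap=qmap, md_curve=curve, q_opt=q_opt, darkfield_norm=field_norm,
        masks=masks, maps=maps, cell_labels=labels,
        cell_anisotropy=cell_anis,
    )
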