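"""Scan container, HDF5 interchange format and pipeline configuration.

A raster scan is stored as a single HDF5 file with layout::

    /frames   uint32/uint64, shape (ny*nz, n_rows, n_cols), row-major scan
              order with y (columns of the scan grid) the fast axis
    /mask     uint8, shape (n_rows, n_cols); 0 = invalid, 255 = valid
    /meta     group with scalar attributes: ny, nz, dy_um, dz_um,
              exposure_ms, flux, energy_kev, distance_m, pixel_size_m,
              beam_center_row, beam_center_col, scan_index

All angles are serialized in degrees, q in nm⁻¹, doses in Gy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

from .geometry import BeamGeometry

_META_KEYS = (
    "ny", "nz", "dy_um", "dz_um", "exposure_ms", "flux", "energy_kev",
    "distance_m", "pixel_size_m", "beam_center_row", "beam_center_col",
    "scan_index",
)


@dataclass
class ScanStack:
    """Raster-scan stack of detector frames plus scan metadata.

    ``frames`` has shape (nz, ny, det_rows, det_cols): the first grid
    axis is the slow scan axis (z, one entry per raster line), the
    second the fast scan axis (y, position within a line), then the
    detector pixels.  Counts are non-negative integers on ingest;
    background subtraction may later make them floating and signed.
    """

    frames: np.ndarray
    valid_mask: np.ndarray
    geometry: BeamGeometry
    dy_um: float
    dz_um: float
    exposure_ms: float
    flux: float
    scan_index: int = 1

    def __post_init__(self) -> None:
        if self.frames.ndim != 4:
            raise ValueError("frames must be (nz, ny, det_rows, det_cols)")
        if self.frames.shape[2:] != tuple(self.geometry.detector_shape):
            raise ValueError(
                f"frame shape {self.frames.shape[2:]} != detector "
                f"{self.geometry.detector_shape}"
            )
        if self.valid_mask.shape != self.frames.shape[2:]:
            raise ValueError("valid_mask must match the detector shape")

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(n_rows, n_cols) = (nz slow lines, ny fast positions)."""
        return self.frames.shape[:2]

    @property
    def n_rows(self) -> int:
        """Number of raster lines (slow z axis)."""
        return self.frames.shape[0]

    @property
    def n_cols(self) -> int:
        """Number of positions per line (fast y axis)."""
        return self.frames.shape[1]


def write_scan(path: str | Path, stack: ScanStack) -> None:
    """Write a ScanStack to the documented HDF5 layout."""
    nz, ny = stack.grid_shape
    with h5py.File(path, "w") as f:
        f.create_dataset(
            "frames",
            data=stack.frames.reshape(ny * nz, *stack.frames.shape[2:]),
            compression="gzip", compression_opts=4,
        )
        f.create_dataset("mask",
                         data=(stack.valid_mask.astype(np.uint8) * 255))
        meta = f.create_group("meta")
        g = stack.geometry
        vals = dict(
            ny=ny, nz=nz, dy_um=stack.dy_um, dz_um=stack.dz_um,
            exposure_ms=stack.exposure_ms, flux=stack.flux,
            energy_kev=g.photon_energy, distance_m=g.sample_detector_distance,
            pixel_size_m=g.pixel_size, beam_center_row=g.beam_center[0],
            beam_center_col=g.beam_center[1], scan_index=stack.scan_index,
        )
        for k in _META_KEYS:
            meta.attrs[k] = vals[k]


def read_scan(path: str | Path) -> ScanStack:
    """Read and validate a scan container written by :func:`write_scan`.

    Raises
    ------
    ValueError
        On a missing dataset, frame-count/grid mismatch, or negative
        counts.
    """
    with h5py.File(path, "r") as f:
        for name in ("frames", "mask", "meta"):
            if name not in f:
                raise ValueError(f"{path}: missing '/{name}' in scan container")
        meta = dict(f["meta"].attrs)
        missing = [k for k in _META_KEYS if k not in meta]
        if missing:
            raise ValueError(f"{path}: missing metadata attributes {missing}")
        frames = f["frames"][()]
        mask = f["mask"][()] > 0
    ny, nz = int(meta["ny"]), int(meta["nz"])
    if frames.shape[0] != ny * nz:
        raise ValueError(
            f"{path}: frame count {frames.shape[0]} != ny*nz = {ny * nz}"
        )
    if np.issubdtype(frames.dtype, np.floating):
        if not np.all(frames[np.isfinite(frames)] >= 0):
            raise ValueError(f"{path}: negative counts on ingest")
        if not np.allclose(frames, np.rint(frames), atol=0):
            raise ValueError(f"{path}: counts must be integer-valued on ingest")
        frames = np.rint(frames).astype(np.uint64)
    elif frames.min() < 0:
        raise ValueError(f"{path}: negative counts on ingest")
    geometry = BeamGeometry(
        photon_energy=float(meta["energy_kev"]),
        sample_detector_distance=float(meta["distance_m"]),
        pixel_size=float(meta["pixel_size_m"]),
        beam_center=(float(meta["beam_center_row"]),
                     float(meta["beam_center_col"])),
        detector_shape=frames.shape[1:],
    )
    return ScanStack(
        frames=frames.reshape(nz, ny, *frames.shape[1:]),
        valid_mask=mask,
        geometry=geometry,
        dy_um=float(meta["dy_um"]),
        dz_um=float(meta["dz_um"]),
        exposure_ms=float(meta["exposure_ms"]),
        flux=float(meta["flux"]),
        scan_index=int(meta["scan_index"]),
    )


@dataclass
class PipelineConfig:
    """Validated knobs of the analysis pipeline.

    Unknown keys in a config mapping are rejected on load to catch
    typos; every field carries the pipeline default.
    """

    q_step: float = 0.003          # nm⁻¹, MD-curve grid spacing
    q_lo: float = 0.0              # nm⁻¹, dark-field lower bound (q0)
    q2: float | None = None        # nm⁻¹, orientation lower bound
    md_region: tuple[int, int, int, int] | None = None  # (row0, col0, a, b)
    smoothing_window: int | str = "auto"
    a_min: int = 500               # scan px, minimum cell area
    n_thresholds: int = 64
    local_pad: int = 5
    dilation_radius: int = 3
    n_bins: int = 72               # azimuthal bins (5° each)
    percentile: float = 99.0       # background-anisotropy threshold
    nucleus_h: float = 0.2         # h-maxima contrast depth, normalized
    a_nuc: int | None = None       # defaults to a_min // 2
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.q_step <= 0:
            raise ValueError("q_step must be > 0")
        if self.n_bins < 8:
            raise ValueError("n_bins must be >= 8")
        if not 0 < self.percentile <= 100:
            raise ValueError("percentile must be in (0, 100]")
        if not 0 < self.nucleus_h < 1:
            raise ValueError("nucleus_h must be in (0, 1)")
        if self.a_nuc is None:
            self.a_nuc = max(1, self.a_min // 2)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)
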