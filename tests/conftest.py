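"""Shared fixtures: small synthetic scenes sized for fast tests."""

from __future__ import annotations

import numpy as np
import pytest

import scansaxs as sx


@pytest.fixture(scope="session")
def small_scene() -> sx.SceneSpec:
    """Compact two-cell scene on a 32x32 grid with a 64x64 detector.

    The doubled pixel size keeps the q-range (~3 nm^-1) of the default
    scene while shrinking the detector for speed.
    """
    return sx.SceneSpec(
        n_rows=32, n_cols=32, detector_shape=(64, 64),
        beam_center=(31.5, 31.5), pixel_size_m=2.4e-3, seed=1,
        cells=(
            sx.CellSpec(center=(10.0, 10.0), axes=(8.0, 6.0)),
            sx.CellSpec(center=(22.0, 20.0), axes=(7.0, 7.0),
                        fiber_angle_deg=-45.0),
        ),
    )


@pytest.fixture(scope="session")
def small_scan(small_scene):
    """One simulated pass over the small scene, with its ground truth."""
    return sx.generate_scan(small_scene, scan_index=1)


@pytest.fixture(scope="session")
def default_scan():
    """One pass over the default reference scene (64x64 grid)."""
    return sx.generate_scan(sx.SceneSpec(seed=21), scan_index=1)


@pytest.fixture
def flat_qmap() -> sx.QMap:
    """Fully valid q-map of a tiny centered detector."""
    geom = sx.BeamGeometry(
        photon_energy=15.0, sample_detector_distance=1.89,
        pixel_size=2.4e-3, beam_center=(15.5, 15.5),
        detector_shape=(32, 32),
    )
    return sx.compute_q_map(geom)
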