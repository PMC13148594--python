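"""Segmentation, outlier filtering and row-wise background subtraction."""

import numpy as np
import pytest
from scipy import ndimage

import scansaxs as sx
from scansaxs.darkfield import DarkFieldImage
from scansaxs.scan_io import ScanStack


def _disc(shape, center, radius):
    rows = np.arange(shape[0])[:, None] - center[0]
    cols = np.arange(shape[1])[None, :] - center[1]
    return rows ** 2 + cols ** 2 <= radius ** 2


def _norm_image(values):
    return sx.normalize01(DarkFieldImage(np.asarray(values, float), (0, 1)))


class TestAcsatSegment:
    def test_two_bright_discs_recovered(self):
        img = np.zeros((40, 40))
        d1 = _disc((40, 40), (10, 10), 6)
        d2 = _disc((40, 40), (28, 27), 7)
        img[d1] = 1.0
        img[d2] = 1.0
        mask = sx.acsat_segment(_norm_image(img), a_min=20)
        assert np.array_equal(mask, d1 | d2)

    def test_area_filter_boundary(self):
        img = np.zeros((30, 30))
        blob = _disc((30, 30), (15, 15), 4)  # 49 pixels
        img[blob] = 1.0
        area = int(blob.sum())
        with pytest.warns(UserWarning):
            mask = sx.acsat_segment(_norm_image(img), a_min=area + 1)
        assert not mask.any()

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(8)
        img = rng.random((40, 40)) * 0.1
        img[_disc((40, 40), (14, 20), 8)] += 1.0
        base = sx.acsat_segment(_norm_image(img), a_min=30)
        scaled = sx.acsat_segment(
            DarkFieldImage(3.7 * img + 11.0, (0, 1), normalized=True),
            a_min=30,
        )
        assert np.array_equal(base, scaled)

    def test_simulator_ground_truth_iou(self, default_scan):
        stack, truth = default_scan
        qmap = sx.compute_q_map(stack.geometry, stack.valid_mask)
        image = sx.normalize01(sx.darkfield_image(stack, qmap, 0.0, 1.0))
        mask = sx.acsat_segment(image, a_min=200)
        iou = (mask & truth.cell_mask).sum() / (mask | truth.cell_mask).sum()
        assert iou >= 0.8


class TestGaussianOutlierFilter:
    def test_constant_background_no_outliers(self):
        img = np.full((10, 10), 0.2)
        out = sx.gaussian_outlier_filter(img, np.ones((10, 10), bool))
        assert not out.any()

    def test_extreme_pixel_flagged(self):
        rng = np.random.default_rng(9)
        img = rng.normal(0.0, 1.0, (20, 20))
        img[4, 7] = 10.0 * img.std() + img.mean()
        out = sx.gaussian_outlier_filter(img, np.ones((20, 20), bool))
        assert out[4, 7]

    def test_three_sigma_rate_on_standard_normal(self):
        rng = np.random.default_rng(10)
        img = rng.normal(0.0, 1.0, (100, 100))
        out = sx.gaussian_outlier_filter(img, np.ones((100, 100), bool), k=3)
        assert out.mean() == pytest.approx(0.0027, abs=0.002)

    def test_empty_candidate_rejected(self):
        with pytest.raises(ValueError):
            sx.gaussian_outlier_filter(np.zeros((4, 4)),
                                       np.zeros((4, 4), bool))


class TestBackgroundMask:
    def test_empty_inputs_give_full_grid(self):
        empty = np.zeros((12, 12), bool)
        assert sx.background_mask(empty, empty).all()

    def test_single_pixel_excludes_disc(self):
        cell = np.zeros((15, 15), bool)
        cell[7, 7] = True
        bg = sx.background_mask(cell, np.zeros_like(cell), dilation_radius=3)
        excluded = ~bg
        assert np.array_equal(excluded, _disc((15, 15), (7, 7), 3))

    def test_matches_bruteforce_max_filter(self):
        cell = np.zeros((16, 16), bool)
        out = np.zeros((16, 16), bool)
        cell[2, 3] = cell[9, 12] = cell[14, 1] = True
        out[5, 8] = out[0, 15] = True
        bg = sx.background_mask(cell, out, dilation_radius=3)
        union = cell | out
        brute = np.zeros_like(union)
        for i in range(16):
            for j in range(16):
                for di in range(-3, 4):
                    for dj in range(-3, 4):
                        if di * di + dj * dj <= 9:
                            r, c = i + di, j + dj
                            if 0 <= r < 16 and 0 <= c < 16 and union[r, c]:
                                brute[i, j] = True
        assert np.array_equal(bg, ~brute)

    def test_never_intersects_dilated_union(self, default_scan):
        stack, truth = default_scan
        out = np.zeros_like(truth.cell_mask)
        bg = sx.background_mask(truth.cell_mask, out, dilation_radius=3)
        from skimage import morphology

        dil = morphology.dilation(truth.cell_mask, morphology.disk(3))
        assert not (bg & dil).any()


def _stack(frames, det=(8, 8)):
    geom = sx.BeamGeometry(15.0, 1.89, 2e-3, (3.5, 3.5), det)
    return ScanStack(frames=frames, valid_mask=np.ones(det, bool),
                     geometry=geom, dy_um=0.5, dz_um=0.5, exposure_ms=2.0,
                     flux=1e12)


class TestRowwiseBackground:
    def test_identical_frames_reproduce_frame(self):
        frame = np.arange(64, dtype=np.uint32).reshape(8, 8)
        frames = np.broadcast_to(frame, (3, 4, 8, 8)).copy()
        bg_mask = np.ones((3, 4), bool)
        rb = sx.rowwise_background(_stack(frames), bg_mask)
        for i in range(3):
            assert np.allclose(rb.patterns[i], frame)
        assert not rb.fallback_rows.any()

    def test_empty_row_falls_back_to_global_mean(self):
        rng = np.random.default_rng(13)
        frames = rng.poisson(5.0, (3, 4, 8, 8)).astype(np.uint32)
        bg_mask = np.ones((3, 4), bool)
        bg_mask[1] = False
        rb = sx.rowwise_background(_stack(frames), bg_mask)
        assert rb.fallback_rows[1] and not rb.fallback_rows[0]
        global_mean = frames[bg_mask].mean(axis=0)
        assert np.allclose(rb.patterns[1], global_mean)

    def test_matches_bruteforce_accumulation(self):
        rng = np.random.default_rng(14)
        frames = rng.poisson(5.0, (3, 5, 8, 8)).astype(np.uint32)
        bg_mask = rng.random((3, 5)) > 0.3
        bg_mask[:, 0] = True  # keep every row populated
        rb = sx.rowwise_background(_stack(frames), bg_mask)
        for i in range(3):
            acc = np.zeros((8, 8))
            n = 0
            for j in range(5):
                if bg_mask[i, j]:
                    acc += frames[i, j]
                    n += 1
            assert np.allclose(rb.patterns[i], acc / n)

    def test_globally_empty_background_rejected(self):
        frames = np.zeros((2, 2, 8, 8), np.uint32)
        with pytest.raises(ValueError):
            sx.rowwise_background(_stack(frames), np.zeros((2, 2), bool))


class TestSubtractBackground:
    def test_self_subtraction_zeroes_background_rows(self):
        rng = np.random.default_rng(15)
        frames = rng.poisson(20.0, (3, 6, 8, 8)).astype(np.uint32)
        bg_mask = np.ones((3, 6), bool)
        stack = _stack(frames)
        rb = sx.rowwise_background(stack, bg_mask)
        corr = sx.subtract_background(stack, rb)
        for i in range(3):
            assert corr.frames[i].mean() == pytest.approx(0.0, abs=1e-9)

    def test_linearity(self):
        rng = np.random.default_rng(16)
        frames = rng.poisson(9.0, (2, 3, 8, 8)).astype(np.uint32)
        stack = _stack(frames)
        rb = sx.rowwise_background(stack, np.ones((2, 3), bool))
        once = sx.subtract_background(stack, rb)
        twice = sx.subtract_background(once, rb)
        doubled = sx.RowBackground(2 * rb.patterns, rb.counts,
                                   rb.fallback_rows)
        direct = sx.subtract_background(stack, doubled)
        assert np.allclose(twice.frames, direct.frames)

    def test_row_drift_removed_on_simulator(self, small_scene):
        import dataclasses

        spec = dataclasses.replace(small_scene, drift_amplitude=0.2,
                                   stripe_amplitude=0.0, cells=(), seed=6)
        stack, _ = sx.generate_scan(spec)
        qmap = sx.compute_q_map(stack.geometry, stack.valid_mask)
        bg_mask = np.ones(stack.grid_shape, bool)
        rb = sx.rowwise_background(stack, bg_mask)
        corr = sx.subtract_background(stack, rb)
        before = sx.darkfield_image(stack, qmap, 0.0, 1.0).values
        after_rows = np.array([
            corr.frames[i][..., stack.valid_mask].sum(axis=-1).mean()
            for i in range(stack.n_rows)
        ])
        injected = before.mean(axis=1).max() - before.mean(axis=1).min()
        residual = after_rows.max() - after_rows.min()
        assert residual < 0.05 * injected
        # dark-field of the corrected background is centred on zero
        assert abs(after_rows.mean()) < 0.01 * before.mean()
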