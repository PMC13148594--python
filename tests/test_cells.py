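"""Cell annotation, cytoplasmic anisotropy, decay, dose and flow."""

import numpy as np
import pytest

import scansaxs as sx
from scansaxs.cells import CellAnisotropy


def _disc(shape, center, radius):
    rows = np.arange(shape[0])[:, None] - center[0]
    cols = np.arange(shape[1])[None, :] - center[1]
    return rows ** 2 + cols ** 2 <= radius ** 2


class TestNucleiMask:
    def test_bright_plateau_detected(self):
        img = np.zeros((30, 30))
        cell = _disc((30, 30), (15, 15), 10)
        img[cell] = 0.5
        img[_disc((30, 30), (15, 15), 4)] = 0.9
        nuclei, flagged = sx.nuclei_mask(img, cell, h=0.2, a_nuc=5)
        assert nuclei.any() and not flagged
        assert nuclei.sum() == _disc((30, 30), (15, 15), 4).sum()

    def test_flat_cell_flagged(self):
        img = np.zeros((20, 20))
        cell = _disc((20, 20), (10, 10), 7)
        img[cell] = 0.5
        nuclei, flagged = sx.nuclei_mask(img, cell, h=0.2, a_nuc=3)
        assert not nuclei.any()
        assert len(flagged) == 1

    def test_simulator_nuclei_centroids(self, default_scan):
        from scipy import ndimage

        stack, truth = default_scan
        qmap = sx.compute_q_map(stack.geometry, stack.valid_mask)
        image = sx.normalize01(sx.darkfield_image(stack, qmap, 0.0, 1.0))
        nuclei, flagged = sx.nuclei_mask(image.values, truth.cell_mask,
                                         h=0.2, a_nuc=10)
        assert not flagged
        for lab in (1, 2, 3):
            gt_nuc = truth.nuclei_mask & (truth.labels == lab)
            found = nuclei & (truth.labels == lab)
            assert found.any()
            gt_c = np.array(ndimage.center_of_mass(gt_nuc))
            got_c = np.array(ndimage.center_of_mass(found))
            assert np.linalg.norm(gt_c - got_c) < 3.0

    def test_invalid_contrast_depth(self):
        with pytest.raises(ValueError):
            sx.nuclei_mask(np.zeros((5, 5)), np.ones((5, 5), bool), h=1.5)


class TestAnnotateCells:
    def test_two_disjoint_discs(self):
        shape = (40, 40)
        d1, d2 = _disc(shape, (12, 10), 7), _disc(shape, (28, 29), 8)
        nuclei = _disc(shape, (12, 10), 2) | _disc(shape, (28, 29), 2)
        labels = sx.annotate_cells(d1 | d2, nuclei)
        assert labels.n_cells == 2
        vals = {labels.labels[12, 10], labels.labels[28, 29]}
        assert vals == {1, 2}
        for mask in (d1, d2):
            lab = labels.labels[mask]
            assert len(set(lab.tolist())) == 1  # each disc one label

    def test_touching_discs_split_between_nuclei(self):
        shape = (30, 50)
        d1, d2 = _disc(shape, (15, 18), 10), _disc(shape, (15, 32), 10)
        joined = d1 | d2
        nuclei = _disc(shape, (15, 18), 3) | _disc(shape, (15, 32), 3)
        labels = sx.annotate_cells(joined, nuclei)
        assert labels.n_cells == 2
        # labels partition the joined mask
        assert np.array_equal(labels.labels > 0, joined)
        # boundary falls between the nuclei
        l1 = labels.labels[15, 18]
        l2 = labels.labels[15, 32]
        assert l1 != l2
        assert labels.labels[15, 22] == l1
        assert labels.labels[15, 28] == l2

    def test_marker_conservation_with_fallback_seed(self):
        shape = (40, 40)
        d1, d2 = _disc(shape, (12, 10), 7), _disc(shape, (28, 29), 8)
        nuclei = _disc(shape, (12, 10), 2)  # second disc has no nucleus
        labels = sx.annotate_cells(d1 | d2, nuclei)
        assert labels.n_cells == 2
        assert len(labels.flagged) == 1

    def test_empty_mask_gives_empty_labels(self):
        labels = sx.annotate_cells(np.zeros((10, 10), bool),
                                   np.zeros((10, 10), bool))
        assert labels.n_cells == 0
        assert (labels.labels == 0).all()

    def test_labels_partition_cell_mask(self, default_scan):
        _, truth = default_scan
        labels = sx.annotate_cells(truth.cell_mask, truth.nuclei_mask)
        assert np.array_equal(labels.labels > 0, truth.cell_mask)


class TestCytoAnisotropy:
    def _labels(self, shape, cell, nuclei):
        return sx.CellLabels(
            labels=cell.astype(np.int32), nuclei_mask=nuclei,
            bounding_boxes={1: (0, 0, *shape)},
        )

    def test_flat_background_selects_all_cytoplasm(self):
        shape = (20, 20)
        cell = _disc(shape, (10, 10), 6)
        nuclei = _disc(shape, (10, 10), 2)
        anis = np.full(shape, 0.1)
        anis[cell] = 0.5
        bg = ~_disc(shape, (10, 10), 9)
        out = sx.cyto_anisotropy(self._labels(shape, cell, nuclei), anis, bg)
        (rec,) = out
        assert rec.n_selected == int((cell & ~nuclei).sum())
        assert rec.mean == pytest.approx(0.5)

    def test_fully_nuclear_cell_empty_record(self):
        shape = (20, 20)
        cell = _disc(shape, (10, 10), 4)
        out = sx.cyto_anisotropy(self._labels(shape, cell, cell),
                                 np.full(shape, 0.5), ~cell)
        assert out[0].n_selected == 0
        assert np.isnan(out[0].mean)

    def test_percentile_matches_sort_and_interpolate(self):
        rng = np.random.default_rng(20)
        bg_vals = rng.random(136)
        # manual linear-interpolation percentile of the background values
        s = np.sort(bg_vals)
        rank = 0.99 * (len(s) - 1)
        lo, frac = int(rank), rank - int(rank)
        expected = s[lo] * (1 - frac) + s[lo + 1] * frac
        shape = (137, 1)
        cell = np.zeros(shape, bool)
        cell[0, 0] = True
        labels = sx.CellLabels(labels=cell.astype(np.int32),
                               nuclei_mask=np.zeros(shape, bool),
                               bounding_boxes={1: (0, 0, 1, 1)})
        anis = np.zeros(shape)
        anis[1:, 0] = bg_vals
        # threshold realised through selection: cell pixel above/below tau
        anis[0, 0] = expected + 1e-9
        assert sx.cyto_anisotropy(labels, anis, ~cell)[0].n_selected == 1
        anis[0, 0] = expected - 1e-9
        assert sx.cyto_anisotropy(labels, anis, ~cell)[0].n_selected == 0

    def test_selection_shrinks_as_percentile_rises(self, default_scan):
        stack, truth = default_scan
        rng = np.random.default_rng(22)
        anis = np.clip(rng.normal(0.3, 0.15, truth.cell_mask.shape), 0, 1)
        labels = sx.annotate_cells(truth.cell_mask, truth.nuclei_mask)
        bg = ~truth.cell_mask
        sizes = []
        for pct in (50, 90, 99):
            recs = sx.cyto_anisotropy(labels, anis, bg, percentile=pct)
            sizes.append(sum(r.n_selected for r in recs))
        assert sizes[0] >= sizes[1] >= sizes[2]


class TestAnisotropyDecay:
    def _rec(self, label, values):
        values = np.asarray(values, float)
        mean = float(values.mean()) if values.size else float("nan")
        return CellAnisotropy(label=label, values=values, mean=mean,
                              q25=0, q50=0, q75=0, n_selected=len(values))

    def test_identical_distributions_zero(self):
        a = self._rec(1, [0.2, 0.4, 0.6])
        assert sx.anisotropy_decay(a, a) == 0.0

    def test_difference_of_means(self):
        first = self._rec(1, [0.30, 0.30])
        second = self._rec(1, [0.18, 0.18])
        assert sx.anisotropy_decay(first, second) == pytest.approx(0.12)

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sx.anisotropy_decay(self._rec(1, [0.3]), self._rec(2, [0.2]))

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValueError):
            sx.anisotropy_decay(self._rec(1, [0.3]), self._rec(1, []))


class TestRadiationDose:
    # operating table of the reference beamline setup: step sizes (um),
    # exposure (ms) -> dose in 1e7 Gy
    TABLE = [
        (0.2, 0.2, 2.0, 2.09),
        (0.2, 0.5, 2.0, 0.84),
        (0.2, 0.5, 5.0, 2.09),
        (0.5, 0.5, 2.0, 0.33),
        (0.5, 0.5, 5.0, 0.84),
    ]

    @pytest.mark.parametrize("dy, dz, t_ms, expected", TABLE)
    def test_reference_operating_conditions(self, dy, dz, t_ms, expected):
        dose = sx.radiation_dose(sx.DoseParams(
            mu_over_rho=1.60, i0=1.09e12, photon_energy=15.0,
            exposure=t_ms * 1e-3, dy=dy, dz=dz,
        ))
        assert dose / 1e7 == pytest.approx(expected, abs=0.01)

    def test_linear_in_exposure_and_area(self):
        base = sx.DoseParams(exposure=2e-3, dy=0.2, dz=0.2)
        d = sx.radiation_dose(base)
        double_t = sx.DoseParams(exposure=4e-3, dy=0.2, dz=0.2)
        assert sx.radiation_dose(double_t) == pytest.approx(2 * d)
        quad_area = sx.DoseParams(exposure=2e-3, dy=0.4, dz=0.4)
        assert sx.radiation_dose(quad_area) == pytest.approx(d / 4)

    def test_invariant_under_flux_time_tradeoff(self):
        a = sx.DoseParams(i0=1e12, exposure=2e-3)
        b = sx.DoseParams(i0=2e12, exposure=1e-3)
        assert sx.radiation_dose(a) == pytest.approx(sx.radiation_dose(b))

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ValueError):
            sx.DoseParams(dy=0.0)


class TestFlowVelocity:
    def test_printed_channel_velocities(self):
        # 1.5 mm x 20 um channel: 20 uL/h ~ 0.185 mm/s, 1000 uL/h ~ 9.26
        assert sx.mean_flow_velocity(20.0) == pytest.approx(0.185, abs=0.001)
        assert sx.mean_flow_velocity(1000.0) == pytest.approx(9.26, abs=0.01)

    def test_zero_flow(self):
        assert sx.mean_flow_velocity(0.0) == 0.0

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            sx.mean_flow_velocity(10.0, width_mm=0.0)
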