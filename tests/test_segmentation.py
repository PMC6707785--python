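"""Nucleus detection, cytoplasm expansion, marker refinement, measurement."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage
from skimage.filters import gaussian

from imclesion.image import MultichannelImage
from imclesion.segmentation import (
    SegmentationParams,
    expand_cytoplasm,
    measure_cells,
    refine_with_markers,
    segment_and_measure,
    segment_nuclei,
)
from imclesion.validation import segmentation_scores


def _disk_image(centers, radius, size=60, value=30.0):
    yy, xx = np.mgrid[:size, :size]
    img = np.zeros((size, size))
    for cy, cx in centers:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = value
    return img


class TestSegmentNuclei:
    def test_two_separated_disks(self):
        dna = _disk_image([(20, 20), (20, 40)], radius=4)
        labels = segment_nuclei(dna, SegmentationParams())
        assert labels.max() == 2
        for cy, cx in [(20, 20), (20, 40)]:
            com = ndimage.center_of_mass(labels == labels[cy, cx])
            assert np.hypot(com[0] - cy, com[1] - cx) < 1.0

    def test_blank_image_yields_zero_labels(self):
        assert segment_nuclei(np.zeros((30, 30))).max() == 0

    def test_unknown_threshold_method_errors(self):
        with pytest.raises(ValueError, match="threshold"):
            segment_nuclei(np.ones((10, 10)), SegmentationParams(nucleus_threshold="magic"))

    def test_dumbbell_split_into_two(self):
        # centers 1.2*(r1+r2) apart: merged after blur, split by watershed
        r = 4
        dna = _disk_image([(30, 26), (30, 26 + int(1.2 * 2 * r))], radius=r)
        params = SegmentationParams(peak_min_distance_px=r)
        blurred = gaussian(dna, sigma=params.gaussian_sigma_px, preserve_range=True)
        # peak-count oracle on the blurred fixture: two local maxima remain
        from skimage.feature import peak_local_max

        peaks = peak_local_max(blurred, min_distance=r)
        assert len(peaks) == 2
        labels = segment_nuclei(dna, params)
        assert labels.max() == 2

    def test_min_area_filter_drops_fragments(self):
        dna = _disk_image([(15, 15)], radius=4)
        dna[2:4, 2:4] = 30.0  # 4-pixel fragment: below default min area
        labels = segment_nuclei(dna, SegmentationParams(min_nucleus_area_px=9))
        assert labels.max() == 1
        assert labels[2, 2] == 0


class TestExpandCytoplasm:
    def test_radius_zero_is_identity(self):
        labels = np.zeros((10, 10), int)
        labels[4:6, 4:6] = 1
        np.testing.assert_array_equal(expand_cytoplasm(labels, 0), labels)

    def test_negative_radius_errors(self):
        with pytest.raises(ValueError):
            expand_cytoplasm(np.zeros((5, 5), int), -1)

    def test_single_nucleus_matches_distance_transform_oracle(self):
        labels = np.zeros((21, 21), int)
        labels[10, 10] = 1
        out = expand_cytoplasm(labels, 2)
        dist = np.hypot(*np.mgrid[-10:11, -10:11])
        np.testing.assert_array_equal(out == 1, dist <= 2)

    def test_contested_pixels_go_to_nearer_nucleus(self):
        labels = np.zeros((15, 20), int)
        labels[7, 5] = 1
        labels[7, 10] = 2
        out = expand_cytoplasm(labels, 4)
        yy, xx = np.mgrid[:15, :20]
        d1 = np.hypot(yy - 7, xx - 5)
        d2 = np.hypot(yy - 7, xx - 10)
        both = out > 0
        assert (out[both & (d1 < d2)] == 1).all()
        assert (out[both & (d2 < d1)] == 2).all()
        # expansions meet but never overlap: labels partition the pixels
        assert set(np.unique(out)) == {0, 1, 2}


def _refinement_fixture():
    """Two nuclei; cell 1 sits in a CD3+ membrane blob extending past the
    default expansion, cell 2 is CD3-negative."""
    size = 40
    yy, xx = np.mgrid[:size, :size]
    nuclei = np.zeros((size, size), int)
    nuclei[(yy - 15) ** 2 + (xx - 12) ** 2 <= 9] = 1
    nuclei[(yy - 15) ** 2 + (xx - 30) ** 2 <= 9] = 2
    cd3 = np.zeros((size, size))
    cd3[(yy - 15) ** 2 + (xx - 12) ** 2 <= 81] = 1.2  # radius 9 blob
    norm = MultichannelImage({"CD3": cd3})
    cells = expand_cytoplasm(nuclei, 3)
    params = SegmentationParams(refinement_markers=[(("CD3",), 0.5)])
    return nuclei, cells, norm, params


class TestRefinement:
    def test_positive_cell_refits_to_marker_region(self):
        nuclei, cells, norm, params = _refinement_fixture()
        out = refine_with_markers(cells, nuclei, norm, params)
        # footprint equals the CD3+ component minus territory of cell 2
        cd3_pos = norm["CD3"] >= 0.5
        expected = cd3_pos & (cells != 2)
        np.testing.assert_array_equal(out == 1, expected | (nuclei == 1))
        # the CD3-negative neighbor keeps its default expansion
        np.testing.assert_array_equal(out == 2, cells == 2)

    def test_no_positive_cells_is_identity(self):
        nuclei, cells, norm, params = _refinement_fixture()
        params = SegmentationParams(refinement_markers=[(("CD3",), 99.0)])
        np.testing.assert_array_equal(
            refine_with_markers(cells, nuclei, norm, params), cells
        )

    def test_nucleus_always_retained(self):
        nuclei, cells, norm, params = _refinement_fixture()
        out = refine_with_markers(cells, nuclei, norm, params)
        assert np.all(out[nuclei > 0] == nuclei[nuclei > 0])

    def test_unknown_marker_errors(self):
        nuclei, cells, norm, _ = _refinement_fixture()
        params = SegmentationParams(refinement_markers=[(("CD99",), 0.5)])
        with pytest.raises(KeyError, match="CD99"):
            refine_with_markers(cells, nuclei, norm, params)


class TestMeasureCells:
    def _images(self, shape, **channels):
        raw = MultichannelImage({k: v.copy() for k, v in channels.items()})
        return raw, raw

    def test_arithmetic_mean_over_footprint(self):
        labels = np.zeros((4, 4), int)
        labels[0, 0] = labels[0, 1] = 1
        cd3 = np.zeros((4, 4))
        cd3[0, 0], cd3[0, 1] = 0.5, 1.5
        raw, norm = self._images((4, 4), CD3=cd3)
        table = measure_cells(labels, labels, raw, norm)
        assert table.loc[0, "norm_CD3"] == pytest.approx(1.0)

    def test_zero_cells_gives_empty_table_with_header(self):
        raw, norm = self._images((5, 5), CD3=np.zeros((5, 5)))
        table = measure_cells(np.zeros((5, 5), int), np.zeros((5, 5), int), raw, norm)
        assert table.empty
        assert {"cell_id", "raw_CD3", "norm_CD3", "cell_area_px"} <= set(table.columns)

    def test_orphan_cell_label_is_corrupt(self):
        nuclei = np.zeros((5, 5), int)
        cells = np.zeros((5, 5), int)
        cells[2, 2] = 3
        raw, norm = self._images((5, 5), CD3=np.zeros((5, 5)))
        with pytest.raises(ValueError, match="corrupt"):
            measure_cells(nuclei, cells, raw, norm)

    def test_means_match_per_label_accumulation_oracle(self, rng):
        dna = _disk_image([(12, 12), (12, 40), (40, 12), (40, 40), (26, 26)], 4)
        chan = rng.uniform(0, 5, dna.shape)
        raw = MultichannelImage({"DNA": dna, "CD3": chan})
        table, nuclei, cells = segment_and_measure(raw, raw)
        for _, row in table.iterrows():
            sel = cells == row.cell_id
            assert row["raw_CD3"] == pytest.approx(chan[sel].mean(), abs=1e-9)
            cy, cx = np.argwhere(sel).mean(axis=0)
            assert row["y_px"] == pytest.approx(cy)
            assert row["x_px"] == pytest.approx(cx)

    def test_permutation_invariance_of_measurement(self, rng):
        dna = _disk_image([(12, 12), (12, 40), (40, 26)], 4)
        chan = rng.uniform(0, 5, dna.shape)
        raw = MultichannelImage({"DNA": dna, "CD3": chan})
        table, nuclei, cells = segment_and_measure(raw, raw)
        perm = {1: 3, 2: 1, 3: 2, 0: 0}
        nuclei_p = np.vectorize(perm.get)(nuclei)
        cells_p = np.vectorize(perm.get)(cells)
        table_p = measure_cells(nuclei_p, cells_p, raw, raw)
        a = table.assign(cell_id=table.cell_id.map(perm)).sort_values("cell_id").reset_index(drop=True)
        b = table_p.sort_values("cell_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


class TestLabelMapInvariants:
    def test_nucleus_subset_and_disjointness_after_every_stage(self, default_result):
        _, _, result, _ = default_result
        nuc, cell = result.nucleus_labels, result.cell_labels
        inside = nuc > 0
        assert np.array_equal(cell[inside], nuc[inside])  # nucleus ⊆ cell, same id

    def test_recall_precision_on_default_scene(self, default_scene, default_result):
        _, _, truth = default_scene
        _, _, result, _ = default_result
        recall, precision = segmentation_scores(truth.cells, result.cells)
        assert recall >= 0.95
        assert precision >= 0.95
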