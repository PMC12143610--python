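"""Segmentation and focus-calling rules, checked against planted truth."""

import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from cytofoci import imaging, synth
from cytofoci.imaging import SegmentationResult


def _manual_segmentation(shape=(40, 60)):
    """Hand-built one-cell segmentation: nucleus label 1 in a square,
    cytoplasm label 1 in a surrounding frame."""
    nuc = np.zeros(shape, dtype=np.int32)
    nuc[15:25, 20:30] = 1
    cyt = np.zeros(shape, dtype=np.int32)
    cyt[5:35, 10:40] = 1
    cyt[nuc > 0] = 0
    cells = pd.DataFrame(
        [dict(cell_id=1, nucleus_area=100, cytoplasm_area=int((cyt == 1).sum()),
              touches_border=False)]
    )
    return SegmentationResult(nuc, cyt, cells)


def _component(pixels):
    pix = np.asarray(pixels, dtype=int)
    return imaging.SpotComponent(
        pixels=pix, area=len(pix),
        centroid=(float(pix[:, 0].mean()), float(pix[:, 1].mean())),
    )


class TestSegmentNuclei:
    def test_counts_match_truth(self, clean_field):
        fov, truth = clean_field
        labels = imaging.segment_nuclei(fov.nucleus_stain)
        assert labels.max() == truth.nucleus_labels.max()

    def test_blank_image_empty_mask(self):
        assert imaging.segment_nuclei(np.zeros((32, 32))).max() == 0

    def test_touching_nuclei_merge_without_splitting(self):
        # the declared policy: touching components are not declumped
        img = np.zeros((60, 60))
        rr, cc = draw_ellipse(30, 20, 9, 6)
        img[rr, cc] = 100.0
        rr, cc = draw_ellipse(30, 31, 9, 6)
        img[rr, cc] = 100.0
        labels = imaging.segment_nuclei(img)
        assert labels.max() == 1

    def test_small_components_removed(self):
        img = np.zeros((40, 40))
        img[5:7, 5:7] = 100.0      # 4 px: below min area
        img[20:32, 20:32] = 100.0  # 144 px: kept
        labels = imaging.segment_nuclei(img, min_nucleus_area=50)
        assert labels.max() == 1
        assert labels[6, 6] == 0


class TestSegmentCytoplasm:
    def test_single_cell_territory_matches_truth(self):
        p = synth.ImagingTruthParams(n_cells=1, psf_sigma=0.0, noise_sd=0.0, seed=3)
        fov, truth = synth.generate_field(p, 0.0, "xray", 0)
        nuc = imaging.segment_nuclei(fov.nucleus_stain)
        cyt = imaging.segment_cytoplasm(fov.cytoplasm_stain, nuc)
        truth_ring = (truth.cell_labels == 1) & (truth.nucleus_labels == 0)
        got = cyt == 1
        iou = (got & truth_ring).sum() / (got | truth_ring).sum()
        assert iou >= 0.95

    def test_empty_nucleus_mask_gives_empty_territories(self):
        stain = np.full((32, 32), 50.0)
        cyt = imaging.segment_cytoplasm(stain, np.zeros((32, 32), dtype=np.int32))
        assert cyt.max() == 0

    def test_adjacent_cells_partition_shared_stain(self):
        # two nuclei inside one connected stained blob: territories must
        # tile the blob with no doubly-assigned pixel and split it at
        # the nearest-nucleus boundary
        shape = (50, 80)
        nuc = np.zeros(shape, dtype=np.int32)
        rr, cc = draw_disk((25, 25), 8, shape=shape)
        nuc[rr, cc] = 1
        rr, cc = draw_disk((25, 55), 8, shape=shape)
        nuc[rr, cc] = 2
        stain = np.zeros(shape)
        stain[10:40, 10:70] = 60.0
        cyt = imaging.segment_cytoplasm(stain, nuc, threshold=30.0)
        fg = (stain > 30.0) & (nuc == 0)
        assert (cyt[fg] > 0).all()
        assert cyt[35, 15] == 1 and cyt[35, 65] == 2
        assert (cyt[nuc > 0] == 0).all()

    def test_orphan_stain_stays_unlabelled(self):
        shape = (60, 60)
        nuc = np.zeros(shape, dtype=np.int32)
        rr, cc = draw_disk((15, 15), 6, shape=shape)
        nuc[rr, cc] = 1
        stain = np.zeros(shape)
        stain[5:25, 5:25] = 60.0
        stain[40:55, 40:55] = 60.0  # stained region with no nucleus
        cyt = imaging.segment_cytoplasm(stain, nuc, threshold=30.0)
        assert cyt[45:55, 45:55].max() == 0

    def test_shape_mismatch_is_error(self):
        with pytest.raises(ValueError, match="shape"):
            imaging.segment_cytoplasm(np.zeros((10, 10)), np.zeros((8, 8), dtype=int))


class TestDetect:
    def test_blank_image_no_components(self):
        assert imaging.detect_dsdna_signals(np.zeros((64, 64))) == []

    def test_single_planted_component_exact_area(self):
        img = np.zeros((50, 50))
        offs = synth.digital_disk(7)
        img[25 + offs[:, 0], 25 + offs[:, 1]] = 160.0
        comps = imaging.detect_dsdna_signals(img)
        assert len(comps) == 1
        assert comps[0].area == 7

    def test_recall_on_seeded_fields(self, default_params):
        stats = []
        for i in range(5):
            fov, truth = synth.generate_field(default_params, 8.0, "carbon", 10 + i)
            _, foci, _ = imaging.process_field(fov)
            stats.append(imaging.evaluate_detection(foci, truth))
        recall = sum(s["n_matched"] for s in stats) / sum(s["n_truth"] for s in stats)
        assert recall >= 0.95


class TestFilterFoci:
    def test_small_component_rejected(self):
        seg = _manual_segmentation()
        comp = _component([(8, 12), (8, 13), (9, 12), (9, 13)])  # 4 px in cytoplasm
        (focus,) = imaging.filter_cytoplasmic_foci([comp], seg)
        assert not focus.accepted and focus.reason == "too_small"

    def test_five_pixel_component_accepted(self):
        # the size cutoff is inclusive: >= 5 px counts
        seg = _manual_segmentation()
        comp = _component([(8, 12), (8, 13), (9, 12), (9, 13), (8, 14)])
        (focus,) = imaging.filter_cytoplasmic_foci([comp], seg)
        assert focus.accepted and focus.cell_id == 1

    def test_any_nucleus_pixel_rejects(self):
        seg = _manual_segmentation()
        pix = [(15, 19), (15, 20)] + [(r, 18) for r in range(10, 20)]
        comp = _component(pix)  # 12 px, one pixel on the nucleus
        (focus,) = imaging.filter_cytoplasmic_foci([comp], seg)
        assert not focus.accepted and focus.reason == "in_nucleus"

    def test_outside_cytoplasm_rejected(self):
        seg = _manual_segmentation()
        comp = _component([(2, r) for r in range(45, 52)])  # off-territory
        (focus,) = imaging.filter_cytoplasmic_foci([comp], seg)
        assert not focus.accepted and focus.reason == "outside_cytoplasm"

    def test_min_area_below_one_is_error(self):
        seg = _manual_segmentation()
        with pytest.raises(ValueError):
            imaging.filter_cytoplasmic_foci([], seg, min_area=0)

    def test_raising_min_area_never_raises_counts(self, default_field):
        fov, _ = default_field
        seg = imaging.segment_field(fov)
        comps = imaging.detect_dsdna_signals(fov.dsdna)
        prev = None
        for min_area in (1, 3, 5, 8, 12):
            foci = imaging.filter_cytoplasmic_foci(comps, seg, min_area=min_area)
            table = imaging.count_foci_per_cell(foci, seg)
            counts = table.set_index("cell_id")["n_foci"]
            if prev is not None:
                assert (counts <= prev).all()
            prev = counts


class TestCountsAndCorrection:
    def test_counts_include_zero_cells(self):
        seg = _manual_segmentation()
        table = imaging.count_foci_per_cell([], seg)
        assert table["n_foci"].tolist() == [0]

    def test_unknown_cell_id_is_error(self):
        seg = _manual_segmentation()
        f = imaging.Focus(pixels=np.zeros((5, 2), dtype=int), area=5,
                          centroid=(1.0, 1.0), cell_id=99, accepted=True)
        with pytest.raises(ValueError, match="unknown cell"):
            imaging.count_foci_per_cell([f], seg)

    def test_clean_field_counts_equal_truth(self, clean_field):
        fov, truth = clean_field
        _, _, table = imaging.process_field(fov)
        got = dict(zip(table["cell_id"], table["n_foci"]))
        want = truth.cytoplasmic_counts(min_area=5).to_dict()
        assert got == want

    def test_background_correction_arithmetic(self):
        summary = pd.DataFrame(
            dict(quality=["xray", "xray"], dose_gy=[0.0, 8.0],
                 n_cells=[50, 50], mean_foci=[2.0, 6.5],
                 sd_foci=[1.0, 1.0], se_foci=[0.14, 0.14])
        )
        out = imaging.background_correct(summary)
        assert out["corrected_mean"].tolist() == [0.0, 4.5]

    def test_each_quality_uses_its_own_control(self):
        summary = pd.DataFrame(
            dict(quality=["xray", "xray", "carbon", "carbon"],
                 dose_gy=[0.0, 8.0, 0.0, 8.0],
                 n_cells=[50] * 4, mean_foci=[2.0, 6.5, 1.0, 6.5],
                 sd_foci=[1.0] * 4, se_foci=[0.14] * 4)
        )
        out = imaging.background_correct(summary).set_index(["quality", "dose_gy"])
        assert out.loc[("xray", 8.0), "corrected_mean"] == 4.5
        assert out.loc[("carbon", 8.0), "corrected_mean"] == 5.5

    def test_missing_zero_dose_group_is_error(self):
        summary = pd.DataFrame(
            dict(quality=["xray"], dose_gy=[8.0], n_cells=[50],
                 mean_foci=[6.5], sd_foci=[1.0], se_foci=[0.14])
        )
        with pytest.raises(ValueError, match="0 Gy"):
            imaging.background_correct(summary)


class TestCompartmentSoundness:
    def test_accepted_foci_never_touch_nuclei(self, default_field):
        fov, _ = default_field
        seg, foci, _ = imaging.process_field(fov)
        for f in foci:
            if f.accepted:
                labels = seg.nucleus_labels[f.pixels[:, 0], f.pixels[:, 1]]
                assert (labels == 0).all()
                assert f.cell_id in set(seg.cell_ids)
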