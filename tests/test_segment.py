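"""Illumination correction and segmentation behaviour."""

import numpy as np
import pytest

from cbmn import SegmentationParams, SynthParams, correct_illumination, \
    generate_field, nuclei_count_normalized, segment_cytoplasm, segment_nuclei
from cbmn.segment import count_nuclei
from conftest import toy_disk


class TestCorrectIllumination:
    def test_flat_field_passes_through(self):
        img = np.full((128, 128), 7.5)
        out = correct_illumination(img)
        assert np.allclose(out, img, atol=1e-6 * 7.5)

    def test_all_zero_warns_and_passes_through(self):
        img = np.zeros((64, 64))
        with pytest.warns(UserWarning, match="all-zero"):
            out = correct_illumination(img)
        assert np.array_equal(out, img)

    def test_gradient_only_image_becomes_near_constant(self):
        p = SynthParams(seed=5, cells_per_field=0, background_gradient=0.4,
                        noise_sd=0.0, shot_noise=False)
        fld, _ = generate_field(p, 0)
        out = correct_illumination(fld.channels["dna"])
        # residual trend < 5% of the nuclear signal amplitude (100)
        assert np.ptp(out) < 5.0

    def test_residual_background_under_cells(self):
        p = SynthParams(seed=5, background_gradient=0.4, noise_sd=0.0,
                        shot_noise=False)
        fld, _ = generate_field(p, 0)
        out = correct_illumination(fld.channels["dna"])
        bg_pixels = out[fld.channels["dna"] < 60.0]
        assert np.ptp(bg_pixels) < 5.0


class TestSegmentNuclei:
    def test_empty_field_has_zero_labels(self):
        p = SynthParams(seed=4, cells_per_field=0)
        fld, _ = generate_field(p, 0)
        labels = segment_nuclei(correct_illumination(fld.channels["dna"]))
        assert labels.max() == 0

    def test_count_matches_truth_on_separated_field(self):
        p = SynthParams(seed=6, clustering=0.0)
        total = true = 0
        for fi in range(2):
            fld, truth = generate_field(p, fi)
            total += count_nuclei(fld)
            true += sum(len(c.nuclei) for c in truth.cells)
        assert abs(total - true) <= 0.02 * true

    def test_touching_discs_are_split_into_two(self):
        img = np.full((100, 100), 20.0)
        img[toy_disk((100, 100), (50, 38), 11)] = 120.0
        img[toy_disk((100, 100), (50, 58), 11)] = 120.0
        labels = segment_nuclei(img)
        assert labels.max() == 2

    def test_counts_invariant_to_translation_and_rotation(self, default_field):
        fld, _ = default_field
        dna = correct_illumination(fld.channels["dna"])
        n = segment_nuclei(dna).max()
        assert segment_nuclei(np.roll(dna, (7, 13), axis=(0, 1))).max() == n
        assert segment_nuclei(np.rot90(dna)).max() == n

    def test_clustered_growth_degrades_counts_more(self):
        # the motivation for enzymatic cell separation, as a measurable property
        err = {0.0: 0, 3.0: 0}
        for s in range(3):
            for cl in err:
                p = SynthParams(seed=200 + s, clustering=cl,
                                cells_per_field=10, field_shape=(384, 384))
                fld, truth = generate_field(p, 0)
                true = sum(len(c.nuclei) for c in truth.cells)
                err[cl] += abs(count_nuclei(fld) - true)
        assert err[3.0] > err[0.0]


class TestSegmentCytoplasm:
    def test_one_blob_with_two_nuclei_is_one_territory(self):
        actin = np.full((100, 100), 20.0)
        actin[toy_disk((100, 100), (50, 50), 30)] = 80.0
        nuclei = np.zeros((100, 100), dtype=np.int32)
        nuclei[toy_disk((100, 100), (50, 38), 8)] = 1
        nuclei[toy_disk((100, 100), (50, 62), 8)] = 2
        labels = segment_cytoplasm(actin, nuclei)
        assert labels.max() == 1

    def test_two_disjoint_blobs_are_two_territories(self):
        actin = np.full((120, 120), 20.0)
        actin[toy_disk((120, 120), (40, 40), 22)] = 80.0
        actin[toy_disk((120, 120), (80, 80), 22)] = 80.0
        nuclei = np.zeros((120, 120), dtype=np.int32)
        nuclei[toy_disk((120, 120), (40, 40), 8)] = 1
        nuclei[toy_disk((120, 120), (80, 80), 8)] = 2
        assert segment_cytoplasm(actin, nuclei).max() == 2

    def test_shape_mismatch_is_contract_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            segment_cytoplasm(np.zeros((10, 10)), np.zeros((5, 5), dtype=int))

    def test_cell_count_matches_truth(self):
        p = SynthParams(seed=8)
        fld, truth = generate_field(p, 0)
        from cbmn.score import score_field
        cells, cyto = score_field(fld)
        n_true = sum(not c.touches_border for c in truth.cells)
        assert abs(cyto.max() - n_true) <= max(1, 0.02 * n_true)


class TestNucleiCountNormalized:
    def test_identical_collections_give_one(self, default_field):
        fld, _ = default_field
        assert nuclei_count_normalized([fld], [fld]) == pytest.approx(1.0)
        assert nuclei_count_normalized([fld, fld], [fld]) == pytest.approx(1.0)

    def test_half_density_gives_half(self):
        ctrl = SynthParams(seed=21, cells_per_field=20)
        half = SynthParams(seed=22, cells_per_field=10)
        cf = [generate_field(ctrl, fi)[0] for fi in range(3)]
        tf = [generate_field(half, fi)[0] for fi in range(3)]
        ratio = nuclei_count_normalized(tf, cf)
        assert ratio == pytest.approx(0.5, abs=0.1)

    def test_zero_control_is_an_error(self):
        p = SynthParams(seed=23, cells_per_field=0)
        empty = [generate_field(p, 0)[0]]
        with pytest.raises(ZeroDivisionError):
            nuclei_count_normalized(empty, empty)


def test_segmentation_params_validation():
    with pytest.raises(ValueError):
        SegmentationParams(min_nucleus_area=500, max_nucleus_area=100)
    with pytest.raises(ValueError):
        SegmentationParams(border_policy="bogus")
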