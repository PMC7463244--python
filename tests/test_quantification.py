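"""Nucleated-region construction, drug partitioning, histograms, occupancy."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import slidequant as sq

CAL1 = sq.PixelCalibration(1.0)


def _disc_lattice_count(radius):
    """Independent enumeration of lattice points with x^2+y^2 <= r^2."""
    r = int(np.ceil(radius))
    return sum(
        1
        for x in range(-r, r + 1)
        for y in range(-r, r + 1)
        if x * x + y * y <= radius * radius
    )


class TestNucleatedCellMask:
    def test_empty_set_warns_empty_mask(self):
        with pytest.warns(UserWarning):
            mask = sq.nucleated_cell_mask(sq.NucleusSet(np.empty((0, 2))), (32, 32), CAL1)
        assert mask.area_px == 0

    def test_seven_micron_disc_area_149(self):
        nuclei = sq.NucleusSet(np.array([[32, 32]]))
        mask = sq.nucleated_cell_mask(nuclei, (64, 64), CAL1, radius_um=7.0)
        assert mask.area_px == 149 == _disc_lattice_count(7.0)

    def test_overlapping_discs_merge(self):
        nuclei = sq.NucleusSet(np.array([[32, 30], [32, 33]]))
        mask = sq.nucleated_cell_mask(nuclei, (64, 64), CAL1, radius_um=7.0)
        assert mask.area_px < 2 * 149

    def test_border_clipping(self):
        nuclei = sq.NucleusSet(np.array([[0, 0]]))
        mask = sq.nucleated_cell_mask(nuclei, (64, 64), CAL1, radius_um=7.0)
        assert 0 < mask.area_px < 149

    def test_adding_a_nucleus_never_shrinks_masks(self):
        epi = sq.BinaryMask(np.ones((50, 50), dtype=bool), CAL1)
        base = sq.nucleated_cell_mask(sq.NucleusSet(np.array([[10, 10]])), (50, 50), CAL1)
        more = sq.nucleated_cell_mask(
            sq.NucleusSet(np.array([[10, 10], [40, 40]])), (50, 50), CAL1
        )
        assert np.all(more.mask >= base.mask)
        ne_base = sq.nucleated_epithelial_mask(base, epi)
        ne_more = sq.nucleated_epithelial_mask(more, epi)
        assert np.all(ne_more.mask >= ne_base.mask)
        assert np.all(ne_base.mask <= base.mask)


class TestNucleatedEpithelialMask:
    def test_full_epithelium_is_identity(self):
        cells = sq.nucleated_cell_mask(sq.NucleusSet(np.array([[16, 16]])), (32, 32), CAL1)
        epi = sq.BinaryMask(np.ones((32, 32), dtype=bool), CAL1)
        np.testing.assert_array_equal(
            sq.nucleated_epithelial_mask(cells, epi).mask, cells.mask
        )

    def test_disjoint_masks_empty(self):
        a = np.zeros((10, 10), dtype=bool)
        a[:5] = True
        b = ~a
        out = sq.nucleated_epithelial_mask(sq.BinaryMask(a, CAL1), sq.BinaryMask(b, CAL1))
        assert out.area_px == 0

    def test_checkerboard_against_enumeration(self):
        checker = np.indices((8, 8)).sum(axis=0) % 2 == 0
        top = np.zeros((8, 8), dtype=bool)
        top[:4] = True
        out = sq.nucleated_epithelial_mask(
            sq.BinaryMask(checker, CAL1), sq.BinaryMask(top, CAL1)
        )
        expected = sum(
            1 for r in range(4) for c in range(8) if (r + c) % 2 == 0
        )
        assert out.area_px == expected == checker.sum() // 2

    def test_shape_mismatch(self):
        with pytest.raises(sq.ShapeMismatchError):
            sq.nucleated_epithelial_mask(
                sq.BinaryMask(np.ones((4, 4), dtype=bool), CAL1),
                sq.BinaryMask(np.ones((5, 5), dtype=bool), CAL1),
            )


class TestPartitionDrug:
    def test_all_in_mask(self):
        drug = np.arange(16.0).reshape(4, 4)
        ne = sq.BinaryMask(np.ones((4, 4), dtype=bool), CAL1)
        assert sq.partition_drug(drug, ne) == (drug.sum(), 0.0)

    def test_none_in_mask(self):
        drug = np.arange(16.0).reshape(4, 4)
        ne = sq.BinaryMask(np.zeros((4, 4), dtype=bool), CAL1)
        assert sq.partition_drug(drug, ne) == (0.0, drug.sum())

    def test_hand_case_2x2(self):
        drug = np.array([[1.0, 2.0], [3.0, 4.0]])
        ne = sq.BinaryMask(np.array([[1, 0], [0, 1]]), CAL1)
        assert sq.partition_drug(drug, ne) == (5.0, 5.0)

    def test_conservation_exact(self):
        rng = np.random.default_rng(7)
        drug = rng.random((100, 100)) * 50
        ne = sq.BinaryMask(rng.random((100, 100)) > 0.5, CAL1)
        s, n = sq.partition_drug(drug, ne)
        assert s + n == pytest.approx(drug.sum(), rel=1e-12)


class TestRegionDensityHistogram:
    def test_uniform_region_density(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:7, 5:10] = True  # 10 px region
        drug = np.where(mask, 5.0, 0.0)
        (_, counts), table = sq.region_density_histogram(drug, sq.BinaryMask(mask, CAL1))
        assert len(table) == 1
        assert table["density_per_um2"].iloc[0] == pytest.approx(5.0)
        assert counts.sum() == 1

    def test_zero_drug_all_in_lowest_bin(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:5, 2:5] = True
        mask[10:14, 10:14] = True
        (edges, counts), table = sq.region_density_histogram(
            np.zeros((20, 20)), sq.BinaryMask(mask, CAL1), bins=4
        )
        assert (table["density_per_um2"] == 0).all()
        assert counts[0] == len(table) == 2

    def test_two_regions_known_densities(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:4, 2:4] = True  # 4 px
        mask[10:12, 10:12] = True  # 4 px
        drug = np.zeros((20, 20))
        drug[2:4, 2:4] = 2.0
        drug[10:12, 10:12] = 8.0
        (edges, counts), _ = sq.region_density_histogram(
            drug, sq.BinaryMask(mask, CAL1), bins=np.array([0.0, 5.0, 10.0])
        )
        np.testing.assert_array_equal(counts, [1, 1])

    def test_empty_mask_warns(self):
        with pytest.warns(UserWarning):
            (_, counts), table = sq.region_density_histogram(
                np.zeros((8, 8)), sq.BinaryMask(np.zeros((8, 8), dtype=bool), CAL1)
            )
        assert len(table) == 0

    def test_density_stable_under_finer_sampling(self):
        """Halving the pixel pitch changes a smooth region density < 5%."""
        def density(mpp):
            cal = sq.PixelCalibration(mpp)
            n = int(round(40 / mpp))
            yy, xx = np.mgrid[:n, :n] * mpp
            drug_per_um2 = 3.0 + np.sin(yy / 8.0) + np.cos(xx / 11.0)
            mask = np.zeros((n, n), dtype=bool)
            r = int(round(15 / mpp))
            mask[n // 2 - r : n // 2 + r, n // 2 - r : n // 2 + r] = True
            drug = drug_per_um2 * mpp**2  # per-pixel integrated signal
            _, table = sq.region_density_histogram(drug, sq.BinaryMask(mask, cal))
            return table["density_per_um2"].iloc[0]

        d1, d2 = density(1.0), density(0.5)
        assert abs(d2 - d1) / d1 < 0.05


class TestOccupancy:
    def _mask100(self):
        m = np.zeros((20, 20), dtype=bool)
        m[5:15, 5:15] = True  # 100 px
        return sq.BinaryMask(m, CAL1)

    def test_zero_drug_zero_occupancy(self):
        bg = sq.BackgroundModel(method="fixed", fixed_value=1.0)
        assert sq.occupancy(np.zeros((20, 20)), self._mask100(), bg) == 0.0

    def test_uniform_above_threshold_is_one(self):
        bg = sq.BackgroundModel(method="fixed", fixed_value=2.0)
        drug = np.full((20, 20), 3.0)
        assert sq.occupancy(drug, self._mask100(), bg) == 1.0

    def test_forty_of_hundred_pixels(self):
        ne = self._mask100()
        drug = np.zeros((20, 20))
        drug[5:9, 5:15] = 2.0  # 40 masked pixels above threshold 1
        bg = sq.BackgroundModel(method="fixed", fixed_value=1.0)
        assert sq.occupancy(drug, ne, bg) == pytest.approx(0.40)

    def test_context_statistics_threshold(self):
        ne = self._mask100()
        drug = np.full((20, 20), 10.0)
        context = np.zeros(500)  # mean 0, sd 0 -> tau 0
        assert sq.occupancy(drug, ne, sq.BackgroundModel(), context) == 1.0

    def test_empty_mask_rejected(self):
        with pytest.raises(sq.EmptyInputError):
            sq.occupancy(np.zeros((8, 8)),
                         sq.BinaryMask(np.zeros((8, 8), dtype=bool), CAL1),
                         sq.BackgroundModel(method="fixed", fixed_value=0.0))

    def test_per_region_variant(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:4, 2:4] = True
        mask[10:12, 10:12] = True
        drug = np.zeros((20, 20))
        drug[2:4, 2:4] = 10.0  # one hot region of two
        bg = sq.BackgroundModel(method="fixed", fixed_value=5.0)
        occ = sq.occupancy(drug, sq.BinaryMask(mask, CAL1), bg, per_region=True)
        assert occ == pytest.approx(0.5)


class TestTimecourse:
    def _result(self, t, tissue="colon", occ=0.5):
        return sq.QuantResult(
            region_table=pd.DataFrame(),
            histogram=(np.array([0.0, 1.0]), np.array([0])),
            specific_total=1.0,
            nonspecific_total=1.0,
            occupancy=occ,
            meta={"time_h": t, "tissue_label": tissue},
        )

    def test_single_row(self):
        df = sq.timecourse([self._result(24.0)])
        assert len(df) == 1

    def test_study_time_points_sorted(self):
        df = sq.timecourse([self._result(48.0), self._result(2.0), self._result(24.0)])
        assert list(df["time_h"]) == [2.0, 24.0, 48.0]

    def test_order_invariance(self):
        results = [self._result(t, tissue) for t in (48.0, 2.0, 24.0)
                   for tissue in ("intestine", "colon")]
        a = sq.timecourse(results)
        b = sq.timecourse(results[::-1])
        pd.testing.assert_frame_equal(a, b)

    def test_duplicates_kept_with_warning(self):
        with pytest.warns(UserWarning):
            df = sq.timecourse([self._result(2.0), self._result(2.0)])
        assert len(df) == 2


class TestQuantifyEndToEnd:
    def test_specific_fraction_recovery_with_truth_masks(self, small_slide, small_params):
        """Planted specific fraction recovered within 0.1 despite degradation."""
        slide, truth = small_slide
        cal = slide.calibration
        cells = sq.nucleated_cell_mask(
            sq.NucleusSet(truth.nucleus_centers), truth.epithelium_mask.shape, cal
        )
        ne = sq.nucleated_epithelial_mask(
            cells, sq.BinaryMask(truth.epithelium_mask, cal)
        )
        spec, nonspec = sq.partition_drug(slide.channels["drug"], ne)
        planted = 1.0 - small_params.interstitial_fraction
        assert abs(spec / (spec + nonspec) - planted) <= 0.1

    def test_quantify_bundles_consistent_result(self, small_slide):
        slide, truth = small_slide
        res = sq.quantify(
            slide.channels["drug"],
            sq.NucleusSet(truth.nucleus_centers),
            sq.BinaryMask(truth.epithelium_mask, slide.calibration),
            slide.calibration,
            background_context=(0.0, 1.0),
            time_h=24.0,
            tissue_label="colon",
        )
        assert res.total_drug == pytest.approx(slide.channels["drug"].sum(), rel=1e-9)
        assert 0.0 <= res.occupancy <= 1.0
        assert res.histogram[1].sum() == len(res.region_table)
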