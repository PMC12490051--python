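import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from histoquant.fixtures import make_fluor_phantom
from histoquant.image_io import SectionImage, convert_bit_depth
from histoquant.segmentation import (
    SegmentationConfig,
    binarize,
    count_cells,
    region_table,
    segment_and_count,
    size_filter,
    watershed_segment,
)

from .conftest import disk_pair_image

STRUCT8 = np.ones((3, 3), bool)


def brute_force_otsu(values: np.ndarray) -> float:
    """Exhaustive between-class-variance maximization over all cut points."""
    best_t, best_var = 0.0, -1.0
    vals = values.ravel().astype(float)
    for t in np.unique(vals)[:-1]:
        lo, hi = vals[vals <= t], vals[vals > t]
        w0, w1 = len(lo) / len(vals), len(hi) / len(vals)
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


class TestBinarize:
    def test_constant_image_warns_and_returns_empty(self, default_cfg):
        img = SectionImage(np.full((32, 32), 40, dtype=np.uint8), bit_depth=8)
        with pytest.warns(UserWarning, match="constant"):
            mask = binarize(img, default_cfg)
        assert not mask.any()

    def test_two_level_image_matches_brute_force_otsu(self):
        rng = np.random.default_rng(0)
        img_arr = np.where(rng.random((64, 64)) < 0.3, 200, 10).astype(np.uint8)
        cfg = SegmentationConfig(blur_sigma_px=0.01)
        img = SectionImage(img_arr, bit_depth=8)
        mask = binarize(img, cfg)
        # negligible blur: the Otsu cut must land between the two levels,
        # exactly as the exhaustive search says
        t = brute_force_otsu(img_arr)
        assert 10 <= t < 200
        assert np.array_equal(mask, img_arr > t)
        assert mask.sum() == (img_arr == 200).sum()

    def test_fixed_threshold_is_strictly_above(self):
        img = SectionImage(np.array([[127, 128, 129]], dtype=np.uint8), bit_depth=8)
        cfg = SegmentationConfig(binarize_method="fixed", fixed_threshold=128,
                                 blur_sigma_px=0.01)
        assert list(binarize(img, cfg)[0]) == [False, False, True]


class TestWatershed:
    def test_blank_image_yields_no_objects(self, default_cfg):
        img = SectionImage(np.zeros((64, 64), dtype=np.uint8), bit_depth=8)
        with pytest.warns(UserWarning):
            labels = watershed_segment(img, default_cfg)
        assert count_cells(labels) == 0

    def test_well_separated_phantom_recovered_with_matching_centroids(self, default_cfg):
        p = make_fluor_phantom(10, min_separation_px=40, seed=7, shape=(512, 512))
        img = convert_bit_depth(p.image)
        labels = watershed_segment(img, default_cfg)
        regions = region_table(labels, img)
        labels, regions = size_filter(labels, regions, default_cfg)
        assert count_cells(labels) == 10
        found = regions[["centroid_row", "centroid_col"]].to_numpy()
        truth = np.asarray(p.truth_centroids)
        d = np.sqrt(((found[:, None, :] - truth[None, :, :]) ** 2).sum(-1))
        assert np.all(d.min(axis=1) <= p.params["blob_radius_px"])

    def test_touching_disk_pair_splits_in_two(self, binary_cfg):
        img = disk_pair_image(radius=8, distance=12)
        # brute-force oracle: the EDT has exactly two regional maxima
        mask = img.pixels > 100
        edt = ndimage.distance_transform_edt(mask)
        peaks = mask & (edt == ndimage.maximum_filter(edt, size=3))
        assert ndimage.label(peaks, structure=STRUCT8)[1] == 2
        assert count_cells(watershed_segment(img, binary_cfg)) == 2

    def test_disjoint_objects_equal_connected_component_partition(self, default_cfg):
        """Oracle equivalence: when nothing touches, watershed is exactly
        8-connected labeling of the binarized mask (same K, same partition)."""
        p = make_fluor_phantom(12, min_separation_px=45, seed=9, shape=(512, 512))
        img = convert_bit_depth(p.image)
        ws = watershed_segment(img, default_cfg)
        cc, n_cc = ndimage.label(binarize(img, default_cfg), structure=STRUCT8)
        assert count_cells(ws) == n_cc
        # same pixel partition up to label permutation
        pair_ids = set(zip(ws.ravel().tolist(), cc.ravel().tolist()))
        assert len(pair_ids) == n_cc + 1  # a bijection plus the background pair

    def test_count_invariant_under_rotation(self, default_cfg):
        p = make_fluor_phantom(8, seed=11, shape=(256, 256), min_separation_px=30)
        img = convert_bit_depth(p.image)
        counts = {
            count_cells(watershed_segment(
                SectionImage(np.rot90(img.pixels, k), bit_depth=8), default_cfg))
            for k in range(4)
        }
        assert counts == {8}

    def test_count_invariant_to_subthreshold_background_shift(self, binary_cfg):
        img = disk_pair_image(radius=6, distance=30)
        shifted = SectionImage(img.pixels + 20, bit_depth=8)
        assert count_cells(watershed_segment(img, binary_cfg)) == count_cells(
            watershed_segment(shifted, binary_cfg)
        )


class TestSizeFilter:
    @staticmethod
    def labels_with_areas(areas):
        """One horizontal run of each requested area, one object per row."""
        w = max(areas) + 2
        arr = np.zeros((2 * len(areas), w), dtype=np.int32)
        for i, a in enumerate(areas):
            arr[2 * i, 1 : 1 + a] = i + 1
        return arr

    def test_fixed_cutoff_drops_small_objects(self):
        labels = self.labels_with_areas([3, 50, 60])
        regions = region_table(labels, pixel_size_um=1.0)
        cfg = SegmentationConfig(size_filter_mode="fixed", min_area_px=10)
        out_labels, out_regions = size_filter(labels, regions, cfg)
        assert len(out_regions) == 2
        assert count_cells(out_labels) == 2
        assert list(out_regions["area_px"]) == [50, 60]

    def test_fixed_cutoff_zero_is_identity(self):
        labels = self.labels_with_areas([3, 50])
        regions = region_table(labels)
        cfg = SegmentationConfig(size_filter_mode="fixed", min_area_px=0)
        out_labels, out_regions = size_filter(labels, regions, cfg)
        assert np.array_equal(out_labels, labels)
        assert len(out_regions) == 2

    def test_data_driven_median_fraction_rule(self):
        # areas {4, 100, 110, 120}: median 105, cutoff 0.25*105 = 26.25 -> drop the 4
        labels = self.labels_with_areas([4, 100, 110, 120])
        regions = region_table(labels)
        cfg = SegmentationConfig(size_filter_mode="data_driven", data_driven_fraction=0.25)
        _, out_regions = size_filter(labels, regions, cfg)
        assert list(out_regions["area_px"]) == [100, 110, 120]
        assert list(out_regions["label"]) == [1, 2, 3]  # re-indexed, order preserved

    def test_empty_table_returned_unchanged(self, default_cfg):
        labels = np.zeros((8, 8), dtype=np.int32)
        regions = region_table(labels)
        out_labels, out_regions = size_filter(labels, regions, default_cfg)
        assert out_regions.empty and count_cells(out_labels) == 0

    @pytest.mark.parametrize("mode,param", [("fixed", "min_area_px"),
                                            ("data_driven", "data_driven_fraction")])
    def test_monotone_filtering_never_increases_count(self, mode, param):
        p = make_fluor_phantom(20, seed=3, shape=(512, 512))
        img = convert_bit_depth(p.image)
        labels = watershed_segment(img, SegmentationConfig())
        regions = region_table(labels, img)
        values = [0, 5, 20, 80] if mode == "fixed" else [0.05, 0.25, 0.5, 1.0]
        counts = []
        for v in values:
            kwargs = {"size_filter_mode": mode, param: v}
            if mode == "data_driven":
                kwargs.pop("min_area_px", None)
            _, out = size_filter(labels, regions, SegmentationConfig(**kwargs))
            counts.append(len(out))
        assert counts == sorted(counts, reverse=True)


class TestRegionTable:
    def test_area_accounting_matches_label_map(self):
        p = make_fluor_phantom(6, seed=13, shape=(256, 256), min_separation_px=30)
        img = convert_bit_depth(p.image)
        labels = watershed_segment(img, SegmentationConfig())
        tbl = region_table(labels, img)
        assert tbl["area_px"].sum() == np.count_nonzero(labels)
        expected_mm2 = tbl["area_px"] * (img.pixel_size_um / 1000.0) ** 2
        assert np.allclose(tbl["area_mm2"], expected_mm2)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"blur_sigma_px": 0},
            {"binarize_method": "magic"},
            {"binarize_method": "fixed"},  # missing fixed_threshold
            {"fixed_threshold": 10},  # otsu + fixed_threshold both active
            {"marker_distance_fraction": 1.0},
            {"size_filter_mode": "fixed"},  # missing min_area_px
            {"data_driven_fraction": 0.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SegmentationConfig(**kwargs)


def test_full_pipeline_counts_exactly_on_clean_phantom():
    p = make_fluor_phantom(25, seed=21)
    result = segment_and_count(convert_bit_depth(p.image))
    assert result["count"] == 25
    assert isinstance(result["regions"], pd.DataFrame)
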