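import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from petmvcc.maps import (
    find_peaks,
    label_regions,
    rank_weights,
    sign_correct,
    threshold_clusters,
    zscore_map,
)
from petmvcc.volume import Volume

from .oracles import flood_fill_label


def make_mask(shape=(12, 12, 12), voxel=2.0, origin=None):
    if origin is None:
        origin = tuple(-(n - 1) / 2 * voxel for n in shape)
    return Volume(np.ones(shape), (voxel,) * 3, origin)


class TestRankWeights:
    def test_34_weights_top_5_percent_gives_two(self):
        rng = np.random.default_rng(0)
        selected, ranking = rank_weights(rng.normal(size=34), 0.05)
        assert len(selected) == 2
        assert len(ranking) == 34

    def test_ties_break_by_component_id(self):
        selected, ranking = rank_weights(np.array([1.0, -1.0, 1.0]), 1.0)
        assert ranking == [0, 1, 2]

    @given(st.integers(0, 10_000))
    def test_matches_bruteforce_sort(self, seed):
        rng = np.random.default_rng(seed)
        w = rng.normal(size=10).round(1)  # rounding creates ties
        _sel, ranking = rank_weights(w, 0.3)
        expected = sorted(range(10), key=lambda i: (-abs(w[i]), i))
        assert ranking == expected


class TestSignCorrect:
    def test_positive_weight_is_identity_negative_negates(self):
        img = np.random.default_rng(1).normal(size=(3, 3, 3))
        np.testing.assert_array_equal(sign_correct(img, 2.5), img)
        np.testing.assert_array_equal(sign_correct(img, -0.1), -img)
        np.testing.assert_array_equal(
            sign_correct(sign_correct(img, -1.0), -1.0), img
        )

    def test_zero_weight_errors(self):
        with pytest.raises(ValueError, match="zero"):
            sign_correct(np.ones((2, 2, 2)), 0.0)

    def test_score_contribution_invariant_under_joint_flip(self):
        # negating a component and its coefficient column leaves w.a fixed
        rng = np.random.default_rng(2)
        comp = rng.normal(size=50)
        coeff = rng.normal(size=8)
        weight = -1.3
        assert np.allclose(weight * coeff, (-weight) * (-coeff))


class TestZScoreMap:
    def test_standardized_over_mask(self):
        mask = make_mask()
        img = np.random.default_rng(3).normal(2.0, 3.0, mask.shape)
        zm = zscore_map(img, mask)
        inside = mask.data > 0.5
        assert zm.volume.data[inside].mean() == pytest.approx(0, abs=1e-9)
        assert zm.volume.data[inside].std() == pytest.approx(1, abs=1e-9)

    def test_affine_invariance(self):
        mask = make_mask()
        img = np.random.default_rng(4).normal(size=mask.shape)
        z1 = zscore_map(img, mask).volume.data
        z2 = zscore_map(3.2 * img + 17.0, mask).volume.data
        np.testing.assert_allclose(z1, z2, atol=1e-10)

    def test_five_voxel_hand_example(self):
        mask = Volume(np.ones((5, 1, 1)))
        vals = np.array([1.0, 2.0, 3.0, 4.0, 10.0]).reshape(5, 1, 1)
        zm = zscore_map(vals, mask)
        mu, sd = 4.0, np.std([1, 2, 3, 4, 10])
        np.testing.assert_allclose(
            zm.volume.data.ravel(), (vals.ravel() - mu) / sd, atol=1e-12
        )

    def test_constant_image_errors(self):
        with pytest.raises(ValueError, match="deviation"):
            zscore_map(np.ones((4, 4, 4)), make_mask((4, 4, 4)))


def planted_blob_zmap(n_voxels, shape=(14, 14, 14), where=None, sign=1):
    """A z-map with an exact-count suprathreshold box plus background."""
    mask = make_mask(shape)
    z = np.zeros(shape)
    # fill a compact connected region with exactly n_voxels voxels
    coords = []
    cx = [s // 2 for s in shape] if where is None else list(where)
    radius = 1
    while len(coords) < n_voxels:
        coords = [
            (i, j, k)
            for i in range(max(0, cx[0] - radius), min(shape[0], cx[0] + radius + 1))
            for j in range(max(0, cx[1] - radius), min(shape[1], cx[1] + radius + 1))
            for k in range(max(0, cx[2] - radius), min(shape[2], cx[2] + radius + 1))
        ]
        radius += 1
    for c in coords[:n_voxels]:
        z[c] = sign * 5.0
    zm = zscore_map(z + np.random.default_rng(0).normal(0, 1e-6, shape), mask)
    # rescale so the blob is comfortably above threshold and the rest isn't
    zm.volume.data[:] = z
    return zm


class TestThresholdClusters:
    def test_planted_60_voxel_blob_is_one_positive_cluster(self):
        zm = planted_blob_zmap(60)
        table = threshold_clusters(zm, 2.58, 50, 18)
        assert len(table.clusters) == 1
        assert table.clusters[0]["extent_voxels"] == 60
        assert table.clusters[0]["direction"] == "+"

    def test_49_voxel_blob_discarded_at_extent_50(self):
        zm = planted_blob_zmap(49)
        table = threshold_clusters(zm, 2.58, 50, 18)
        assert table.clusters == []

    def test_all_zero_map_empty_table(self):
        mask = make_mask()
        zm = zscore_map(np.random.default_rng(5).normal(size=mask.shape), mask)
        zm.volume.data[:] = 0.0
        assert threshold_clusters(zm, 2.58, 1, 18).clusters == []

    def test_positive_negative_never_merge(self):
        zm = planted_blob_zmap(30, where=(3, 7, 7))
        neg = planted_blob_zmap(30, where=(5, 7, 7), sign=-1)
        zm.volume.data += neg.volume.data
        table = threshold_clusters(zm, 2.58, 10, 26)
        dirs = sorted(c["direction"] for c in table.clusters)
        assert dirs == ["+", "-"]

    def test_extent_and_threshold_monotonicity(self):
        mask = make_mask((10, 10, 10))
        rng = np.random.default_rng(6)
        img = rng.normal(size=mask.shape)
        zm = zscore_map(img, mask)
        counts = [
            len(threshold_clusters(zm, 1.0, ext, 6).clusters) for ext in (1, 3, 9)
        ]
        assert counts == sorted(counts, reverse=True)
        ext_low = [c["extent_voxels"] for c in threshold_clusters(zm, 0.8, 1, 6).clusters]
        ext_high = [c["extent_voxels"] for c in threshold_clusters(zm, 1.2, 1, 6).clusters]
        assert sum(ext_high) <= sum(ext_low)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_labeling_agrees_with_flood_fill(self, connectivity):
        rng = np.random.default_rng(connectivity)
        for _ in range(3):
            binary = rng.random((10, 10, 10)) < 0.25
            mask = make_mask((10, 10, 10))
            zm = zscore_map(rng.normal(size=(10, 10, 10)), mask)
            zm.volume.data[:] = np.where(binary, 5.0, 0.0)
            table = threshold_clusters(zm, 2.58, 1, connectivity)
            got = {frozenset(map(tuple, c["voxels"])) for c in table.clusters}
            want = set(flood_fill_label(binary, connectivity))
            assert got == want


class TestFindPeaks:
    def gaussian_zmap(self, centers, shape=(20, 20, 20)):
        mask = make_mask(shape)
        x = np.arange(shape[0])
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        img = np.zeros(shape)
        for (cx, cy, cz), amp in centers:
            img += amp * np.exp(
                -((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2) / (2 * 2.0**2)
            )
        zm = zscore_map(img, mask)
        return mask, zm

    def test_single_blob_single_peak_at_center(self):
        mask, zm = self.gaussian_zmap([((10, 10, 10), 8.0)])
        table = threshold_clusters(zm, 2.58, 5, 18)
        table = find_peaks(zm, table, min_separation_mm=8.0)
        assert len(table.clusters) == 1
        peaks = table.clusters[0]["peaks"]
        assert len(peaks) == 1
        assert peaks[0]["ijk"] == [10, 10, 10]

    def test_bimodal_cluster_reports_two_peaks(self):
        mask, zm = self.gaussian_zmap([((7, 10, 10), 8.0), ((13, 10, 10), 7.5)])
        table = threshold_clusters(zm, 1.5, 5, 18)
        assert len(table.clusters) == 1  # merged through the saddle
        table = find_peaks(zm, table, min_separation_mm=6.0)
        assert len(table.clusters[0]["peaks"]) == 2

    def test_min_separation_suppresses_weaker_peak(self):
        mask, zm = self.gaussian_zmap([((7, 10, 10), 8.0), ((13, 10, 10), 7.5)])
        table = threshold_clusters(zm, 1.5, 5, 18)
        table = find_peaks(zm, table, min_separation_mm=30.0)
        assert len(table.clusters[0]["peaks"]) == 1
        assert table.clusters[0]["peaks"][0]["ijk"][0] == 7

    def test_peak_mm_matches_bruteforce_affine(self):
        mask, zm = self.gaussian_zmap([((6, 12, 9), 8.0)])
        table = find_peaks(zm, threshold_clusters(zm, 2.58, 5, 18))
        pk = table.clusters[0]["peaks"][0]
        for val, idx, ax in zip(
            (pk["x_mm"], pk["y_mm"], pk["z_mm"]), pk["ijk"], range(3)
        ):
            assert val == pytest.approx(
                mask.origin_mm[ax] + idx * mask.voxel_size_mm[ax]
            )


class TestLabelRegions:
    def test_lookup_missing_and_permuted(self):
        mask, zm = TestFindPeaks().gaussian_zmap([((10, 10, 10), 8.0)])
        table = find_peaks(zm, threshold_clusters(zm, 2.58, 5, 18))
        labels = np.zeros(mask.shape)
        labels[8:13, 8:13, 8:13] = 7
        lab_vol = mask.copy(data=labels)
        out = label_regions(table, lab_vol, {7: "Putamen"})
        assert out.clusters[0]["peaks"][0]["region"] == "Putamen"
        out = label_regions(table, lab_vol, {7: "Caudate"})
        assert out.clusters[0]["peaks"][0]["region"] == "Caudate"
        lab_vol2 = mask.copy(data=np.zeros(mask.shape))
        out = label_regions(table, lab_vol2, {7: "Putamen"})
        assert out.clusters[0]["peaks"][0]["region"] == "-"

    def test_grid_mismatch_errors(self):
        mask, zm = TestFindPeaks().gaussian_zmap([((10, 10, 10), 8.0)])
        table = find_peaks(zm, threshold_clusters(zm, 2.58, 5, 18))
        other = Volume(np.zeros((5, 5, 5)))
        with pytest.raises(ValueError, match="grid"):
            label_regions(table, other, {})

    def test_frame_columns(self):
        mask, zm = TestFindPeaks().gaussian_zmap([((10, 10, 10), 8.0)])
        table = find_peaks(zm, threshold_clusters(zm, 2.58, 5, 18))
        df = table.to_frame()
        assert list(df.columns) == [
            "component", "cluster_id", "direction", "extent_voxels",
            "peak_z", "x_mm", "y_mm", "z_mm", "region",
        ]
        assert len(df) == 1
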