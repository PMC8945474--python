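import numpy as np
import pytest
from scipy.ndimage import rotate

from octamorph import ScanGeometry, binarize, enhance_vessels, estimate_calibers, skeletonize
from octamorph.vessels import neighbor_counts, prune_spurs


def full_mask(shape):
    return np.ones(shape, dtype=bool)


class TestEnhanceVessels:
    def test_constant_image_gives_zero_response(self):
        v = enhance_vessels(np.full((64, 64), 7.0), full_mask((64, 64)))
        assert np.all(v == 0)

    def test_bright_ridge_peaks_on_centerline_with_matching_scale(self):
        img = np.zeros((101, 101))
        img[48:51, :] = 1.0  # width 3 px, half-width 1.5
        v, sc = enhance_vessels(img, full_mask(img.shape), (1.0, 2.0), return_scales=True)
        center = v[49, 30:70]
        off = v[44, 30:70]
        assert center.min() > off.max()
        # argmax scale within a factor 2 of the ridge half-width
        assert 0.75 <= sc[49, 50] <= 3.0

    def test_rotation_equivariance_within_10_percent(self):
        img = np.zeros((101, 101))
        img[48:51, :] = 1.0
        mask = full_mask(img.shape)
        v_axis = enhance_vessels(img, mask)[49, 50]
        img_rot = np.clip(rotate(img, 37, reshape=False, order=3), 0, None)
        v_rot = enhance_vessels(img_rot, mask)[35:65, 35:65].max()
        assert v_rot == pytest.approx(v_axis, rel=0.10)

    def test_zero_outside_mask(self):
        rng = np.random.default_rng(0)
        img = rng.random((64, 64))
        mask = np.zeros((64, 64), bool)
        mask[10:30, 10:30] = True
        v = enhance_vessels(img, mask)
        assert np.all(v[~mask] == 0)

    def test_empty_scale_list_rejected(self):
        with pytest.raises(ValueError):
            enhance_vessels(np.zeros((32, 32)), full_mask((32, 32)), [])


class TestBinarize:
    def test_all_zero_with_fixed_threshold_gives_empty_map(self):
        out = binarize(np.zeros((32, 32)), full_mask((32, 32)), 0.5)
        assert not out.any()

    def test_planted_two_population_recovery(self):
        rng = np.random.default_rng(7)
        plant = np.zeros((100, 100), bool)
        plant[::7] = True  # every 7th row is "vessel"
        x = np.where(plant, 10.0, 0.0) + rng.normal(0, 0.5, (100, 100))
        out = binarize(x, full_mask(x.shape), "otsu_in_mask",
                       closing_radius=0, min_object_px=0, max_hole_px=0)
        recall = (out & plant).sum() / plant.sum()
        fp = (out & ~plant).sum() / (~plant).sum()
        assert recall >= 0.95
        assert fp <= 0.05

    def test_output_subset_of_mask(self):
        rng = np.random.default_rng(1)
        x = rng.random((64, 64))
        mask = np.zeros((64, 64), bool)
        mask[5:40, 5:40] = True
        out = binarize(x, mask)
        assert not (out & ~mask).any()

    def test_otsu_needs_two_distinct_values(self):
        with pytest.raises(ValueError, match="distinct"):
            binarize(np.ones((16, 16)), full_mask((16, 16)), "otsu_in_mask")


class TestSkeletonize:
    def test_one_pixel_bar_is_its_own_skeleton(self):
        bar = np.zeros((11, 30), bool)
        bar[5, 3:27] = True
        sk = skeletonize(bar, prune_spur_px=0)
        assert np.array_equal(sk, bar)

    def test_thick_bar_reduces_to_centerline(self):
        bar = np.zeros((15, 40), bool)
        bar[5:10, 5:35] = True  # 5 px tall, 30 px long
        sk = skeletonize(bar, 3)
        # interior is a single central row; ends may taper diagonally
        assert sk[7, 10:30].all()
        rows, cols = np.nonzero(sk)
        assert set(rows) <= {6, 7, 8}
        # length N minus boundary effects of at most 2 px per end
        assert 30 - 4 <= sk.sum() <= 30 + 2

    def test_t_shape_has_one_junction_three_endpoints(self, geometry):
        T = np.zeros((60, 60), bool)
        T[10:15, 5:55] = True
        T[10:45, 27:32] = True
        sk = skeletonize(T, 3)
        counts = neighbor_counts(sk)
        # brute-force census: junction pixels cluster at one fork
        from scipy import ndimage
        _, n_junction_clusters = ndimage.label(
            sk & (counts >= 3), structure=np.ones((3, 3), int)
        )
        assert n_junction_clusters == 1
        assert int((sk & (counts == 1)).sum()) == 3

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        blob = rng.random((80, 80)) > 0.6
        from scipy import ndimage
        blob = ndimage.binary_closing(blob, structure=np.ones((3, 3)))
        blob[0] = True  # guarantee nonempty
        sk = skeletonize(blob, 3)
        assert np.array_equal(skeletonize(sk, 0), sk)

    def test_no_2x2_block(self, phantom):
        img, mask, _ = phantom
        from octamorph import compute_all
        _, inter = compute_all(img, mask, return_intermediates=True)
        sk = inter["skeleton"]
        assert not (sk[:-1, :-1] & sk[:-1, 1:] & sk[1:, :-1] & sk[1:, 1:]).any()

    def test_subset_of_vessels_and_topology_preserved(self, phantom):
        img, mask, _ = phantom
        from octamorph import compute_all
        from scipy import ndimage
        _, inter = compute_all(img, mask, return_intermediates=True)
        vessels, sk = inter["vessels"], inter["skeleton"]
        assert not (sk & ~vessels).any()
        s8 = np.ones((3, 3), int)
        assert ndimage.label(sk, s8)[1] == ndimage.label(vessels, s8)[1]

    def test_spur_pruning_removes_short_spur_only(self):
        sk = np.zeros((21, 41), bool)
        sk[10, 2:39] = True
        sk[9, 20] = sk[8, 20] = True  # 2-px spur off the line
        out = skeletonize(sk, prune_spur_px=3)
        assert not out[9, 20] and not out[8, 20]
        assert out[10, 3:38].all()

    def test_prune_spurs_keeps_isolated_lines(self):
        sk = np.zeros((11, 30), bool)
        sk[5, 3:9] = True  # short free-standing line, no junction
        assert np.array_equal(prune_spurs(sk, 10), sk)

    def test_empty_vessel_map_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            skeletonize(np.zeros((10, 10), bool))


class TestEstimateCalibers:
    def test_five_px_bar_reads_60_um_within_one_pitch(self, geometry):
        bar = np.zeros((15, 40), bool)
        bar[5:10, 5:35] = True
        sk = np.zeros_like(bar)
        sk[7, 10:30] = True
        cal = estimate_calibers(bar, sk, geometry)
        interior = cal[7, 12:28]
        assert np.all(np.abs(interior - 60.0) <= geometry.pixel_pitch_um)

    def test_one_px_line_reads_resolution_floor(self, geometry):
        line = np.zeros((9, 30), bool)
        line[4, 2:28] = True
        cal = estimate_calibers(line, line, geometry)
        assert np.all(cal[4, 5:25] == 24.0)  # 2 × distance 1 px × 12 µm

    def test_wedge_calibers_monotone_non_increasing(self, geometry):
        W = np.zeros((30, 80), bool)
        hws = np.floor(np.linspace(5, 0.4, 66)).astype(int)
        for i, k in enumerate(hws):
            W[15 - k:15 + k + 1, i + 2] = True
        sk = np.zeros_like(W)
        sk[15, 2:68] = True
        cal = estimate_calibers(W, sk, geometry)
        interior = cal[15, 9:66]  # skip the left boundary ramp of the EDT
        assert np.all(np.diff(interior) <= 0 + 1e-12)

    def test_all_values_at_least_pitch_and_finite(self, phantom):
        img, mask, _ = phantom
        from octamorph import compute_all
        _, inter = compute_all(img, mask, return_intermediates=True)
        vals = inter["calibers"][inter["skeleton"]]
        assert np.all(np.isfinite(vals))
        assert np.all(vals >= img.geometry.pixel_pitch_um)

    def test_skeleton_outside_vessels_rejected(self, geometry):
        v = np.zeros((10, 10), bool)
        v[3, 3] = True
        s = np.zeros_like(v)
        s[5, 5] = True
        with pytest.raises(ValueError, match="outside"):
            estimate_calibers(v, s, geometry)
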