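"""CT localization: boxes, air detection, wall learning, hexagon geometry,
up-sampling, rescaling and the large/small sphere localizers."""

import numpy as np
import pytest

from niqa.ct_localize import (
    detect_air,
    extract_box,
    hexagon_extrapolate,
    learn_wall,
    localize_large,
    localize_small,
    localize_spheres,
    rescale_to_wall,
    upsample_integer,
)
from niqa.errors import ClippedBoxWarning, DegenerateArrangementError, WallModelError
from niqa.roi_report import distance_discrepancies
from niqa.synthetic_phantom import PhantomConfig, render_noiseless
from niqa.volume_io import ImageVolume


def _axial_volume(shape=(40, 80, 80), spacing=(2.5, 1.37, 1.37)):
    return ImageVolume(
        voxels=np.zeros(shape), spacing=spacing, origin=(0, 0, 0),
        orientation=np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]], float),
        modality="CT",
    )


def _truth_vox(truth, i):
    return truth.ct_noiseless.world_to_voxel(truth.centers_ct_world[i - 1])


def _err_mm(truth, i, center_vox):
    found = truth.ct_noiseless.voxel_to_world(center_vox)
    return np.linalg.norm(found - truth.centers_ct_world[i - 1])


class TestExtractBox:
    def test_minimal_voxel_counts(self):
        ct = _axial_volume()
        box = extract_box(ct, (20, 40, 40), 37.0, k_diameters=2)
        # in-plane: smallest n with n * 1.37 >= 74 is 55
        assert box.shape[1] == 55 and box.shape[2] == 55
        # axial: smallest n with n * 2.5 >= 74 is 30
        assert box.shape[0] == 30
        box = extract_box(ct, (20, 40, 40), 10.0, k_diameters=3)
        # axial: 30 mm / 2.5 mm = exactly 12 voxels
        assert box.shape[0] == 12

    def test_centered_on_rounded_estimate(self):
        ct = _axial_volume()
        box = extract_box(ct, (20.4, 40.6, 39.9), 10.0, k_diameters=3)
        center = (box.lo + np.array(box.shape) / 2.0 - 0.5).round()
        assert np.allclose(center, (20, 41, 40), atol=1)

    def test_corner_estimate_clips_with_warning(self):
        ct = _axial_volume()
        with pytest.warns(ClippedBoxWarning):
            box = extract_box(ct, (1, 1, 1), 37.0, k_diameters=2)
        assert box.clipped
        assert np.all(box.lo >= 0)


class TestDetectAir:
    def test_water_plastic_air_mixture_detected(self, rng):
        # 90% water (0 HU), 6% plastic (+120), 4% air (-1000): the mode
        # (water) falls in the upper half of the [min, max] histogram
        n = 4000
        vals = np.concatenate([
            np.zeros(int(n * 0.90)), np.full(int(n * 0.06), 120.0),
            np.full(int(n * 0.04), -1000.0),
        ])
        vals = rng.permutation(vals).reshape(10, 20, 20)
        res = detect_air(vals)
        assert res.detected
        # independent arithmetic: mean/sd of the three-component mixture
        mean = 0.90 * 0 + 0.06 * 120 + 0.04 * (-1000)
        sd = np.sqrt(0.90 * mean**2 + 0.06 * (120 - mean) ** 2 + 0.04 * (-1000 - mean) ** 2)
        assert res.mean == pytest.approx(mean)
        assert res.sd == pytest.approx(sd)
        assert -1000 <= mean - 2 * sd  # threshold separates air from water
        assert np.array_equal(res.air_mask, vals == -1000.0)

    def test_no_air_not_detected(self, rng):
        n = 4000
        vals = np.concatenate([np.zeros(int(n * 0.94)), np.full(int(n * 0.06), 120.0)])
        vals = rng.permutation(vals).reshape(10, 20, 20)
        res = detect_air(vals)
        assert not res.detected
        assert not res.air_mask.any()

    def test_constant_subvolume_not_detected(self):
        res = detect_air(np.full((4, 4, 4), 7.0))
        assert not res.detected
        assert not res.air_mask.any()


class TestUpsampleAndRescale:
    @pytest.mark.parametrize(
        "spacing,expected",
        [((2.5, 2.5, 2.5), 3), ((2.0, 2.0, 2.0), 3), ((0.7, 0.7, 0.7), 1), ((1.37, 1.37, 1.37), 2)],
    )
    def test_replication_factors(self, spacing, expected):
        vals = np.arange(24, dtype=float).reshape(2, 3, 4)
        up, f = upsample_integer(vals, spacing)
        assert np.all(f == expected)
        assert up.shape == tuple(expected * np.array(vals.shape))
        # multiset preserved up to multiplicity
        assert set(np.unique(up)) == set(np.unique(vals))

    def test_upsample_replicates_without_interpolation(self):
        vals = np.array([[[1.0, 2.0]]])
        up, f = upsample_integer(vals, (2.5, 2.5, 2.5))
        assert np.array_equal(np.unique(up), [1.0, 2.0])
        assert up[0, 0, 0] == 1.0 and up[0, 0, -1] == 2.0

    def test_rescale_fixed_point_and_symmetry(self):
        mu = 120.0
        assert rescale_to_wall(np.array([mu]), mu)[0] == 0.0
        assert rescale_to_wall(np.array([mu + 30]), mu)[0] == -30.0
        assert rescale_to_wall(np.array([mu - 30]), mu)[0] == -30.0
        # water and air: air maximally penalized
        out = rescale_to_wall(np.array([0.0, -1000.0]), mu)
        assert out[0] == -120.0 and out[1] == -1120.0


class TestLearnWall:
    def test_constant_walls(self):
        model = learn_wall([np.full(10, 120.0), np.full(5, 120.0)])
        assert model.mu_psw == 120.0
        assert model.n_wall_voxels == 15

    def test_pooled_weighted_mean(self):
        model = learn_wall([np.full(10, 100.0), np.full(20, 120.0), np.full(10, 140.0)])
        assert model.mu_psw == pytest.approx((10 * 100 + 20 * 120 + 10 * 140) / 40)

    def test_empty_pool_fails(self):
        with pytest.raises(WallModelError):
            learn_wall([np.array([]), None])


class TestHexagonExtrapolate:
    @staticmethod
    def _hexagon(radius=57.2, angle0=97.0, center=(3.0, -2.0, 5.0)):
        c = np.asarray(center, float)
        pts = {}
        for k, sphere in enumerate((6, 5, 4, 3, 2, 1)):
            ang = np.radians(angle0 - 60.0 * k)
            pts[sphere] = c + radius * np.array([np.cos(ang), np.sin(ang), 0.0])
        return c, pts

    def test_perfect_hexagon_exact(self):
        center, pts = self._hexagon()
        c1, c2, c3 = hexagon_extrapolate(pts[4], pts[5], pts[6])
        assert np.allclose(c1, pts[1], atol=1e-9)
        assert np.allclose(c2, pts[2], atol=1e-9)
        assert np.allclose(c3, pts[3], atol=1e-9)
        # the adopted center formula reproduces the configured center
        assert np.allclose(pts[4] + pts[6] - pts[5], center, atol=1e-9)

    def test_involution(self):
        _, pts = self._hexagon()
        c1, c2, c3 = hexagon_extrapolate(pts[4], pts[5], pts[6])
        # reflecting back from the small-sphere positions recovers the
        # large-sphere positions (reflection through the same center)
        b4, b5, b6 = hexagon_extrapolate(c1, c2, c3)
        assert np.allclose(b4, pts[4], atol=1e-9)
        assert np.allclose(b5, pts[5], atol=1e-9)
        assert np.allclose(b6, pts[6], atol=1e-9)

    def test_jittered_hexagon_stays_in_search_box(self, rng):
        # jitter of magnitude <= 2 mm per vertex; the reflection amplifies
        # error by at most ||j_i|| + 2||j_5or6|| + 2||j_...|| (triangle
        # inequality on C_i = C_{i+3} + 2 C_a - 2 C_b), so predictions stay
        # well inside the k=3 small-sphere search box
        _, pts = self._hexagon()
        for _ in range(100):
            jitter = {}
            for i in (4, 5, 6):
                v = rng.normal(size=3)
                jitter[i] = v / np.linalg.norm(v) * rng.uniform(0, 2.0)
            c1, c2, c3 = hexagon_extrapolate(
                pts[4] + jitter[4], pts[5] + jitter[5], pts[6] + jitter[6]
            )
            j4, j5, j6 = (np.linalg.norm(jitter[i]) for i in (4, 5, 6))
            # C1 = C4 + 2C6 - 2C5; C2 = 2C4 - 3C5 + 2C6; C3 = 2C4 - 2C5 + C6
            bounds = {1: j4 + 2 * j5 + 2 * j6, 2: 2 * j4 + 3 * j5 + 2 * j6, 3: 2 * j4 + 2 * j5 + j6}
            half_box = {1: 15.0, 2: 19.5, 3: 25.5}  # k=3 box half-extents
            for pred, i in ((c1, 1), (c2, 2), (c3, 3)):
                err = np.linalg.norm(pred - pts[i])
                assert err <= bounds[i] + 1e-9
                assert err < half_box[i]

    def test_rigid_equivariance(self, rng):
        from niqa.volume_io import RigidTransform

        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        t = RigidTransform(q, rng.normal(size=3) * 10)
        _, pts = self._hexagon()
        base = hexagon_extrapolate(pts[4], pts[5], pts[6])
        moved = hexagon_extrapolate(t(pts[4]), t(pts[5]), t(pts[6]))
        for b, m in zip(base, moved):
            assert np.allclose(t(b), m, atol=1e-9)

    def test_collinear_raises(self):
        a = np.array([0.0, 0.0, 0.0])
        b = np.array([1.0, 1.0, 0.0])
        c = np.array([2.0, 2.0, 0.0])
        with pytest.raises(DegenerateArrangementError):
            hexagon_extrapolate(a, b, c)


class TestLocalizeLarge:
    def test_noiseless_accuracy(self, clean_truth):
        ct = clean_truth.ct_noiseless
        for i, d in ((6, 37.0), (5, 28.0), (4, 22.0)):
            box = extract_box(ct, _truth_vox(clean_truth, i), d, k_diameters=2)
            res = localize_large(ct, box, d)
            assert _err_mm(clean_truth, i, res.center) < 0.5 * ct.spacing.min()
            assert res.wall_values is not None and res.wall_values.size > 0

    def test_wall_values_near_plastic(self, clean_truth):
        ct = clean_truth.ct_noiseless
        box = extract_box(ct, _truth_vox(clean_truth, 6), 37.0, k_diameters=2)
        res = localize_large(ct, box, 37.0)
        # partial volume pulls wall voxels below the pure plastic value,
        # but they must sit well above water
        assert 20.0 < res.wall_values.mean() < 120.0

    def test_miscentered_box_recovers_same_center(self, clean_truth):
        ct = clean_truth.ct_noiseless
        est = _truth_vox(clean_truth, 6)
        box_a = extract_box(ct, est, 37.0, k_diameters=2)
        box_b = extract_box(ct, est + np.array([2, 3, -3]), 37.0, k_diameters=2)  # ~5 mm off
        ca = localize_large(ct, box_a, 37.0).center
        cb = localize_large(ct, box_b, 37.0).center
        assert np.linalg.norm((ca - cb) * ct.spacing) < 0.05

    def test_bubble_compensation_beats_no_compensation(self, bubbled_truth):
        ct = bubbled_truth.ct_noiseless
        i, d = 5, 28.0  # 8 mm bubble configured in sphere 5
        box = extract_box(ct, _truth_vox(bubbled_truth, i), d, k_diameters=2)
        with_air = localize_large(ct, box, d, air_detection=True)
        without = localize_large(ct, box, d, air_detection=False)
        assert with_air.air.detected
        err_on = _err_mm(bubbled_truth, i, with_air.center)
        err_off = _err_mm(bubbled_truth, i, without.center)
        assert err_off > err_on

    def test_no_air_path_identical_when_no_bubble(self, clean_truth):
        ct = clean_truth.ct_noiseless
        box = extract_box(ct, _truth_vox(clean_truth, 6), 37.0, k_diameters=2)
        on = localize_large(ct, box, 37.0, air_detection=True)
        off = localize_large(ct, box, 37.0, air_detection=False)
        assert not on.air.detected
        assert np.array_equal(on.center, off.center)


class TestLocalizeSmall:
    @pytest.fixture(scope="class")
    def wall_model(self, clean_truth):
        ct = clean_truth.ct_noiseless
        walls = []
        for i, d in ((6, 37.0), (5, 28.0), (4, 22.0)):
            box = extract_box(ct, _truth_vox(clean_truth, i), d, k_diameters=2)
            walls.append(localize_large(ct, box, d).wall_values)
        return learn_wall(walls)

    def test_noiseless_accuracy(self, clean_truth, wall_model):
        ct = clean_truth.ct_noiseless
        for i, d in ((1, 10.0), (2, 13.0), (3, 17.0)):
            box = extract_box(ct, _truth_vox(clean_truth, i), d, k_diameters=3)
            res = localize_small(ct, box, d, wall_model)
            assert _err_mm(clean_truth, i, res.center) < 0.5

    def test_displaced_estimate_recovers_same_center(self, clean_truth, wall_model):
        ct = clean_truth.ct_noiseless
        est = _truth_vox(clean_truth, 1)
        box_a = extract_box(ct, est, 10.0, k_diameters=3)
        box_b = extract_box(ct, est + np.array([3, 3, 3]), 10.0, k_diameters=3)  # ~8 mm off
        ca = localize_small(ct, box_a, 10.0, wall_model).center
        cb = localize_small(ct, box_b, 10.0, wall_model).center
        # box-edge voxels entering/leaving shift the subvolume statistics a
        # little; agreement to 0.1 mm is "the same center" at this spacing
        assert np.linalg.norm((ca - cb) * ct.spacing) < 0.1

    def test_small_path_consistent_with_large_path(self, clean_truth, wall_model):
        # the 22 mm sphere can be localized by either code path; the two
        # must agree
        ct = clean_truth.ct_noiseless
        est = _truth_vox(clean_truth, 4)
        big = localize_large(ct, extract_box(ct, est, 22.0, k_diameters=2), 22.0)
        small = localize_small(ct, extract_box(ct, est, 22.0, k_diameters=3), 22.0, wall_model)
        assert np.linalg.norm((big.center - small.center) * ct.spacing) < 0.3

    def test_bubbled_small_sphere_within_twice_clean_error(self, clean_truth, bubbled_truth, wall_model):
        i, d = 2, 13.0  # 4 mm bubble configured in sphere 2
        clean_ct = clean_truth.ct_noiseless
        bub_ct = bubbled_truth.ct_noiseless
        box_c = extract_box(clean_ct, _truth_vox(clean_truth, i), d, k_diameters=3)
        box_b = extract_box(bub_ct, _truth_vox(bubbled_truth, i), d, k_diameters=3)
        err_clean = _err_mm(clean_truth, i, localize_small(clean_ct, box_c, d, wall_model).center)
        res_b = localize_small(bub_ct, box_b, d, wall_model)
        err_bub = _err_mm(bubbled_truth, i, res_b.center)
        assert res_b.air.detected
        assert err_bub < max(2.0 * err_clean, 0.5)


def _localized_centers_world(truth_or_ct, estimates=None):
    if estimates is None:
        truth = truth_or_ct
        ct = truth.ct_noiseless
        estimates = {i: _truth_vox(truth, i) for i in (4, 5, 6)}
    else:
        ct = truth_or_ct
    vox, _, _ = localize_spheres(ct, estimates)
    return np.array([ct.voxel_to_world(vox[i]) for i in range(1, 7)])


class TestFullCTLocalization:
    def test_transformed_copy_preserves_distances(self, clean_truth):
        # an exact grid isometry of the volume (90 deg in-plane rotation:
        # in-plane spacings are equal) must preserve all pairwise sphere
        # distances of the localization result
        ct = clean_truth.ct_noiseless
        rot = ImageVolume(
            voxels=np.rot90(ct.voxels, k=1, axes=(1, 2)).copy(),
            spacing=ct.spacing, origin=ct.origin, orientation=ct.orientation,
            modality="CT",
        )
        n2 = ct.shape[2]
        est = {i: _truth_vox(clean_truth, i) for i in (4, 5, 6)}
        # rot90 over axes (1,2): voxel (a, b, c) moves to (a, n2-1-c, b)
        est_rot = {i: np.array([e[0], n2 - 1 - e[2], e[1]]) for i, e in est.items()}
        base = _localized_centers_world(clean_truth)
        moved = _localized_centers_world(rot, est_rot)
        deltas = distance_discrepancies(base, moved)
        assert max(deltas.values()) < 0.2

    def test_repositioned_phantom_nearly_isometric(self, clean_truth):
        # re-rendering the phantom rotated ~150 deg on the bed (fresh
        # rasterization at a new sub-voxel phase): pairwise distances stay
        # nearly isometric, at the level the physical repositioning
        # experiment showed (discrepancies a few tenths of a millimeter)
        moved_cfg = PhantomConfig(
            ct_noise_sd_hu=0.0, pet_noise_sd=0.0,
            hexagon_angle0_deg=97.0 + 150.0, center_mm=(-4.0, 6.0, 1.3),
        )
        moved = render_noiseless(moved_cfg)
        deltas = distance_discrepancies(
            _localized_centers_world(clean_truth), _localized_centers_world(moved)
        )
        vals = np.array(list(deltas.values()))
        assert vals.mean() < 0.2
        assert vals.max() < 0.6
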