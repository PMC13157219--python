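"""Phenotype alignment: pinhole projection, IOU matching, area, inclination."""

import numpy as np
import pytest

from plantfill.cloud import PointCloud, RigidTransform, apply_rigid, rotate_z
from plantfill.phenotype import (
    CameraModel,
    InstanceMask,
    camera_to_world,
    extract_leaf_clusters,
    leaf_area,
    leaf_inclination,
    mask_iou,
    project_pinhole,
    world_to_camera,
)
from plantfill.synthetic import PlantSpec, generate_plant


def simple_camera(H=64, W=64, f=32.0):
    k = np.array([[f, 0, W / 2], [0, f, H / 2], [0, 0, 1.0]])
    return CameraModel(k, RigidTransform.identity(), H, W)


class TestFrames:
    def test_identity_and_translation(self):
        t = RigidTransform(np.eye(3), [1.0, 2.0, 3.0])
        np.testing.assert_allclose(camera_to_world(np.zeros((1, 3)), t), [[1, 2, 3]])

    def test_round_trip(self, rng):
        rot = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1.0]])
        t = RigidTransform(rot, rng.normal(size=3))
        p = rng.normal(size=(10, 3))
        np.testing.assert_allclose(world_to_camera(camera_to_world(p, t), t), p, atol=1e-12)


class TestPinhole:
    def test_unit_intrinsics_example(self):
        cam = CameraModel(np.eye(3), RigidTransform.identity(), 2, 2)
        uv, valid = project_pinhole(np.array([[1.0, 1.0, 2.0]]), cam)
        np.testing.assert_allclose(uv[0], [0.5, 0.5])
        assert valid[0]

    def test_point_behind_camera_invalid(self):
        cam = simple_camera()
        _, valid = project_pinhole(np.array([[0.0, 0, -1.0]]), cam)
        assert not valid[0]

    def test_focal_length_scales_offset(self):
        p = np.array([[0.5, 0.0, 2.0]])
        cam1 = simple_camera(f=16.0)
        cam2 = simple_camera(f=32.0)
        u1 = project_pinhole(p, cam1)[0][0, 0] - 32
        u2 = project_pinhole(p, cam2)[0][0, 0] - 32
        assert u2 == pytest.approx(2 * u1)

    def test_extrinsics_equivalence(self, rng):
        # projecting world points == projecting camera-frame points with identity [R|t]
        rot = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1.0]])
        t = RigidTransform(rot, [0.1, -0.2, 0.3])
        cam_w = CameraModel(simple_camera().intrinsics, t, 64, 64)
        cam_c = simple_camera()
        p_w = rng.uniform(-0.3, 0.3, (20, 3)) + [0, 0, 0]
        p_c = t.apply(p_w)
        uv_w, ok_w = project_pinhole(p_w, cam_w)
        uv_c, ok_c = project_pinhole(p_c, cam_c)
        np.testing.assert_allclose(uv_w, uv_c, atol=1e-9)
        np.testing.assert_array_equal(ok_w, ok_c)

    def test_validation(self):
        with pytest.raises(ValueError):
            CameraModel(np.diag([-1.0, 1, 1]), RigidTransform.identity(), 4, 4)


class TestMaskIOU:
    def test_identical_sets(self):
        m = InstanceMask(np.eye(4, dtype=bool), 0)
        pix = {(i, i) for i in range(4)}
        assert mask_iou(m, pix) == 1.0

    def test_disjoint_sets(self):
        m = InstanceMask(np.eye(4, dtype=bool), 0)
        assert mask_iou(m, {(0, 1), (1, 2)}) == 0.0

    def test_half_overlap_equal_sizes(self):
        pixels = np.zeros((4, 4), dtype=bool)
        pixels[0, 0] = pixels[0, 1] = True
        m = InstanceMask(pixels, 0)
        assert mask_iou(m, {(0, 1), (0, 2)}) == pytest.approx(1 / 3)


class TestExtractLeafClusters:
    def _plant_setup(self):
        plant = generate_plant(PlantSpec(n_leaves=2, leaf_scale=0.7, curvature=0.2,
                                         seed=9, points_total=5000))
        # camera above, looking down (+z is down in this camera frame)
        rot = np.diag([1.0, -1.0, -1.0])
        t = RigidTransform(rot, np.array([0.0, 0.0, 2.5]))
        cam = CameraModel(
            np.array([[80.0, 0, 64], [0, 80.0, 64], [0, 0, 1]]),
            t, 128, 128,
        )
        return plant, cam

    def _perfect_masks(self, plant, cam):
        masks = []
        for leaf in (1, 2):
            pts = plant.points[plant.labels == leaf]
            uv, valid = project_pinhole(pts, cam)
            pix = np.zeros((cam.height, cam.width), dtype=bool)
            cc = np.rint(uv[valid]).astype(int)
            pix[np.clip(cc[:, 1], 0, 127), np.clip(cc[:, 0], 0, 127)] = True
            # dilate so rounding never drops boundary points
            grown = pix.copy()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    grown |= np.roll(np.roll(pix, dr, 0), dc, 1)
            masks.append(InstanceMask(grown, leaf))
        return masks

    def test_single_covering_mask_claims_whole_cloud(self):
        plant, cam = self._plant_setup()
        full = InstanceMask(np.ones((128, 128), dtype=bool), 0)
        clusters = extract_leaf_clusters(plant, [full], cam, tau_iou=0.01)
        assert len(clusters) == 1
        uv, valid = project_pinhole(plant.points, cam)
        assert len(clusters[0][1]) == int(valid.sum())

    def test_no_passing_mask_warns_and_returns_empty(self):
        plant, cam = self._plant_setup()
        tiny = np.zeros((128, 128), dtype=bool)
        tiny[0, 0] = True
        with pytest.warns(UserWarning):
            assert extract_leaf_clusters(plant, [InstanceMask(tiny, 0)], cam) == []

    def test_clusters_disjoint_and_within_cloud(self):
        plant, cam = self._plant_setup()
        masks = self._perfect_masks(plant, cam)
        clusters = extract_leaf_clusters(plant, masks, cam, tau_iou=0.01)
        ids = [set(map(tuple, c.points)) for _, c in clusters]
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                assert not ids[i] & ids[j]

    def test_perfect_masks_recover_leaf_labels(self):
        plant, cam = self._plant_setup()
        masks = self._perfect_masks(plant, cam)
        clusters = extract_leaf_clusters(plant, masks, cam, tau_iou=0.01)
        assert len(clusters) == 2
        for mask, cluster in clusters:
            want = plant.points[plant.labels == mask.instance_id]
            got = {tuple(p) for p in cluster.points}
            overlap = sum(tuple(p) in got for p in want) / len(want)
            assert overlap > 0.95


class TestLeafArea:
    def test_unit_square_grid(self, rng):
        g = np.linspace(0, 1, 25)
        xx, yy = np.meshgrid(g, g)
        pts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
        assert leaf_area(PointCloud(pts)) == pytest.approx(1.0, rel=0.02)

    def test_rigid_invariance(self, rng):
        g = np.linspace(0, 1, 20)
        xx, yy = np.meshgrid(g, g)
        pts = np.column_stack([xx.ravel(), yy.ravel(), 0.1 * np.sin(3 * xx.ravel())])
        cloud = PointCloud(pts)
        a0 = leaf_area(cloud)
        rot = apply_rigid(rotate_z(cloud, 33),
                          RigidTransform(np.eye(3), [0.5, -1.0, 2.0]))
        assert leaf_area(rot) == pytest.approx(a0, rel=1e-6)

    def test_bent_synthetic_leaf_matches_surface_integral(self):
        from plantfill.synthetic import leaf_surface

        spec = PlantSpec(n_leaves=1, seed=3, points_total=9000)
        cloud = generate_plant(spec)
        leaf = cloud.select(np.flatnonzero(cloud.labels == 1))
        # numerical surface integral of the parametric patch (first
        # fundamental form on a fine grid), independent of the triangulation
        u = np.linspace(0.04, 1.0, 400)
        v = np.linspace(-1.0, 1.0, 400)
        uu, vv = np.meshgrid(u, v, indexing="ij")
        s = leaf_surface(spec, 1, uu.ravel(), vv.ravel()).reshape(400, 400, 3)
        su = np.gradient(s, u, axis=0)
        sv = np.gradient(s, v, axis=1)
        da = np.linalg.norm(np.cross(su, sv), axis=2)
        exact = np.trapezoid(np.trapezoid(da, v, axis=1), u)
        assert leaf_area(leaf) == pytest.approx(exact, rel=0.05)

    def test_collinear_rejected(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        with pytest.raises(ValueError):
            leaf_area(PointCloud(pts))


class TestLeafInclination:
    @staticmethod
    def _flat_leaf(rng, n=200):
        return np.column_stack([rng.uniform(-1, 1, (n, 2)), np.zeros(n)])

    def test_horizontal_leaf_zero(self, rng):
        assert leaf_inclination(PointCloud(self._flat_leaf(rng))) == pytest.approx(0.0, abs=1e-9)

    def test_vertical_leaf_ninety(self, rng):
        pts = self._flat_leaf(rng)[:, [0, 2, 1]]  # rotate into the xz plane
        assert leaf_inclination(PointCloud(pts)) == pytest.approx(90.0, abs=1e-9)

    @pytest.mark.parametrize("theta", [10.0, 35.0, 62.0])
    def test_known_tilt_recovered(self, rng, theta):
        pts = self._flat_leaf(rng)
        c, s = np.cos(np.radians(theta)), np.sin(np.radians(theta))
        rot = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
        tilted = PointCloud(pts @ rot.T)
        assert leaf_inclination(tilted) == pytest.approx(theta, abs=0.5)

    def test_in_plane_rotation_invariance(self, rng):
        pts = self._flat_leaf(rng)
        c, s = np.cos(0.4), np.sin(0.4)
        rot = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
        cloud = PointCloud(pts @ rot.T)
        assert leaf_inclination(rotate_z(cloud, 71)) == pytest.approx(
            leaf_inclination(cloud), abs=1e-6
        )
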