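"""Virtual camera: projection, DARE silhouettes, visibility partitioning."""

import numpy as np
import pytest

from plantfill.cloud import PointCloud, apply_rigid, RigidTransform, ifps_indices, normalize
from plantfill.camera import (
    VirtualCamera,
    camera_for_viewpoint,
    dare_radius,
    partition_visibility,
    plane_uv,
    project_point,
    render_silhouette,
    sample_viewpoints,
    silhouette_mask,
)
from plantfill.synthetic import PlantSpec, generate_plant


class TestViewpoints:
    def test_cameras_on_sphere(self, rng):
        cloud = PointCloud(rng.normal(size=(100, 3)))
        cams = sample_viewpoints(cloud, 10, seed=0)
        for cam in cams:
            assert np.isclose(np.linalg.norm(cam.p_view - cam.p_cen), cam.radius, atol=1e-6)
            basis = np.stack([cam.basis_u, cam.basis_v, cam.n_hat])
            np.testing.assert_allclose(basis @ basis.T, np.eye(3), atol=1e-9)

    def test_seed_determinism(self, rng):
        cloud = PointCloud(rng.normal(size=(50, 3)))
        a = sample_viewpoints(cloud, 5, seed=3)
        b = sample_viewpoints(cloud, 5, seed=3)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.p_view, cb.p_view)

    def test_uniformity_over_many_draws(self, rng):
        cloud = PointCloud(rng.normal(size=(20, 3)))
        cams = sample_viewpoints(cloud, 10_000, seed=1)
        offsets = np.stack([c.p_view - c.p_cen for c in cams])
        radius = cams[0].radius
        se = radius / np.sqrt(3) / np.sqrt(len(cams))
        assert np.all(np.abs(offsets.mean(axis=0)) < 3 * se)

    def test_radius_factor_validation(self, rng):
        cloud = PointCloud(rng.normal(size=(10, 3)))
        with pytest.raises(ValueError):
            sample_viewpoints(cloud, 1, radius_factor=0.4)


class TestProjection:
    def test_drop_z_example(self):
        cam = camera_for_viewpoint([0, 0, -5], [0, 0, 0])
        np.testing.assert_allclose(project_point(np.array([1.0, 2, 3]), cam), [1, 2, 0], atol=1e-12)

    def test_point_on_plane_is_fixed(self):
        cam = camera_for_viewpoint([3, 1, 2], [0, 0, 0])
        n = cam.normal
        p = np.cross(n, [0, 0, 1.0])  # orthogonal to n, so on the plane
        np.testing.assert_allclose(project_point(p, cam), p, atol=1e-12)

    def test_plane_membership_random(self, rng):
        cam = camera_for_viewpoint(rng.normal(size=3) * 5, rng.normal(size=3))
        pts = rng.normal(size=(100, 3))
        proj = project_point(pts, cam)
        assert np.abs((proj - cam.p_cen) @ cam.normal).max() < 1e-9

    def test_center_maps_to_center_pixel(self):
        cam = camera_for_viewpoint([0, 0, -5], [0, 0, 0])
        row, col, depth, ok = plane_uv(cam.p_cen, cam, 64, 64, scale=0.1)
        assert (row[0], col[0]) == (32, 32) and ok[0]

    def test_basis_u_step_moves_one_column(self):
        cam = camera_for_viewpoint([0, 0, -5], [0, 0, 0])
        scale = 0.25
        p0 = cam.p_cen + 0.0
        p1 = cam.p_cen + scale * cam.basis_u
        _, c0, _, _ = plane_uv(p0, cam, 64, 64, scale)
        _, c1, _, _ = plane_uv(p1, cam, 64, 64, scale)
        assert c1[0] == c0[0] + 1

    def test_depth_ordering_on_optical_axis(self):
        cam = camera_for_viewpoint([0, 0, -5], [0, 0, 0])
        pts = np.array([[0, 0, -2.0], [0, 0, 0.0], [0, 0, 3.0]])
        _, _, depth, _ = plane_uv(pts, cam, 64, 64, 0.1)
        dist = np.linalg.norm(pts - cam.p_view, axis=1)
        assert np.all(np.argsort(depth) == np.argsort(dist))
        assert depth[0] < 0  # toward the camera is negative


class TestDare:
    def test_arithmetic_example(self):
        assert dare_radius(100, 400, eta=2.0) == 8

    def test_unit_density(self):
        assert dare_radius(500, 500, eta=1.0) == 1

    def test_monotone_in_visible_pixels(self):
        radii = [dare_radius(100, a, eta=1.0) for a in (100, 200, 400, 800)]
        assert radii == sorted(radii)

    def test_validation(self):
        with pytest.raises(ValueError):
            dare_radius(0, 10)
        with pytest.raises(ValueError):
            dare_radius(10, 10, eta=0.0)


def _interior_holes(pixels: np.ndarray) -> int:
    """Off pixels 4-connected-surrounded by on pixels."""
    interior = ~pixels[1:-1, 1:-1]
    return int(
        (interior & pixels[:-2, 1:-1] & pixels[2:, 1:-1]
         & pixels[1:-1, :-2] & pixels[1:-1, 2:]).sum()
    )


class TestRenderSilhouette:
    def test_single_point_disc_area(self):
        cloud = PointCloud([[0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        cam = camera_for_viewpoint([0, 0, -5], [0, 0, 0])
        sil = render_silhouette(cloud, cam, 64, 64, scale=0.1)
        r = sil.pixel_radius
        dr, dc = np.mgrid[-r:r + 1, -r:r + 1]
        assert sil.pixels.sum() == (dr**2 + dc**2 <= r**2).sum()

    def test_dense_planar_square_has_no_holes(self, rng):
        g = np.linspace(-1, 1, 40)
        xx, yy = np.meshgrid(g, g)
        pts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(1600)])
        cloud = PointCloud(pts + 1e-4 * rng.normal(size=pts.shape))
        cam = camera_for_viewpoint([0, 0, -6], [0, 0, 0])
        sil = render_silhouette(cloud, cam, 128, 128)
        assert _interior_holes(sil.pixels) == 0

    def test_eta_monotone(self, rng):
        cloud = PointCloud(rng.uniform(-1, 1, (200, 3)))
        cam = camera_for_viewpoint([0, 0, -6], [0, 0, 0])
        on = [render_silhouette(cloud, cam, 96, 96, eta=e).pixels.sum() for e in (0.5, 1.0, 2.0)]
        assert on == sorted(on)

    def test_out_of_frame_error(self):
        cloud = PointCloud([[100.0, 100, 100], [101.0, 100, 100]])
        cam = camera_for_viewpoint([0, 0, -5], [0, 0, 0])
        with pytest.raises(ValueError, match="scale"):
            render_silhouette(cloud, cam, 32, 32, scale=1e-6)


class TestPartition:
    def test_two_points_on_one_ray(self):
        cloud = PointCloud([[0, 0, -1.0], [0, 0, 1.0], [5, 0, 0.0], [0, 5, 0.0]])
        cam = camera_for_viewpoint([0, 0, -20], [0, 0, 0])
        part = partition_visibility(cloud, cam, missing_size=1, depth_tol=0.1)
        assert list(part.missing_indices) == [1]  # the farther of the stacked pair
        assert 0 in part.visible_indices

    def test_disjoint_cover_with_exact_sizes(self, plant_2048):
        cam = sample_viewpoints(plant_2048, 1, seed=4)[0]
        part = partition_visibility(plant_2048, cam, 512)
        assert len(part.visible) == 1536 and len(part.missing) == 512
        merged = np.sort(np.concatenate([part.visible_indices, part.missing_indices]))
        np.testing.assert_array_equal(merged, np.arange(2048))

    def test_rigid_invariance(self, rng):
        cloud = PointCloud(rng.uniform(-1, 1, (300, 3)))
        cam = sample_viewpoints(cloud, 1, seed=0)[0]
        part = partition_visibility(cloud, cam, 60, seed=1)
        rot = RigidTransform(
            np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1.0]]), np.array([0.3, -0.2, 0.5])
        )
        cloud_r = apply_rigid(cloud, rot)
        cam_r = camera_for_viewpoint(rot.apply(cam.p_view[None])[0], rot.apply(cam.p_cen[None])[0])
        part_r = partition_visibility(cloud_r, cam_r, 60, seed=1)
        np.testing.assert_array_equal(part.missing_indices, part_r.missing_indices)

    def test_size_error(self, rng):
        cloud = PointCloud(rng.normal(size=(10, 3)))
        cam = sample_viewpoints(cloud, 1, seed=0)[0]
        with pytest.raises(ValueError):
            partition_visibility(cloud, cam, 10)


class TestSilhouetteMask:
    def test_source_cloud_fully_kept(self, plant_2048):
        cams = sample_viewpoints(plant_2048, 5, seed=2)
        sils = [render_silhouette(plant_2048, c, 128, 128) for c in cams]
        keep = silhouette_mask(plant_2048, sils)
        assert keep.mean() >= 0.99

    def test_missing_region_kept_against_own_views(self, plant_2048):
        cams = sample_viewpoints(plant_2048, 5, seed=3)
        sils = [render_silhouette(plant_2048, c, 128, 128) for c in cams]
        part = partition_visibility(plant_2048, cams[0], 512)
        keep = silhouette_mask(part.missing, sils)
        assert keep.mean() >= 0.99

    def test_outlier_removed(self, plant_2048):
        cams = sample_viewpoints(plant_2048, 3, seed=4)
        sils = [render_silhouette(plant_2048, c, 128, 128) for c in cams]
        outlier = PointCloud(np.vstack([plant_2048.points[:5], [[50.0, 50, 50]]]))
        keep = silhouette_mask(outlier, sils)
        assert keep[-1] == False  # noqa: E712

    def test_keep_fraction_monotone_in_views(self, plant_2048, rng):
        cams = sample_viewpoints(plant_2048, 6, seed=5)
        sils = [render_silhouette(plant_2048, c, 128, 128) for c in cams]
        probe = PointCloud(rng.uniform(-1.2, 1.2, (500, 3)))
        fracs = [silhouette_mask(probe, sils[:k]).mean() for k in (1, 3, 6)]
        assert fracs[0] >= fracs[1] >= fracs[2]

    def test_empty_list_rejected(self, plant_2048):
        with pytest.raises(ValueError):
            silhouette_mask(plant_2048, [])


class TestConvexSurfaceSanity:
    def test_hemisphere_facing_camera_mostly_visible(self):
        rng = np.random.default_rng(0)
        # hemisphere opening away from the camera: the camera sees the dome
        u = rng.uniform(0, 1, 3000)
        phi = rng.uniform(0, 2 * np.pi, 3000)
        z = u  # upper half, camera above
        r = np.sqrt(1 - z**2)
        pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
        cloud = PointCloud(pts)
        cam = camera_for_viewpoint([0, 0, 6.0], centroid := pts.mean(axis=0))
        part = partition_visibility(cloud, cam, missing_size=1)
        assert part.raw_occluded / len(cloud) < 0.05
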