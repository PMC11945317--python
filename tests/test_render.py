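"""Projection, alpha compositing, contribution tracking and point colouring."""

import numpy as np
import pytest

from splatplant import (CameraView, GaussianScene, PointCloud, SamplerConfig,
                        assign_point_colors, build_point_cloud, eval_sh_color,
                        project_gaussian, render_with_contributions)
from splatplant.render import ALPHA_MAX, COV2D_DILATION, SUPPORT_SD, _project_all
from splatplant.scene import SH_C0

from conftest import random_scene


def camera_at(pos, target=(0, 0, 0), width=32, height=32, f=40.0,
              near_clip=0.25):
    from splatplant.views import look_at
    return CameraView(width=width, height=height, fx=f, fy=f,
                      cx=width / 2.0, cy=height / 2.0,
                      c2w=look_at(pos, target), convention="opengl",
                      near_clip=near_clip)


def gray_scene(means, scales, opacities, rgbs):
    n = len(means)
    sh = np.zeros((n, 3, 16))
    sh[:, :, 0] = (np.asarray(rgbs, dtype=float) - 0.5) / SH_C0
    q = np.tile([1.0, 0, 0, 0], (n, 1))
    return GaussianScene(means=means, scales=scales, rotations=q,
                         opacities=opacities, sh_coeffs=sh)


class TestProjection:
    def test_on_axis_projects_to_principal_point(self):
        scene = gray_scene([[0, 0, 0]], [[1e-3] * 3], [1.0], [[0.5] * 3])
        view = camera_at([1.0, 0, 0])
        mean2d, _, depth = project_gaussian(scene, 0, view)
        np.testing.assert_allclose(mean2d, [view.cx, view.cy], atol=1e-9)
        assert depth == pytest.approx(1.0)

    def test_isotropic_covariance_on_axis(self):
        sigma, z, f = 2e-3, 0.8, 40.0
        scene = gray_scene([[0, 0, 0]], [[sigma] * 3], [1.0], [[0.5] * 3])
        _, cov2d, _ = project_gaussian(scene, 0, camera_at([z, 0, 0], f=f))
        expected = (f * sigma / z) ** 2 * np.eye(2) + COV2D_DILATION * np.eye(2)
        np.testing.assert_allclose(cov2d, expected, rtol=1e-9, atol=1e-12)

    def test_near_clip_culls(self):
        scene = gray_scene([[0, 0, 0]], [[1e-3] * 3], [1.0], [[0.5] * 3])
        assert project_gaussian(scene, 0, camera_at([0.2, 0, 0])) is None
        assert project_gaussian(scene, 0, camera_at([0.26, 0, 0])) is not None


def reference_render(scene, views):
    """Independent per-pixel compositing oracle (pure loops).

    Same semantics as the renderer: depth sort by camera-frame mean
    depth, alpha zero outside the 3-SD 2D ellipse, alpha ceiling, white
    background. Returns (images, per-Gaussian best weight/camera/pixel,
    total weight, per-pixel weight sums).
    """
    n = scene.count
    best_w = np.zeros(n)
    best_cam = np.full(n, -1)
    best_px = np.full((n, 2), -1)
    total_w = np.zeros(n)
    images, wsums = [], []
    from splatplant.scene import eval_sh_colors

    for cam_idx, view in enumerate(views):
        mean2d, cov2d, depth, valid = _project_all(scene, view)
        dirs = scene.means - view.center
        colors = eval_sh_colors(scene, dirs / np.linalg.norm(dirs, axis=1,
                                                             keepdims=True))
        order = sorted(np.flatnonzero(valid), key=lambda g: depth[g])
        img = np.zeros((view.height, view.width, 3))
        wsum = np.zeros((view.height, view.width))
        for row in range(view.height):
            for col in range(view.width):
                T = 1.0
                for g in order:
                    d = np.array([col, row]) - mean2d[g]
                    m2 = d @ np.linalg.inv(cov2d[g]) @ d
                    if m2 > SUPPORT_SD**2:
                        continue
                    alpha = min(scene.opacities[g] * np.exp(-0.5 * m2), ALPHA_MAX)
                    w = alpha * T
                    img[row, col] += w * colors[g]
                    wsum[row, col] += w
                    total_w[g] += w
                    if w > best_w[g]:
                        best_w[g] = w
                        best_cam[g] = cam_idx
                        best_px[g] = (row, col)
                    T *= 1 - alpha
                img[row, col] += T
        images.append(np.clip(img, 0, 1))
        wsums.append(wsum)
    return images, best_w, best_cam, best_px, total_w, wsums


class TestCompositing:
    def test_single_opaque_splat_pixel_colour(self):
        # colour chosen near gray so the <=1% background bleed through the
        # alpha ceiling stays below one unit of 255
        rgb = [0.75, 0.7, 0.72]
        scene = gray_scene([[0, 0, 0]], [[5e-3] * 3], [1.0], [rgb])
        view = camera_at([0.8, 0, 0])
        res = render_with_contributions(scene, [view])
        px = res.table.best_pixel[0]
        got = res.images[0][px[0], px[1]]
        want = eval_sh_color(scene, 0, (scene.means[0] - view.center)
                             / np.linalg.norm(scene.means[0] - view.center))
        assert np.abs(got - want).max() <= 1.0 / 255.0

    def test_back_splat_weight_capped_by_front_transmittance(self):
        # 1-pixel camera centred on two coincident splats: the only pixel
        # is the shared peak, where the front alpha is clipped to 0.99 and
        # the back weight is the hand-computed transmittance product
        from splatplant.views import look_at
        means = [[0, 0, 0], [0, 0, 0]]
        scene = gray_scene(means, [[5e-3] * 3] * 2, [1.0, 0.5],
                           [[0.9, 0.1, 0.1], [0.1, 0.9, 0.1]])
        view = CameraView(width=1, height=1, fx=40, fy=40, cx=0.0, cy=0.0,
                          c2w=look_at([0.8, 0, 0], [0, 0, 0]))
        res = render_with_contributions(scene, [view])
        # equal depth: stable sort puts index 0 (opacity 1) in front
        assert res.table.best_weight[0] == pytest.approx(ALPHA_MAX)
        assert res.table.best_weight[1] == pytest.approx((1 - ALPHA_MAX) * 0.5)

    def test_weights_plus_transmittance_is_one(self):
        rng = np.random.default_rng(21)
        scene = random_scene(rng, 12, scale_range=(2e-3, 8e-3), extent=0.05)
        views = [camera_at([0.7, 0, 0]), camera_at([0, 0.7, 0.1])]
        res = render_with_contributions(scene, views)
        for w, T in zip(res.weight_sum, res.transmittance):
            np.testing.assert_allclose(w + T, 1.0, atol=1e-6)

    def test_matches_per_pixel_oracle(self):
        rng = np.random.default_rng(22)
        scene = random_scene(rng, 10, scale_range=(2e-3, 8e-3), extent=0.05)
        views = [camera_at([0.7, 0, 0], width=24, height=24),
                 camera_at([0, 0.7, 0.1], width=24, height=24)]
        res = render_with_contributions(scene, views)
        images, best_w, best_cam, best_px, total_w, wsums = \
            reference_render(scene, views)
        np.testing.assert_allclose(res.table.best_weight, best_w, atol=1e-9)
        np.testing.assert_array_equal(res.table.best_camera, best_cam)
        np.testing.assert_array_equal(res.table.best_pixel, best_px)
        np.testing.assert_allclose(res.table.total_weight, total_w, atol=1e-7)
        for got, want in zip(res.images, images):
            np.testing.assert_allclose(got, want, atol=1e-9)

    def test_rendering_is_deterministic(self):
        rng = np.random.default_rng(23)
        scene = random_scene(rng, 8, extent=0.05)
        views = [camera_at([0.7, 0, 0])]
        a = render_with_contributions(scene, views)
        b = render_with_contributions(scene, views)
        np.testing.assert_array_equal(a.images[0], b.images[0])
        np.testing.assert_array_equal(a.table.best_weight, b.table.best_weight)


class TestColourAssignment:
    def test_opaque_gaussian_colours_all_points(self):
        rgb = [0.8, 0.15, 0.1]
        scene = gray_scene([[0, 0, 0]], [[5e-3] * 3], [1.0], [rgb])
        cloud = build_point_cloud(scene, SamplerConfig(total_points=500,
                                                       top_volume_frac=0.0))
        res = render_with_contributions(scene, [camera_at([0.8, 0, 0])])
        colored = assign_point_colors(cloud, res.table, res.images)
        # one best pixel -> one colour for every point; ~1% white bleed allowed
        assert len(np.unique(colored.colors, axis=0)) == 1
        np.testing.assert_allclose(colored.colors[0], np.array(rgb) * 255,
                                   atol=3.0)

    def test_distinct_gaussians_keep_their_own_colour(self):
        scene = gray_scene([[0, 0.03, 0], [0, -0.03, 0]], [[3e-3] * 3] * 2,
                           [1.0, 1.0], [[0.8, 0.2, 0.2], [0.2, 0.2, 0.8]])
        views = [camera_at([0.6, 0, 0], width=16, height=16),
                 camera_at([0.6, 0.1, 0.1], width=16, height=16)]
        res = render_with_contributions(scene, views)
        cloud = PointCloud(positions=scene.means, source_index=[0, 1])
        colored = assign_point_colors(cloud, res.table, res.images)
        assert colored.colors[0, 0] > 150 and colored.colors[0, 2] < 100
        assert colored.colors[1, 2] > 150 and colored.colors[1, 0] < 100

    def test_hidden_gaussian_takes_its_own_peak_pixel(self):
        # near-transparent splat behind an opaque one: colour must come from
        # the pixel where its own weight peaked, not an unrelated pixel
        scene = gray_scene([[0, 0, 0], [-0.01, 0, 0]], [[4e-3] * 3] * 2,
                           [0.05, 1.0], [[0.2, 0.8, 0.2], [0.8, 0.2, 0.2]])
        view = camera_at([0.8, 0, 0])  # opaque one is in front
        res = render_with_contributions(scene, [view])
        assert not res.table.unseen[0]
        mean2d, _, _ = project_gaussian(scene, 0, view)
        px = res.table.best_pixel[0]
        # own weight peak sits inside the splat's small 2D support, never
        # at an unrelated background pixel
        assert np.hypot(px[1] - mean2d[0], px[0] - mean2d[1]) <= 3.0

    def test_unseen_gaussian_gets_fallback_colour(self):
        from splatplant import dc_fallback_colors
        scene = gray_scene([[0, 0, 0], [10.0, 0, 0]], [[4e-3] * 3] * 2,
                           [1.0, 1.0], [[0.6, 0.6, 0.6], [0.1, 0.9, 0.1]])
        res = render_with_contributions(scene, [camera_at([0.8, 0, 0])])
        assert res.table.unseen[1]
        cloud = PointCloud(positions=scene.means, source_index=[0, 1])
        colored = assign_point_colors(cloud, res.table, res.images,
                                      dc_fallback_colors(scene))
        np.testing.assert_allclose(colored.colors[1],
                                   [0.1 * 255, 0.9 * 255, 0.1 * 255], atol=1)
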