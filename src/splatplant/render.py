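"""Perspective alpha-compositing splat renderer with contribution tracking.

Gaussians are projected to image-plane 2D Gaussians via the local affine
pinhole Jacobian (EWA-style), depth-sorted by camera-frame mean depth,
and composited front to back: Gaussian i contributes weight
``w_i = alpha_i * prod_{j<i} (1 - alpha_j)`` at each pixel, with
``alpha_i = opacity_i * exp(-0.5 d^T Sigma2D^{-1} d)`` clipped at 0.99.
Support is limited to the 3-SD 2D Mahalanobis ellipse (alpha treated as
zero outside). The renderer records, per Gaussian, the pixel (over all
cameras) where its compositing weight peaked — the signal used to give
extracted points colours that match the final rendered scene rather than
their own (possibly transparent or occluded) splat colour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .pointcloud import PointCloud
from .scene import SH_C0, GaussianScene, covariances, eval_sh_colors

logger = logging.getLogger(__name__)

#: 2D covariance dilation in px^2 (anti-aliasing, reference-rasteriser value).
COV2D_DILATION = 0.3
#: Per-splat alpha ceiling keeping transmittance strictly positive.
ALPHA_MAX = 0.99
#: Support cutoff in 2D Mahalanobis SD units.
SUPPORT_SD = 3.0


@dataclass
class CameraView:
    """Pinhole camera with a metric camera-to-world pose.

    ``convention`` tags the axis convention of ``c2w``: "opencv"
    (+x right, +y down, +z forward) or "opengl" (+x right, +y up,
    -z forward, the transforms.json convention).
    """

    width: int
    height: int
    fx: float
    fy: float
    cx: float
    cy: float
    c2w: np.ndarray
    convention: str = "opengl"
    near_clip: float = 0.25
    far_clip: float = np.inf

    def __post_init__(self):
        self.c2w = np.asarray(self.c2w, dtype=float).reshape(4, 4)
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if self.convention not in ("opengl", "opencv"):
            raise ValueError(f"unknown convention {self.convention!r}")
        R = self.c2w[:3, :3]
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("c2w rotation block is not orthonormal")

    @property
    def center(self) -> np.ndarray:
        return self.c2w[:3, 3]

    def c2w_opencv(self) -> np.ndarray:
        """Pose with the camera axes in OpenCV convention."""
        if self.convention == "opencv":
            return self.c2w
        flip = np.diag([1.0, -1.0, -1.0, 1.0])
        return self.c2w @ flip

    def w2c_opencv(self) -> np.ndarray:
        c2w = self.c2w_opencv()
        R = c2w[:3, :3]
        t = c2w[:3, 3]
        w2c = np.eye(4)
        w2c[:3, :3] = R.T
        w2c[:3, 3] = -R.T @ t
        return w2c


@dataclass
class ContributionTable:
    """Per-Gaussian best (camera, pixel) and accumulated compositing weight.

    ``best_camera`` is -1 for Gaussians never composited ("unseen").
    """

    best_camera: np.ndarray
    best_pixel: np.ndarray   # (n, 2) int, (row, col)
    best_weight: np.ndarray
    total_weight: np.ndarray

    @property
    def unseen(self) -> np.ndarray:
        return self.best_camera < 0

    @classmethod
    def empty(cls, n: int) -> "ContributionTable":
        return cls(
            best_camera=np.full(n, -1, dtype=np.int64),
            best_pixel=np.full((n, 2), -1, dtype=np.int64),
            best_weight=np.zeros(n),
            total_weight=np.zeros(n),
        )


@dataclass
class RenderResult:
    """Rendered images in [0, 1], per-view diagnostics and the table."""

    images: list            # each (H, W, 3) float in [0, 1]
    transmittance: list     # each (H, W): residual background weight
    weight_sum: list        # each (H, W): sum of compositing weights
    table: ContributionTable


def _project_all(scene: GaussianScene, view: CameraView):
    """Batched EWA projection of every Gaussian into one view.

    Returns (means2d (n,2) in (x=col, y=row) px, cov2d (n,2,2) px^2,
    depth (n,) m, valid mask). Invalid entries are those culled by the
    near/far clip.
    """
    w2c = view.w2c_opencv()
    W = w2c[:3, :3]
    p_cam = scene.means @ W.T + w2c[:3, 3]
    depth = p_cam[:, 2]
    valid = (depth >= view.near_clip) & (depth <= view.far_clip)
    z = np.where(depth == 0, 1.0, depth)
    x, y = p_cam[:, 0], p_cam[:, 1]
    mean2d = np.stack([view.fx * x / z + view.cx, view.fy * y / z + view.cy], axis=1)
    # local affine Jacobian of the pinhole map at the Gaussian centre
    n = scene.count
    J = np.zeros((n, 2, 3))
    J[:, 0, 0] = view.fx / z
    J[:, 0, 2] = -view.fx * x / z**2
    J[:, 1, 1] = view.fy / z
    J[:, 1, 2] = -view.fy * y / z**2
    JW = J @ W
    cov2d = JW @ covariances(scene) @ np.transpose(JW, (0, 2, 1))
    cov2d = cov2d + COV2D_DILATION * np.eye(2)
    return mean2d, cov2d, depth, valid


def project_gaussian(scene: GaussianScene, index: int, view: CameraView):
    """Project one Gaussian; returns (mean2d, cov2d, depth) or None if culled."""
    sub = scene.subset([index])
    mean2d, cov2d, depth, valid = _project_all(sub, view)
    if not valid[0]:
        return None
    return mean2d[0], cov2d[0], float(depth[0])


def render_with_contributions(scene: GaussianScene,
                              views: list[CameraView]) -> RenderResult:
    """Render every view over a white background, tracking contributions.

    Per pixel the compositing weights plus the residual transmittance sum
    to one; the table records the argmax-weight pixel per Gaussian with
    ties broken by lowest camera index then row-major pixel order.
    """
    if not views:
        raise ValueError("at least one view is required")
    table = ContributionTable.empty(scene.count)
    images, trans_maps, wsum_maps = [], [], []
    for cam_idx, view in enumerate(views):
        H, Wd = view.height, view.width
        mean2d, cov2d, depth, valid = _project_all(scene, view)
        dirs = scene.means - view.center
        nrm = np.linalg.norm(dirs, axis=1, keepdims=True)
        nrm = np.where(nrm == 0, 1.0, nrm)
        colors = eval_sh_colors(scene, dirs / nrm)

        # conservative per-Gaussian support radius: 3 SD of the major axis
        tr = cov2d[:, 0, 0] + cov2d[:, 1, 1]
        det = cov2d[:, 0, 0] * cov2d[:, 1, 1] - cov2d[:, 0, 1] ** 2
        lam_max = tr / 2 + np.sqrt(np.maximum(tr**2 / 4 - det, 0.0))
        radius = SUPPORT_SD * np.sqrt(np.maximum(lam_max, 0.0))
        on_image = (valid & (det > 0)
                    & (mean2d[:, 0] + radius >= 0) & (mean2d[:, 0] - radius <= Wd - 1)
                    & (mean2d[:, 1] + radius >= 0) & (mean2d[:, 1] - radius <= H - 1))
        order = np.flatnonzero(on_image)[np.argsort(depth[on_image], kind="stable")]

        T = np.ones((H, Wd))
        img = np.zeros((H, Wd, 3))
        wsum = np.zeros((H, Wd))
        inv = np.empty((2, 2))
        for g in order:
            c0 = max(0, int(np.floor(mean2d[g, 0] - radius[g])))
            c1 = min(Wd - 1, int(np.ceil(mean2d[g, 0] + radius[g])))
            r0 = max(0, int(np.floor(mean2d[g, 1] - radius[g])))
            r1 = min(H - 1, int(np.ceil(mean2d[g, 1] + radius[g])))
            if c1 < c0 or r1 < r0:
                continue
            a, b, c = cov2d[g, 0, 0], cov2d[g, 0, 1], cov2d[g, 1, 1]
            inv[0, 0], inv[1, 1] = c / det[g], a / det[g]
            inv[0, 1] = inv[1, 0] = -b / det[g]
            dx = np.arange(c0, c1 + 1) - mean2d[g, 0]
            dy = np.arange(r0, r1 + 1) - mean2d[g, 1]
            maha2 = (inv[0, 0] * dx[None, :] ** 2
                     + 2 * inv[0, 1] * dy[:, None] * dx[None, :]
                     + inv[1, 1] * dy[:, None] ** 2)
            alpha = scene.opacities[g] * np.exp(-0.5 * maha2)
            alpha[maha2 > SUPPORT_SD**2] = 0.0
            np.minimum(alpha, ALPHA_MAX, out=alpha)
            if not alpha.any():
                continue
            w = alpha * T[r0:r1 + 1, c0:c1 + 1]
            img[r0:r1 + 1, c0:c1 + 1] += w[:, :, None] * colors[g]
            wsum[r0:r1 + 1, c0:c1 + 1] += w
            table.total_weight[g] += w.sum()
            flat = int(np.argmax(w))  # first max in row-major patch order
            wmax = w.flat[flat]
            if wmax > table.best_weight[g]:
                table.best_weight[g] = wmax
                table.best_camera[g] = cam_idx
                table.best_pixel[g] = (r0 + flat // (c1 - c0 + 1),
                                       c0 + flat % (c1 - c0 + 1))
            T[r0:r1 + 1, c0:c1 + 1] *= 1.0 - alpha
        img += T[:, :, None]  # white background weighted by residual transmittance
        images.append(np.clip(img, 0.0, 1.0))
        trans_maps.append(T)
        wsum_maps.append(wsum)
    n_unseen = int(table.unseen.sum())
    if n_unseen:
        logger.info("%d of %d Gaussians unseen in all %d views",
                    n_unseen, scene.count, len(views))
    return RenderResult(images=images, transmittance=trans_maps,
                        weight_sum=wsum_maps, table=table)


def assign_point_colors(cloud: PointCloud, table: ContributionTable,
                        images: list,
                        fallback_colors: Optional[np.ndarray] = None) -> PointCloud:
    """Colour each point from its source Gaussian's most-contributed pixel.

    Points whose Gaussian was never composited fall back to
    ``fallback_colors`` (per-Gaussian RGB in [0, 1]; pass
    ``dc_fallback_colors(scene)`` for the DC spherical-harmonic colour);
    their count is logged. Colours are returned on the 0-255 scale.
    """
    if cloud.source_index is None:
        raise ValueError("cloud must carry source_index to be coloured")
    src = cloud.source_index
    n_g = len(table.best_camera)
    if fallback_colors is None:
        fallback_colors = np.full((n_g, 3), 0.5)
    gauss_rgb = np.asarray(fallback_colors, dtype=float).reshape(n_g, 3).copy()
    seen = ~table.unseen
    for cam in np.unique(table.best_camera[seen]):
        m = seen & (table.best_camera == cam)
        px = table.best_pixel[m]
        gauss_rgb[m] = images[cam][px[:, 0], px[:, 1]]
    unseen_pts = int(table.unseen[src].sum())
    if unseen_pts:
        logger.info("%d points take the DC fallback colour (unseen Gaussians)",
                    unseen_pts)
    colors = np.clip(np.rint(gauss_rgb[src] * 255.0), 0, 255)
    return PointCloud(positions=cloud.positions, colors=colors,
                      source_index=cloud.source_index)


def dc_fallback_colors(scene: GaussianScene) -> np.ndarray:
    """DC-only SH colour per Gaussian, in [0, 1] (used for unseen fallback)."""
    return np.clip(0.5 + scene.sh_coeffs[:, :, 0] * SH_C0, 0.0, 1.0)
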