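"""Parametric toy plant scenes with known ground truth.

The generator builds a wheat-like Gaussian scene: a vertical stem made
of a dense chain of thin elongated Gaussians, curved leaf chains
branching off it, and sparse background clutter placed well away from
the plant. Plant Gaussians have sub-1.25-mm 1-SD axes so the default
axis-mode background size cull can never touch them, and clutter is
placed with a minimum mutual spacing that guarantees its 15-NN average
distance exceeds the 3.5-cm background threshold by construction. The
ground truth is a dense point cloud on the 1-SD ellipsoid surfaces of
the plant Gaussians only, which is the right comparison surface for
points sampled from the Gaussians' cores.

Everything is deterministic per seed, so the fixture stands in for a
real captured scene in tests without any download.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import EmptyResultError
from .imaging import make_mask
from .pointcloud import PointCloud
from .render import render_with_contributions
from .scene import SH_C0, GaussianScene
from .views import ViewPlan, write_transforms_json

logger = logging.getLogger(__name__)

#: Minimum clutter spacing (m); > knn threshold by a wide margin.
BACKGROUND_MIN_SPACING = 0.08
#: Longest 1-SD plant axis (m); diameter stays under the 2.5-mm size cull.
PLANT_AXIAL_SCALE = 0.0012


@dataclass
class PlantSceneSpec:
    """Parameters of the toy plant; defaults mimic a mid-growth wheat pot.

    ``gaussian_thickness`` is the full lateral thickness (m) of stem and
    leaf Gaussians, about 1 mm to emulate thin stem structures.
    """

    n_stem_segments: int = 250
    stem_height: float = 0.5
    leaf_count: int = 6
    leaf_length: float = 0.25
    gaussian_thickness: float = 0.001
    background_count: int = 30
    background_volume_scale: float = 50.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_stem_segments", "stem_height", "leaf_count", "leaf_length",
                     "gaussian_thickness", "background_count", "background_volume_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_stem_segments < 1 or self.stem_height <= 0:
            raise ValueError("need at least one stem segment and positive height")


def _quat_z_to(direction: np.ndarray) -> np.ndarray:
    """Unit quaternion (w, x, y, z) rotating +z onto ``direction``."""
    d = direction / np.linalg.norm(direction)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.clip(d @ z, -1.0, 1.0))
    if c > 1 - 1e-12:
        return np.array([1.0, 0.0, 0.0, 0.0])
    if c < -1 + 1e-12:
        return np.array([0.0, 1.0, 0.0, 0.0])  # 180 deg about x
    axis = np.cross(z, d)
    axis /= np.linalg.norm(axis)
    half = math.acos(c) / 2.0
    return np.concatenate([[math.cos(half)], math.sin(half) * axis])


def _dc_from_rgb(rgb) -> np.ndarray:
    """DC SH coefficients reproducing a target base colour."""
    return (np.asarray(rgb, dtype=float) - 0.5) / SH_C0


def _leaf_curve(t: np.ndarray, length: float, base: np.ndarray,
                azimuth: float) -> np.ndarray:
    """Arching leaf midline: rises and bows outward then droops."""
    out = np.array([math.cos(azimuth), math.sin(azimuth), 0.0])
    radial = t * length * 0.9
    lift = 0.45 * length * np.sin(np.pi * np.minimum(t * 0.85, 0.5))
    droop = 0.35 * length * t**2
    return base + radial[:, None] * out + (lift - droop)[:, None] * np.array([0, 0, 1.0])


def make_plant_scene(spec: PlantSceneSpec):
    """Build the fixture.

    Returns (scene, ground-truth PointCloud on plant 1-SD shells,
    per-Gaussian labels "plant" | "background").
    """
    rng = np.random.default_rng(spec.seed)
    lateral = spec.gaussian_thickness / 2.0
    means, scales, quats, colors = [], [], [], []

    # stem: dense chain of elongated Gaussians along +z
    zs = (np.arange(spec.n_stem_segments) + 0.5) / spec.n_stem_segments * spec.stem_height
    for z in zs:
        means.append([0.0, 0.0, z])
        scales.append([lateral, lateral, PLANT_AXIAL_SCALE])
        quats.append([1.0, 0.0, 0.0, 0.0])
        colors.append([0.25, 0.42, 0.15])

    # leaves: curved chains branching off the stem
    spacing = spec.stem_height / spec.n_stem_segments
    for j in range(spec.leaf_count):
        base_z = spec.stem_height * (0.25 + 0.6 * j / max(1, spec.leaf_count - 1))
        azimuth = j * 2.399963229728653  # golden angle spreads leaves evenly
        n_seg = max(2, int(round(spec.leaf_length / spacing)))
        t = (np.arange(n_seg) + 0.5) / n_seg
        pts = _leaf_curve(t, spec.leaf_length, np.array([0.0, 0.0, base_z]), azimuth)
        tangents = np.gradient(pts, axis=0)
        for p, tan in zip(pts, tangents):
            means.append(p)
            scales.append([lateral, lateral, PLANT_AXIAL_SCALE])
            quats.append(_quat_z_to(tan))
            colors.append([0.2 + 0.15 * rng.random(), 0.5, 0.12])

    n_plant = len(means)

    # background clutter: sparse, far from the plant, minimum mutual spacing
    plant_xy_extent = spec.leaf_length * 0.95
    bg_means = _scatter_background(rng, spec.background_count, plant_xy_extent,
                                   spec.stem_height)
    bg_kinds = np.arange(spec.background_count) % 3  # 0 big-in, 1 big-out, 2 small-in
    for i, p in enumerate(bg_means):
        if bg_kinds[i] == 1:  # push outside the 1 x 1 x 1.5 m crop box
            direction = p[:2] / np.linalg.norm(p[:2])
            p = np.array([direction[0], direction[1], 0.0]) * (0.7 + 0.4 * rng.random()) \
                + np.array([0.0, 0.0, p[2]])
        means.append(p)
        if bg_kinds[i] == 2:
            scales.append([lateral, lateral, PLANT_AXIAL_SCALE])  # only kNN catches these
        else:
            s = spec.background_volume_scale * lateral
            scales.append([s, s, s * 0.6])
        quats.append([1.0, 0.0, 0.0, 0.0])
        colors.append([0.55, 0.5, 0.45])

    sh = np.zeros((len(means), 3, 16))
    sh[:, :, 0] = np.array([_dc_from_rgb(c) for c in colors])
    scene = GaussianScene(
        means=np.array(means), scales=np.array(scales),
        rotations=np.array(quats),
        opacities=np.concatenate([np.full(n_plant, 0.92),
                                  rng.uniform(0.4, 0.9, len(means) - n_plant)]),
        sh_coeffs=sh,
    )
    labels = np.array(["plant"] * n_plant
                      + ["background"] * (len(means) - n_plant))

    gt = _ground_truth_cloud(scene, n_plant, rng)
    logger.info("fixture: %d plant + %d background Gaussians, %d GT points",
                n_plant, len(means) - n_plant, len(gt))
    return scene, gt, labels


def _scatter_background(rng, count, plant_extent, stem_height):
    """Clutter positions in an annulus outside the plant, pairwise spaced."""
    placed = []
    r_lo = plant_extent + 0.11  # > 10 cm from any plant Gaussian
    r_hi = 0.48                 # still inside the crop box laterally
    tries = 0
    while len(placed) < count and tries < 20000:
        tries += 1
        r = rng.uniform(r_lo, r_hi)
        az = rng.uniform(0, 2 * np.pi)
        z = rng.uniform(-0.05, stem_height + 0.2)
        p = np.array([r * np.cos(az), r * np.sin(az), z])
        if all(np.linalg.norm(p - q) >= BACKGROUND_MIN_SPACING for q in placed):
            placed.append(p)
    if len(placed) < count:
        raise RuntimeError("could not place background clutter with the "
                           "required spacing; lower background_count")
    return placed


def _ground_truth_cloud(scene: GaussianScene, n_plant: int, rng,
                        points_per_gaussian: int = 60) -> PointCloud:
    """Dense points on the 1-SD ellipsoid shells of the plant Gaussians."""
    from .scene import quaternion_to_matrix

    R = quaternion_to_matrix(scene.rotations[:n_plant])
    pts = []
    for i in range(n_plant):
        u = rng.standard_normal((points_per_gaussian, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        pts.append(scene.means[i] + (u * scene.scales[i]) @ R[i].T)
    return PointCloud(positions=np.concatenate(pts, axis=0))


def render_fixture_dataset(scene: GaussianScene, plan: ViewPlan, outdir,
                           mask_erode_iter: int = 0, mask_dilate_iter: int = 1):
    """Render every planned view to PNG, derive masks, write transforms.json.

    Synthetic renders carry no sensor noise, so masking defaults to no
    erosion (which would delete one-pixel-thin stems) and a single
    dilation to bridge sub-pixel sampling gaps. Returns (list of image
    arrays, list of mask arrays, transforms path). A view whose render
    contains no foreground raises EmptyResultError naming the view.
    """
    import imageio.v3 as iio

    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    result = render_with_contributions(scene, plan.views)
    images, masks = [], []
    for i, img in enumerate(result.images):
        rgb8 = np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)
        try:
            mask = make_mask(rgb8, erode_iter=mask_erode_iter,
                             dilate_iter=mask_dilate_iter)
        except EmptyResultError as exc:
            raise EmptyResultError(f"view {i}: {exc}") from exc
        iio.imwrite(outdir / "images" / f"frame_{i:05d}.png", rgb8)
        iio.imwrite(outdir / "masks" / f"frame_{i:05d}.png",
                    (mask * 255).astype(np.uint8))
        images.append(rgb8)
        masks.append(mask)
    tpath = write_transforms_json(plan, outdir / "transforms.json")
    return images, masks, tpath
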