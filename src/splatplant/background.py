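"""Post-training background removal for trained splat scenes.

Turntable capture leaves the (static) background baked into the trained
scene as Gaussians that are either very large, far from the plant, or
both. The cleaner removes them in three passes, in the order in which
each pass helps the next: (1) a size cull — large Gaussians are in
practice always background; (2) a metric axis-aligned crop around the
plant; (3) a k-nearest-neighbour sparsity test — plant Gaussians are
closely compact, so any Gaussian whose average distance to its 15
nearest neighbours exceeds 3.5 cm is deemed outside the plant group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .scene import AABB, GaussianScene, default_crop_box, volumes

logger = logging.getLogger(__name__)


@dataclass
class BgCleanConfig:
    """Background-removal parameters.

    ``volume_threshold`` is in millimetres under ``volume_mode="axis"``
    (cut on the longest 1-SD axis diameter, 2*max(s)) and in cubic
    millimetres under ``volume_mode="volume"`` (cut on the 1-SD
    ellipsoid volume). The axis reading is the default because a cubic-
    millimetre cut at 2.5 would also delete legitimate foreground
    Gaussians.
    """

    volume_threshold: float = 2.5
    volume_mode: str = "axis"          # "axis" | "volume"
    crop_box: AABB = field(default_factory=default_crop_box)
    knn_k: int = 15
    knn_max_avg_dist: float = 0.035    # metres

    def __post_init__(self):
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.volume_threshold <= 0 or self.knn_max_avg_dist <= 0:
            raise ValueError("thresholds must be positive")
        if self.volume_mode not in ("axis", "volume"):
            raise ValueError(f"unknown volume_mode {self.volume_mode!r}")


def cull_large_gaussians(scene: GaussianScene, config: BgCleanConfig) -> GaussianScene:
    """Remove Gaussians whose size statistic exceeds the threshold."""
    if config.volume_mode == "axis":
        stat = 2.0 * scene.scales.max(axis=1) * 1000.0      # diameter, mm
    else:
        stat = volumes(scene) * 1e9                          # mm^3
    keep = stat <= config.volume_threshold
    logger.info("size cull (%s mode): removed %d of %d",
                config.volume_mode, int((~keep).sum()), scene.count)
    return scene.subset(np.flatnonzero(keep))


def crop_scene(scene: GaussianScene, box: AABB) -> GaussianScene:
    """Keep Gaussians whose mean lies inside the closed box."""
    keep = box.contains(scene.means)
    logger.info("crop: removed %d of %d", int((~keep).sum()), scene.count)
    return scene.subset(np.flatnonzero(keep))


def knn_average_distances(points: np.ndarray, k: int) -> np.ndarray:
    """Per-point mean Euclidean distance to its k nearest *other* points."""
    tree = cKDTree(points)
    dist, _ = tree.query(points, k=k + 1, workers=-1)  # first hit is self
    return dist[:, 1:].mean(axis=1)


def knn_outlier_removal(scene: GaussianScene, config: BgCleanConfig) -> GaussianScene:
    """Single-pass removal of Gaussians whose k-NN average distance is large."""
    if scene.count <= config.knn_k:
        raise ValueError(
            f"scene has {scene.count} Gaussians but knn_k={config.knn_k}; "
            "use a smaller k")
    avg = knn_average_distances(scene.means, config.knn_k)
    keep = avg <= config.knn_max_avg_dist
    logger.info("kNN outlier removal: removed %d of %d",
                int((~keep).sum()), scene.count)
    return scene.subset(np.flatnonzero(keep))


def remove_background(scene: GaussianScene, config: BgCleanConfig) -> GaussianScene:
    """Full pipeline: size cull -> crop -> kNN outlier removal."""
    scene = cull_large_gaussians(scene, config)
    scene = crop_scene(scene, config.crop_box)
    return knn_outlier_removal(scene, config)
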