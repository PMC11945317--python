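"""Dense point-cloud extraction from Gaussian scenes.

The total point budget is fixed up front and distributed across
Gaussians in proportion to their 1-SD ellipsoid volume, so larger
Gaussians generate more points. Each Gaussian is then sampled from its
multivariate normal, with draws beyond a Mahalanobis radius (default
2.5 SD) rejected and regenerated, which keeps every sampled point inside
the ellipsoidal core of its Gaussian. Before sampling, Gaussians are
pre-filtered: means outside the metric crop box, opacities below 1%,
and the largest 2.5% of Gaussians by volume are discarded (the latter
are in practice background structure).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyResultError
from .pointcloud import PointCloud
from .scene import AABB, GaussianScene, default_crop_box, quaternion_to_matrix, volumes

logger = logging.getLogger(__name__)


@dataclass
class SamplerConfig:
    """Extraction parameters; defaults are the production-scale settings."""

    total_points: int = 10_000_000
    mahalanobis_max: float = 2.5       # SD units
    min_opacity: float = 0.01          # strict "less than" cull
    top_volume_frac: float = 0.025     # fraction of largest Gaussians removed
    crop_box: AABB = field(default_factory=default_crop_box)
    seed: int = 0
    max_regen_rounds: int = 100
    size_mode: str = "volume"          # "volume" | "volume_x_opacity"

    def __post_init__(self):
        if self.total_points < 1:
            raise ValueError("total_points must be >= 1")
        if not (0 <= self.min_opacity <= 1 and 0 <= self.top_volume_frac <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.mahalanobis_max <= 0:
            raise ValueError("mahalanobis_max must be > 0")
        if self.size_mode not in ("volume", "volume_x_opacity"):
            raise ValueError(f"unknown size_mode {self.size_mode!r}")


def prefilter_gaussians(scene: GaussianScene, config: SamplerConfig):
    """Crop, opacity-cull and top-volume-cull a scene.

    Returns the filtered scene plus the surviving original indices.
    The top-volume fraction is taken over the population that survives
    the crop and opacity culls.
    """
    keep = config.crop_box.contains(scene.means)
    n_crop = int((~keep).sum())
    keep &= scene.opacities >= config.min_opacity
    n_opacity = int((~keep).sum()) - n_crop
    idx = np.flatnonzero(keep)
    if len(idx) and config.top_volume_frac > 0:
        vols = volumes(scene)[idx]
        n_top = int(np.floor(config.top_volume_frac * len(idx)))
        if n_top > 0:
            # remove the n_top largest volumes; ties resolved toward later indices
            order = np.argsort(vols, kind="stable")
            idx = np.sort(idx[order[:-n_top]])
    logger.info("prefilter: %d cropped, %d opacity-culled, kept %d of %d",
                n_crop, n_opacity, len(idx), scene.count)
    if len(idx) == 0:
        raise EmptyResultError("empty after prefilter: no Gaussians survive "
                               "crop/opacity/volume culls")
    return scene.subset(idx), idx


def allocate_point_counts(scene: GaussianScene, total_points: int,
                          size_mode: str = "volume") -> np.ndarray:
    """Integer point counts proportional to Gaussian size, summing exactly
    to ``total_points`` via largest-remainder (Hamilton) rounding.

    Ties in the fractional remainders are broken toward the lowest index,
    which makes the allocation deterministic and order-equivariant.
    """
    if scene.count == 0:
        raise ValueError("cannot allocate points for an empty scene")
    if total_points < 1:
        raise ValueError("total_points must be >= 1")
    size = volumes(scene)
    if size_mode == "volume_x_opacity":
        size = size * scene.opacities
    total_size = size.sum()
    if total_size <= 0:
        logger.warning("zero total volume; falling back to uniform allocation")
        size = np.ones(scene.count)
        total_size = float(scene.count)
    quota = size / total_size * total_points
    counts = np.floor(quota).astype(np.int64)
    short = total_points - int(counts.sum())
    if short > 0:
        remainder = quota - counts
        # stable sort of -remainder: equal remainders keep index order
        winners = np.argsort(-remainder, kind="stable")[:short]
        counts[winners] += 1
    return counts


def _sample_truncated_std(n: int, rmax: float, rng: np.random.Generator,
                          max_rounds: int):
    """Draw n standard-normal 3-vectors conditioned on |z| <= rmax.

    Rejected draws are regenerated for up to ``max_rounds`` rounds; any
    offenders left after that are radially rescaled onto the boundary
    shell. Returns (points, n_drawn, n_accepted) where the counts cover
    every unconditioned draw made.
    """
    out = np.empty((n, 3))
    filled = 0
    n_drawn = 0
    n_accepted = 0
    need = n
    for _ in range(max_rounds):
        if need == 0:
            break
        z = rng.standard_normal((need, 3))
        n_drawn += need
        ok = np.einsum("ij,ij->i", z, z) <= rmax * rmax
        k = int(ok.sum())
        n_accepted += k
        out[filled:filled + k] = z[ok]
        filled += k
        need -= k
    if need:
        # fallback: project leftover draws onto the truncation shell
        z = rng.standard_normal((need, 3))
        n_drawn += need
        r = np.linalg.norm(z, axis=1, keepdims=True)
        r = np.where(r == 0, 1.0, r)
        scale = np.minimum(1.0, rmax / r)
        out[filled:] = z * scale
        logger.warning("regeneration exhausted after %d rounds; projected %d "
                       "points onto the %.3g-SD shell", max_rounds, need, rmax)
    return out, n_drawn, n_accepted


def _gaussian_rng(seed: int, original_index: int) -> np.random.Generator:
    """Per-Gaussian stream keyed by (seed, original index): reproducible and
    invariant to scene ordering."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(original_index)]))


def sample_gaussian(scene: GaussianScene, index: int, n: int,
                    config: SamplerConfig, rng=None, return_stats: bool = False):
    """Sample ``n`` points from Gaussian ``index`` under Mahalanobis truncation.

    Points are i.i.d. MVN(mu, Sigma) conditioned on Mahalanobis distance
    <= ``config.mahalanobis_max``; deterministic given the RNG stream.
    With ``return_stats=True`` also returns a dict with the number of
    unconditioned draws made and how many were accepted.
    """
    if rng is None:
        rng = _gaussian_rng(config.seed, index)
    z, n_drawn, n_accepted = _sample_truncated_std(
        int(n), config.mahalanobis_max, rng, config.max_regen_rounds)
    R = quaternion_to_matrix(scene.rotations[index])
    pts = scene.means[index] + (z * scene.scales[index]) @ R.T
    if return_stats:
        return pts, {"n_drawn": n_drawn, "n_accepted": n_accepted}
    return pts


def build_point_cloud(scene: GaussianScene, config: SamplerConfig) -> PointCloud:
    """prefilter -> allocate -> sample; the full extraction pipeline.

    The output has exactly ``config.total_points`` positions, each tagged
    with the original index of its generating Gaussian. Colours are left
    unset — they are filled in by the contribution renderer.
    """
    scene.validate()
    filtered, kept = prefilter_gaussians(scene, config)
    counts = allocate_point_counts(filtered, config.total_points, config.size_mode)
    positions = np.empty((config.total_points, 3))
    source = np.empty(config.total_points, dtype=np.int64)
    offset = 0
    for i in range(filtered.count):
        n_i = int(counts[i])
        if n_i == 0:
            continue
        rng = _gaussian_rng(config.seed, kept[i])
        positions[offset:offset + n_i] = sample_gaussian(filtered, i, n_i, config, rng)
        source[offset:offset + n_i] = kept[i]
        offset += n_i
    assert offset == config.total_points
    return PointCloud(positions=positions, source_index=source)
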