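"""Point-cloud cleaning, rigid registration and accuracy metrics.

Cleaning follows the three-stage recipe used for reconstructed plant
clouds: statistical outlier removal (points far from their local
neighbourhood), a surface-residual filter (points far from the locally
fitted surface), and rejection of small connected components. Accuracy
against a scanned ground truth is measured as the directional mean
nearest-neighbour distance with its SD, after rigid ICP alignment;
camera-pose agreement is measured as the absolute trajectory error with
a 1.5-mm convergence criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .pointcloud import PointCloud

logger = logging.getLogger(__name__)


@dataclass
class CleanConfig:
    sor_k: int = 20
    sor_nsigma: float = 1.0
    surf_radius: float = 0.005       # metres
    surf_nsigma: float = 1.0
    surf_max_neighbors: int = 30     # cap for vectorised plane fits
    cluster_radius: float = 0.005    # metres
    min_cluster_points: int = 2000

    def __post_init__(self):
        for name in ("sor_k", "sor_nsigma", "surf_radius", "surf_nsigma",
                     "surf_max_neighbors", "cluster_radius", "min_cluster_points"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class DistanceReport:
    """Directional nearest-neighbour distance summary, metres."""

    mean_distance: float
    sd: float
    direction: str = "A->B"

    def as_dict(self):
        return {"mean_mm": self.mean_distance * 1000.0, "sd_mm": self.sd * 1000.0,
                "direction": self.direction}


def statistical_outlier_removal(cloud: PointCloud, config: CleanConfig) -> PointCloud:
    """Remove points whose mean k-NN distance exceeds the global
    mean + nsigma * SD of that statistic (single pass, strict >)."""
    n = len(cloud)
    if n <= config.sor_k:
        raise ValueError(f"cloud has {n} points but sor_k={config.sor_k}")
    tree = cKDTree(cloud.positions)
    dist, _ = tree.query(cloud.positions, k=config.sor_k + 1, workers=-1)
    stat = dist[:, 1:].mean(axis=1)
    cutoff = stat.mean() + config.sor_nsigma * stat.std()
    keep = stat <= cutoff
    logger.info("SOR: removed %d of %d", int((~keep).sum()), n)
    return cloud.subset(keep)


def surface_noise_filter(cloud: PointCloud, config: CleanConfig) -> PointCloud:
    """Remove points far from the locally fitted surface.

    For each point a least-squares plane is fitted to its neighbours
    within ``surf_radius`` (capped at ``surf_max_neighbors`` nearest);
    the residual is the point-to-plane distance and points with residual
    > mean + nsigma * SD are removed. Points with fewer than 3
    neighbours cannot support a plane fit and are kept (logged).
    """
    n = len(cloud)
    if n < 10:
        raise ValueError("surface filter needs at least 10 points")
    pos = cloud.positions
    tree = cKDTree(pos)
    k = min(config.surf_max_neighbors + 1, n)
    dist, idx = tree.query(pos, k=k, workers=-1)
    in_radius = dist <= config.surf_radius
    counts = in_radius.sum(axis=1) - 1  # exclude self
    fittable = counts >= 3

    # masked neighbourhood covariance, batched over all fittable points
    w = in_radius.astype(float)
    nb = pos[idx]                                     # (n, k, 3)
    m = w.sum(axis=1, keepdims=True)
    centroid = (nb * w[:, :, None]).sum(axis=1) / m
    d = (nb - centroid[:, None, :]) * w[:, :, None]
    cov = np.einsum("nki,nkj->nij", d, d)
    # smallest-eigenvector normal per neighbourhood
    _, vecs = np.linalg.eigh(cov + 1e-30 * np.eye(3))
    normal = vecs[:, :, 0]
    residual = np.abs(np.einsum("ni,ni->n", pos - centroid, normal))

    r = residual[fittable]
    cutoff = r.mean() + config.surf_nsigma * r.std()
    keep = ~fittable | (residual <= cutoff)
    n_sparse = int((~fittable).sum())
    if n_sparse:
        logger.info("surface filter: %d points kept with <3 neighbours", n_sparse)
    logger.info("surface filter: removed %d of %d", int((~keep).sum()), n)
    return cloud.subset(keep)


def cluster_filter(cloud: PointCloud, config: CleanConfig) -> PointCloud:
    """Keep only connected components of the radius graph with at least
    ``min_cluster_points`` points (strict 'fewer than' rejection)."""
    n = len(cloud)
    if n == 0:
        return cloud
    tree = cKDTree(cloud.positions)
    pairs = tree.query_pairs(config.cluster_radius, output_type="ndarray")
    adj = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    keep = sizes[labels] >= config.min_cluster_points
    logger.info("cluster filter: kept %d of %d components (%d of %d points)",
                int((sizes >= config.min_cluster_points).sum()), n_comp,
                int(keep.sum()), n)
    return cloud.subset(keep)


def clean_cloud(cloud: PointCloud, config: CleanConfig | None = None) -> PointCloud:
    """Default cleaning pipeline: SOR -> surface filter -> cluster filter."""
    config = config or CleanConfig()
    cloud = statistical_outlier_removal(cloud, config)
    cloud = surface_noise_filter(cloud, config)
    return cluster_filter(cloud, config)


def kabsch(moving: np.ndarray, fixed: np.ndarray, allow_scale: bool = False):
    """Least-squares rigid (optionally similarity) transform mapping
    ``moving`` onto ``fixed``; returns a 4x4 matrix with det(R) = +1."""
    mu_m = moving.mean(axis=0)
    mu_f = fixed.mean(axis=0)
    H = (moving - mu_m).T @ (fixed - mu_f)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    s = 1.0
    if allow_scale:
        var = ((moving - mu_m) ** 2).sum()
        if var > 0:
            s = (S * np.diag(D)).sum() / var
    T = np.eye(4)
    T[:3, :3] = s * R
    T[:3, 3] = mu_f - s * R @ mu_m
    return T


def apply_transform(points: np.ndarray, T: np.ndarray) -> np.ndarray:
    return points @ T[:3, :3].T + T[:3, 3]


def icp_align(moving: PointCloud, fixed: PointCloud, max_iter: int = 50,
              tol: float = 1e-10, center_init: bool = False,
              return_history: bool = False):
    """Point-to-point rigid ICP; returns (4x4 transform, transformed cloud).

    Correspondences are nearest neighbours in ``fixed``; each iteration
    applies a Kabsch update and stops when the RMS change drops below
    ``tol`` or after ``max_iter`` iterations. No scale is estimated —
    both clouds are assumed metric. With ``return_history=True`` the
    per-iteration correspondence RMS list is appended to the result.
    """
    if len(moving) < 3 or len(fixed) < 3:
        raise ValueError("ICP needs at least 3 points in each cloud")
    src = moving.positions.copy()
    if np.linalg.matrix_rank(src - src.mean(axis=0)) < 2:
        raise ValueError("degenerate (collinear) geometry")
    T_total = np.eye(4)
    if center_init:
        T_total[:3, 3] = fixed.positions.mean(axis=0) - src.mean(axis=0)
        src = apply_transform(moving.positions, T_total)
    tree = cKDTree(fixed.positions)
    prev_rms = np.inf
    history = []
    for _ in range(max_iter):
        dist, idx = tree.query(src, workers=-1)
        T_step = kabsch(src, fixed.positions[idx])
        src = apply_transform(src, T_step)
        T_total = T_step @ T_total
        rms = float(np.sqrt((dist**2).mean()))
        history.append(rms)
        if abs(prev_rms - rms) < tol:
            break
        prev_rms = rms
    aligned = PointCloud(positions=src, colors=moving.colors,
                         source_index=moving.source_index)
    if return_history:
        return T_total, aligned, history
    return T_total, aligned


def mean_nn_distance(A: PointCloud, B: PointCloud,
                     direction: str = "A->B") -> DistanceReport:
    """Mean and SD of the distance from each point of A to its nearest
    neighbour in B (directional)."""
    if len(A) == 0 or len(B) == 0:
        raise ValueError("both clouds must be non-empty")
    tree = cKDTree(B.positions)
    dist, _ = tree.query(A.positions, workers=-1)
    return DistanceReport(mean_distance=float(dist.mean()), sd=float(dist.std()),
                          direction=direction)


def absolute_trajectory_error(posesA, posesB, align: bool = True,
                              allow_scale: bool = False,
                              threshold: float = 0.0015):
    """ATE between two index-matched camera-pose sets.

    Optionally rigidly aligns B's camera centres onto A's (Kabsch;
    similarity alignment behind ``allow_scale`` for SfM scale
    ambiguity), then returns (mean Euclidean centre distance in metres,
    converged flag against ``threshold``).
    """
    if len(posesA) != len(posesB):
        raise ValueError(f"pose counts differ: {len(posesA)} vs {len(posesB)}")
    cA = np.array([p.center if hasattr(p, "center") else np.asarray(p)
                   for p in posesA], dtype=float)
    cB = np.array([p.center if hasattr(p, "center") else np.asarray(p)
                   for p in posesB], dtype=float)
    if align:
        T = kabsch(cB, cA, allow_scale=allow_scale)
        cB = apply_transform(cB, T)
    ate = float(np.linalg.norm(cA - cB, axis=1).mean())
    return ate, ate <= threshold
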