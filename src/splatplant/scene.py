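"""Gaussian-splat scenes: domain types, splat-PLY I/O, per-Gaussian geometry
and spherical-harmonic colour evaluation.

A 3DGS scene is a set of anisotropic 3D Gaussians, each with a centre
``mu`` (metres), 1-SD axis lengths ``s`` (metres), a unit quaternion
rotation, an opacity in [0, 1] and 16 real spherical-harmonic
coefficients per colour channel (degree 3: one DC term plus 15
higher-order terms). On disk the de-facto splat dialect stores scales as
natural logs and opacity as a logit, both of which are undone on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from ._ply import read_vertex_element, write_vertex_element
from .errors import FormatError

logger = logging.getLogger(__name__)

#: Real spherical-harmonic constants up to degree 3 (field-standard values).
SH_C0 = 0.28209479177387814
SH_C1 = 0.4886025119029199
SH_C2 = (1.0925484305920792, -1.0925484305920792, 0.31539156525252005,
         -1.0925484305920792, 0.5462742152960396)
SH_C3 = (-0.5900435899266435, 2.890611442640554, -0.4570457994644658,
         0.3731763325901154, -0.4570457994644658, 1.445305721320277,
         -0.5900435899266435)

#: Splat-PLY vertex property names, in declaration order (62 properties).
SPLAT_PROPERTIES = (
    ["x", "y", "z", "nx", "ny", "nz"]
    + [f"f_dc_{i}" for i in range(3)]
    + [f"f_rest_{i}" for i in range(45)]
    + ["opacity"]
    + [f"scale_{i}" for i in range(3)]
    + [f"rot_{i}" for i in range(4)]
)


@dataclass
class AABB:
    """Axis-aligned box given by its centre and full edge lengths, metres."""

    center: np.ndarray
    size: np.ndarray

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.size = np.asarray(self.size, dtype=float)
        if not np.all(self.size > 0):
            raise ValueError("AABB size must be strictly positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the closed box."""
        half = self.size / 2.0
        d = np.abs(np.atleast_2d(points) - self.center)
        return np.all(d <= half, axis=1)


#: Default foreground crop: 1 x 1 x 1.5 m centred at the turntable origin.
def default_crop_box() -> AABB:
    return AABB(center=np.zeros(3), size=np.array([1.0, 1.0, 1.5]))


@dataclass
class GaussianScene:
    """A set of 3D Gaussians with opacity and view-dependent SH colour.

    Attributes
    ----------
    means : (n, 3) float array, metres
    scales : (n, 3) float array, 1-SD axis lengths, metres (strictly positive)
    rotations : (n, 4) float array, unit quaternions in (w, x, y, z) order
    opacities : (n,) float array in [0, 1]
    sh_coeffs : (n, 3, 16) float array, per-channel SH coefficients, degree 3
    """

    means: np.ndarray
    scales: np.ndarray
    rotations: np.ndarray
    opacities: np.ndarray
    sh_coeffs: np.ndarray

    def __post_init__(self):
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float)).reshape(-1, 3)
        n = len(self.means)
        self.scales = np.asarray(self.scales, dtype=float).reshape(n, 3)
        self.rotations = np.asarray(self.rotations, dtype=float).reshape(n, 4)
        self.opacities = np.asarray(self.opacities, dtype=float).reshape(n)
        self.sh_coeffs = np.asarray(self.sh_coeffs, dtype=float).reshape(n, 3, 16)
        norms = np.linalg.norm(self.rotations, axis=1)
        if n and np.any(norms == 0):
            raise ValueError("zero-norm quaternion")
        if n:
            self.rotations = self.rotations / norms[:, None]

    @property
    def count(self) -> int:
        return len(self.means)

    def validate(self) -> None:
        if self.count and not np.all(self.scales > 0):
            raise ValueError("all scales must be > 0")
        if self.count and not (np.all(self.opacities >= 0) and np.all(self.opacities <= 1)):
            raise ValueError("opacities must lie in [0, 1]")
        if not np.all(np.isfinite(self.sh_coeffs)):
            raise ValueError("sh_coeffs must be finite")

    def subset(self, indices) -> "GaussianScene":
        indices = np.asarray(indices)
        return GaussianScene(
            means=self.means[indices],
            scales=self.scales[indices],
            rotations=self.rotations[indices],
            opacities=self.opacities[indices],
            sh_coeffs=self.sh_coeffs[indices],
        )


def empty_scene() -> GaussianScene:
    return GaussianScene(
        means=np.zeros((0, 3)), scales=np.ones((0, 3)),
        rotations=np.tile([1.0, 0, 0, 0], (0, 1)).reshape(0, 4),
        opacities=np.zeros(0), sh_coeffs=np.zeros((0, 3, 16)),
    )


def _rest_order(layout: str) -> np.ndarray:
    """Map (channel, coeff 1..15) -> f_rest index for the given dialect."""
    if layout == "channel-major":
        # f_rest_0..14 = R coeffs, 15..29 = G, 30..44 = B
        return np.arange(45).reshape(3, 15)
    if layout == "coefficient-major":
        # f_rest grouped per coefficient: (c1 RGB, c2 RGB, ...)
        return (np.arange(15)[None, :] * 3 + np.arange(3)[:, None])
    raise ValueError(f"unknown SH layout {layout!r}")


def read_splat_ply(path, sh_layout: str = "channel-major") -> GaussianScene:
    """Read a scene from the standard 3DGS binary PLY splat layout.

    Stored log-scales are exponentiated, stored logit opacities pass
    through a logistic, and quaternions are normalised. Records with any
    non-finite value are dropped with a logged count.
    """
    records = read_vertex_element(path)
    names = set(records.dtype.names)
    for prop in SPLAT_PROPERTIES:
        if prop.startswith("n"):
            continue  # normals optional, ignored on read
        if prop not in names:
            raise FormatError(f"{path}: missing splat property {prop!r}")

    def cols(prefix, k):
        return np.stack([records[f"{prefix}_{i}"].astype(float) for i in range(k)], axis=1)

    means = np.stack([records[c].astype(float) for c in "xyz"], axis=1)
    log_scales = cols("scale", 3)
    logit_op = records["opacity"].astype(float)
    rot = cols("rot", 4)
    f_dc = cols("f_dc", 3)
    f_rest = cols("f_rest", 45)

    finite = (np.isfinite(means).all(axis=1) & np.isfinite(log_scales).all(axis=1)
              & np.isfinite(logit_op) & np.isfinite(rot).all(axis=1)
              & np.isfinite(f_dc).all(axis=1) & np.isfinite(f_rest).all(axis=1))
    n_bad = int((~finite).sum())
    if n_bad:
        logger.warning("%s: dropped %d records with non-finite values", path, n_bad)
        means, log_scales, logit_op, rot, f_dc, f_rest = (
            a[finite] for a in (means, log_scales, logit_op, rot, f_dc, f_rest))

    order = _rest_order(sh_layout)
    sh = np.zeros((len(means), 3, 16))
    sh[:, :, 0] = f_dc
    for ch in range(3):
        sh[:, ch, 1:] = f_rest[:, order[ch]]

    from scipy.special import expit

    return GaussianScene(
        means=means, scales=np.exp(log_scales), rotations=rot,
        opacities=expit(logit_op), sh_coeffs=sh,
    )


def write_splat_ply(scene: GaussianScene, path, sh_layout: str = "channel-major"):
    """Write a scene in the standard splat-PLY layout; inverse of read_splat_ply."""
    scene.validate()
    n = scene.count
    dtype = np.dtype([(name, "<f4") for name in SPLAT_PROPERTIES])
    rec = np.zeros(n, dtype=dtype)
    rec["x"], rec["y"], rec["z"] = scene.means.T
    for i in range(3):
        rec[f"scale_{i}"] = np.log(scene.scales[:, i])
        rec[f"f_dc_{i}"] = scene.sh_coeffs[:, i, 0]
    # logit with clipping so opacity 0/1 stays finite in float32
    op = np.clip(scene.opacities, 1e-12, 1 - 1e-12)
    rec["opacity"] = np.log(op / (1 - op))
    for i in range(4):
        rec[f"rot_{i}"] = scene.rotations[:, i]
    order = _rest_order(sh_layout)
    for ch in range(3):
        for j in range(15):
            rec[f"f_rest_{order[ch, j]}"] = scene.sh_coeffs[:, ch, j + 1]
    write_vertex_element(path, rec)
    return path


def quaternion_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrices from unit quaternions in (w, x, y, z) order.

    Accepts a single quaternion or an (n, 4) batch.
    """
    q = np.asarray(q, dtype=float)
    single = q.ndim == 1
    q = np.atleast_2d(q)
    q = q / np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    R = np.empty((len(q), 3, 3))
    R[:, 0, 0] = 1 - 2 * (y * y + z * z)
    R[:, 0, 1] = 2 * (x * y - w * z)
    R[:, 0, 2] = 2 * (x * z + w * y)
    R[:, 1, 0] = 2 * (x * y + w * z)
    R[:, 1, 1] = 1 - 2 * (x * x + z * z)
    R[:, 1, 2] = 2 * (y * z - w * x)
    R[:, 2, 0] = 2 * (x * z - w * y)
    R[:, 2, 1] = 2 * (y * z + w * x)
    R[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return R[0] if single else R


def covariance_of(scene: GaussianScene, index: int) -> np.ndarray:
    """3x3 covariance Sigma = R diag(s^2) R^T of one Gaussian."""
    R = quaternion_to_matrix(scene.rotations[index])
    return R @ np.diag(scene.scales[index] ** 2) @ R.T


def covariances(scene: GaussianScene) -> np.ndarray:
    """(n, 3, 3) stack of per-Gaussian covariances."""
    R = quaternion_to_matrix(scene.rotations)
    S2 = scene.scales**2
    return np.einsum("nij,nj,nkj->nik", R, S2, R)


def volume_of(scene: GaussianScene, index: int) -> float:
    """1-SD ellipsoid volume (4/3) pi s1 s2 s3, cubic metres."""
    return float(4.0 / 3.0 * np.pi * np.prod(scene.scales[index]))


def volumes(scene: GaussianScene) -> np.ndarray:
    return 4.0 / 3.0 * np.pi * np.prod(scene.scales, axis=1)


def eval_sh_basis(view_dir: np.ndarray) -> np.ndarray:
    """Real SH basis values Y_lm(d) to degree 3, as a length-16 vector.

    ``view_dir`` must be a unit vector; batches (n, 3) give (n, 16).
    """
    d = np.asarray(view_dir, dtype=float)
    single = d.ndim == 1
    d = np.atleast_2d(d)
    x, y, z = d.T
    xx, yy, zz = x * x, y * y, z * z
    xy, yz, xz = x * y, y * z, x * z
    B = np.empty((len(d), 16))
    B[:, 0] = SH_C0
    B[:, 1] = -SH_C1 * y
    B[:, 2] = SH_C1 * z
    B[:, 3] = -SH_C1 * x
    B[:, 4] = SH_C2[0] * xy
    B[:, 5] = SH_C2[1] * yz
    B[:, 6] = SH_C2[2] * (2 * zz - xx - yy)
    B[:, 7] = SH_C2[3] * xz
    B[:, 8] = SH_C2[4] * (xx - yy)
    B[:, 9] = SH_C3[0] * y * (3 * xx - yy)
    B[:, 10] = SH_C3[1] * xy * z
    B[:, 11] = SH_C3[2] * y * (4 * zz - xx - yy)
    B[:, 12] = SH_C3[3] * z * (2 * zz - 3 * xx - 3 * yy)
    B[:, 13] = SH_C3[4] * x * (4 * zz - xx - yy)
    B[:, 14] = SH_C3[5] * z * (xx - yy)
    B[:, 15] = SH_C3[6] * x * (xx - 3 * yy)
    return B[0] if single else B


def eval_sh_color(scene: GaussianScene, index: int, view_dir: np.ndarray,
                  degree: int = 3) -> np.ndarray:
    """View-dependent RGB of one Gaussian, clamped to [0, 1].

    Per channel: colour = clamp(0.5 + sum_lm c_lm Y_lm(d), 0, 1), the
    reference 3DGS convention (the 0.5 shift centres the DC term).
    """
    basis = eval_sh_basis(view_dir)
    k = (degree + 1) ** 2
    rgb = 0.5 + scene.sh_coeffs[index, :, :k] @ basis[:k]
    return np.clip(rgb, 0.0, 1.0)


def eval_sh_colors(scene: GaussianScene, view_dirs: np.ndarray,
                   degree: int = 3) -> np.ndarray:
    """Batched eval_sh_color: per-Gaussian view_dirs (n, 3) -> colours (n, 3)."""
    basis = eval_sh_basis(view_dirs)  # (n, 16)
    k = (degree + 1) ** 2
    rgb = 0.5 + np.einsum("nck,nk->nc", scene.sh_coeffs[:, :, :k], basis[:, :k])
    return np.clip(rgb, 0.0, 1.0)
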