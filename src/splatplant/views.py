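"""Turntable view-pose planning and transforms.json I/O.

Poses are generated on a sphere cap around the plant at a radius of
roughly 1.5x the plant height (the empirically best capture distance),
with every optical axis through the plant centre. Because a fixed-plane
camera plus a turntable realises arbitrary azimuths, each view point
decomposes into a turntable rotation — the angle between the fixed
x-axis and the view point — and a residual camera position in the x-z
plane. The world frame is metric and z-up with the origin at the
turntable centre. Every eighth view is held out for evaluation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError
from .render import CameraView

logger = logging.getLogger(__name__)

#: Empirical capture-radius multiple of the plant height.
RADIUS_HEIGHT_FACTOR = 1.5
GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass
class ViewPlan:
    views: list
    turntable_angles: np.ndarray   # degrees in [0, 360)
    radius: float                  # metres
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    split_labels: list = field(default_factory=list)

    def __post_init__(self):
        self.turntable_angles = np.asarray(self.turntable_angles, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        if not self.split_labels:
            self.split_labels = ["train"] * len(self.views)

    def __len__(self):
        return len(self.views)


def suggest_radius(plant_height: float) -> float:
    """Capture radius for a plant of the given height: 1.5x the height."""
    if plant_height <= 0:
        raise ValueError("plant height must be positive")
    return RADIUS_HEIGHT_FACTOR * plant_height


def look_at(camera_pos, target, world_up=(0.0, 0.0, 1.0)) -> np.ndarray:
    """OpenGL-convention camera-to-world matrix looking from ``camera_pos``
    at ``target``, keeping world-up upward in the image.

    Columns are (right, up, backward); the camera looks along -z.
    """
    camera_pos = np.asarray(camera_pos, dtype=float)
    forward = np.asarray(target, dtype=float) - camera_pos
    nf = np.linalg.norm(forward)
    if nf == 0:
        raise ValueError("camera position coincides with target")
    forward /= nf
    up = np.asarray(world_up, dtype=float)
    right = np.cross(forward, up)
    if np.linalg.norm(right) < 1e-12:   # looking straight up/down
        right = np.cross(forward, np.array([0.0, 1.0, 0.0]))
    right /= np.linalg.norm(right)
    cam_up = np.cross(right, forward)
    c2w = np.eye(4)
    c2w[:3, 0] = right
    c2w[:3, 1] = cam_up
    c2w[:3, 2] = -forward
    c2w[:3, 3] = camera_pos
    return c2w


def fibonacci_cap_points(n: int, min_elevation: float, max_elevation: float) -> np.ndarray:
    """n approximately equidistant unit vectors in an elevation band.

    Equal-area Fibonacci spiral: sin(elevation) is uniformly spaced over
    [sin(min), sin(max)] and azimuths advance by the golden angle so
    point 0 sits on the +x azimuth.
    """
    s0, s1 = math.sin(math.radians(min_elevation)), math.sin(math.radians(max_elevation))
    i = np.arange(n)
    sin_el = s0 + (s1 - s0) * ((i + 0.5) / n) if n > 1 else np.array([(s0 + s1) / 2.0])
    cos_el = np.sqrt(np.maximum(0.0, 1.0 - sin_el**2))
    az = i * GOLDEN_ANGLE
    return np.stack([cos_el * np.cos(az), cos_el * np.sin(az), sin_el], axis=1)


def generate_sphere_views(n: int, radius: float, center=(0.0, 0.0, 0.0),
                          min_elevation: float = 0.0, max_elevation: float = 75.0,
                          width: int = 64, height: int = 64,
                          fov_deg: float = 45.0,
                          reachable=None) -> ViewPlan:
    """Plan ``n`` views on a sphere cap, optical axes through ``center``.

    ``reachable``, if given, is a predicate on view points (world 3-vectors)
    filtering out poses the capture hardware cannot reach.
    """
    if n < 1 or radius <= 0:
        raise ValueError("need n >= 1 and radius > 0")
    center = np.asarray(center, dtype=float)
    unit = fibonacci_cap_points(n, min_elevation, max_elevation)
    points = center + radius * unit
    if reachable is not None:
        mask = np.array([bool(reachable(p)) for p in points])
        points = points[mask]
        logger.info("reachability filter: kept %d of %d views", len(points), n)
    f = (width / 2.0) / math.tan(math.radians(fov_deg) / 2.0)
    views, angles = [], []
    for p in points:
        rel = p - center
        angle, _ = turntable_decompose(rel)
        angles.append(angle)
        views.append(CameraView(
            width=width, height=height, fx=f, fy=f,
            cx=width / 2.0, cy=height / 2.0,
            c2w=look_at(p, center), convention="opengl"))
    return ViewPlan(views=views, turntable_angles=np.array(angles),
                    radius=float(radius), center=center)


def turntable_decompose(view_point) -> tuple[float, np.ndarray]:
    """Split a view point into (turntable azimuth, fixed-plane camera point).

    The azimuth is the angle between the fixed x-axis and the point,
    mapped to [0, 360); rotating the point by -azimuth about z lands it
    in the x-z plane (y = 0). Apex points (x = y = 0) get azimuth 0.
    """
    p = np.asarray(view_point, dtype=float)
    if p[0] == 0.0 and p[1] == 0.0:
        logger.warning("apex view point %s: turntable angle defined as 0", p)
        return 0.0, p.copy()
    angle = math.degrees(math.atan2(p[1], p[0])) % 360.0
    r = math.hypot(p[0], p[1])
    return angle, np.array([r, 0.0, p[2]])


def rotate_about_z(point, angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return R @ np.asarray(point, dtype=float)


def split_train_eval(plan: ViewPlan, ratio_denominator: int = 8) -> ViewPlan:
    """Label every ``ratio_denominator``-th view (index 0 first) as eval."""
    if ratio_denominator < 2:
        raise ValueError("ratio_denominator must be >= 2")
    plan.split_labels = ["eval" if i % ratio_denominator == 0 else "train"
                         for i in range(len(plan))]
    return plan


def write_transforms_json(plan: ViewPlan, path, frame_prefix: str = "images/frame"):
    """Write the plan in the Instant-NGP/NeRFStudio transforms dialect.

    Intrinsics are taken from the first view (the dialect stores them
    top-level); per-frame extras (turntable angle, split label) ride
    along under non-standard keys that other readers ignore.
    """
    if not len(plan):
        raise ValueError("cannot write an empty plan")
    v0 = plan.views[0]
    doc = {
        "fl_x": v0.fx, "fl_y": v0.fy, "cx": v0.cx, "cy": v0.cy,
        "w": v0.width, "h": v0.height,
        "camera_model": "OPENCV",
        "radius": plan.radius,
        "center": plan.center.tolist(),
        "frames": [],
    }
    for i, view in enumerate(plan.views):
        doc["frames"].append({
            "file_path": f"{frame_prefix}_{i:05d}.png",
            "transform_matrix": view.c2w.tolist(),
            "turntable_angle": float(plan.turntable_angles[i]),
            "split": plan.split_labels[i],
        })
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
    return path


def read_transforms_json(path) -> ViewPlan:
    """Read a transforms.json back into a ViewPlan (inverse of write)."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: malformed JSON: {exc}") from exc
    try:
        fx, fy = doc["fl_x"], doc["fl_y"]
        cx, cy, w, h = doc["cx"], doc["cy"], doc["w"], doc["h"]
    except KeyError as exc:
        raise FormatError(f"{path}: missing top-level intrinsic {exc}") from exc
    center = np.asarray(doc.get("center", [0.0, 0.0, 0.0]), dtype=float)
    views, angles, labels = [], [], []
    for i, frame in enumerate(doc.get("frames", [])):
        try:
            c2w = np.asarray(frame["transform_matrix"], dtype=float).reshape(4, 4)
        except (KeyError, ValueError) as exc:
            raise FormatError(f"{path}: bad frame {i}: {exc}") from exc
        view = CameraView(width=int(w), height=int(h), fx=fx, fy=fy,
                          cx=cx, cy=cy, c2w=c2w, convention="opengl")
        views.append(view)
        if "turntable_angle" in frame:
            angles.append(float(frame["turntable_angle"]))
        else:
            angles.append(turntable_decompose(view.center - center)[0])
        labels.append(frame.get("split", "train"))
    radius = float(doc.get("radius", np.mean(
        [np.linalg.norm(v.center - center) for v in views]) if views else 0.0))
    return ViewPlan(views=views, turntable_angles=np.array(angles),
                    radius=radius, center=center, split_labels=labels)
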