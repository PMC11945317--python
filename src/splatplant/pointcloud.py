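"""Point-cloud container and PLY/XYZ readers and writers."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._ply import read_vertex_element, write_vertex_element
from .errors import FormatError


@dataclass
class PointCloud:
    """Positions in metres, optional 0-255 RGB colours and optional
    per-point source-Gaussian indices (same length as positions)."""

    positions: np.ndarray
    colors: Optional[np.ndarray] = None
    source_index: Optional[np.ndarray] = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if self.colors is not None:
            self.colors = np.asarray(self.colors).reshape(-1, 3)
            if len(self.colors) != len(self.positions):
                raise ValueError("colors length must match positions")
        if self.source_index is not None:
            self.source_index = np.asarray(self.source_index, dtype=np.int64).reshape(-1)
            if len(self.source_index) != len(self.positions):
                raise ValueError("source_index length must match positions")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    def __len__(self) -> int:
        return len(self.positions)

    def subset(self, mask_or_indices) -> "PointCloud":
        idx = np.asarray(mask_or_indices)
        return PointCloud(
            positions=self.positions[idx],
            colors=None if self.colors is None else self.colors[idx],
            source_index=None if self.source_index is None else self.source_index[idx],
        )


def write_cloud_ply(cloud: PointCloud, path):
    """Write float32 xyz (+ uchar RGB when present) as binary PLY."""
    fields = [("x", "<f4"), ("y", "<f4"), ("z", "<f4")]
    if cloud.colors is not None:
        fields += [("red", "u1"), ("green", "u1"), ("blue", "u1")]
    rec = np.zeros(len(cloud), dtype=np.dtype(fields))
    rec["x"], rec["y"], rec["z"] = cloud.positions.T
    if cloud.colors is not None:
        rgb = np.clip(np.rint(cloud.colors), 0, 255).astype(np.uint8)
        rec["red"], rec["green"], rec["blue"] = rgb.T
    write_vertex_element(path, rec)
    return path


def read_cloud_ply(path) -> PointCloud:
    rec = read_vertex_element(path)
    names = set(rec.dtype.names)
    for c in "xyz":
        if c not in names:
            raise FormatError(f"{path}: missing coordinate property {c!r}")
    pos = np.stack([rec[c].astype(float) for c in "xyz"], axis=1)
    colors = None
    if {"red", "green", "blue"} <= names:
        colors = np.stack([rec[c].astype(float) for c in ("red", "green", "blue")], axis=1)
    return PointCloud(positions=pos, colors=colors)


def write_cloud_xyz(cloud: PointCloud, path):
    """Whitespace-separated text: x y z [r g b] per line."""
    if cloud.colors is not None:
        rgb = np.clip(np.rint(cloud.colors), 0, 255).astype(int)
        data = np.column_stack([cloud.positions, rgb])
        fmt = ["%.9g"] * 3 + ["%d"] * 3
    else:
        data, fmt = cloud.positions, ["%.9g"] * 3
    np.savetxt(path, data, fmt=fmt)
    return path


def read_cloud_xyz(path) -> PointCloud:
    data = np.atleast_2d(np.loadtxt(path))
    if data.size == 0:
        return PointCloud(positions=np.zeros((0, 3)))
    if data.shape[1] not in (3, 6):
        raise FormatError(f"{path}: expected 3 or 6 columns, got {data.shape[1]}")
    colors = data[:, 3:6] if data.shape[1] == 6 else None
    return PointCloud(positions=data[:, :3], colors=colors)
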