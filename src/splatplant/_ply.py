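"""Minimal binary little-endian PLY codec for single-element vertex files.

Only the subset of PLY used by the 3DGS splat dialect and by simple
xyz/rgb point clouds is supported: one ``vertex`` element, scalar
properties, ``binary_little_endian 1.0``. Property order is preserved
exactly as declared.
"""

from __future__ import annotations

import numpy as np

from .errors import FormatError

_PLY_TO_NUMPY = {
    "float": "<f4",
    "float32": "<f4",
    "double": "<f8",
    "float64": "<f8",
    "uchar": "u1",
    "uint8": "u1",
    "char": "i1",
    "int8": "i1",
    "short": "<i2",
    "int16": "<i2",
    "ushort": "<u2",
    "uint16": "<u2",
    "int": "<i4",
    "int32": "<i4",
    "uint": "<u4",
    "uint32": "<u4",
}
_NUMPY_TO_PLY = {
    np.dtype("<f4"): "float",
    np.dtype("<f8"): "double",
    np.dtype("u1"): "uchar",
    np.dtype("i1"): "char",
    np.dtype("<i2"): "short",
    np.dtype("<u2"): "ushort",
    np.dtype("<i4"): "int",
    np.dtype("<u4"): "uint",
}


def read_vertex_element(path) -> np.ndarray:
    """Read a binary PLY file and return its vertex element as a structured array."""
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise FormatError(f"{path}: not a PLY file (missing 'ply' magic)")
        fmt = fh.readline().split()
        if len(fmt) < 2 or fmt[0] != b"format" or fmt[1] != b"binary_little_endian":
            raise FormatError(f"{path}: only binary_little_endian PLY is supported")
        count = None
        fields: list[tuple[str, str]] = []
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise FormatError(f"{path}: truncated header")
            tokens = line.split()
            if not tokens or tokens[0] == b"comment":
                continue
            if tokens[0] == b"end_header":
                break
            if tokens[0] == b"element":
                in_vertex = tokens[1] == b"vertex"
                if in_vertex:
                    count = int(tokens[2])
            elif tokens[0] == b"property" and in_vertex:
                if tokens[1] == b"list":
                    raise FormatError(f"{path}: list properties are not supported")
                ply_type = tokens[1].decode()
                name = tokens[2].decode()
                if ply_type not in _PLY_TO_NUMPY:
                    raise FormatError(f"{path}: unsupported property type {ply_type!r}")
                fields.append((name, _PLY_TO_NUMPY[ply_type]))
        if count is None:
            raise FormatError(f"{path}: no vertex element declared")
        dtype = np.dtype(fields)
        data = fh.read(count * dtype.itemsize)
        if len(data) < count * dtype.itemsize:
            raise FormatError(f"{path}: vertex data shorter than declared count")
        return np.frombuffer(data, dtype=dtype, count=count).copy()


def write_vertex_element(path, records: np.ndarray) -> None:
    """Write a structured array as a binary PLY vertex element."""
    lines = [b"ply", b"format binary_little_endian 1.0",
             f"element vertex {len(records)}".encode()]
    for name in records.dtype.names:
        dt = records.dtype[name]
        if dt not in _NUMPY_TO_PLY:
            raise FormatError(f"unsupported dtype {dt} for property {name!r}")
        lines.append(f"property {_NUMPY_TO_PLY[dt]} {name}".encode())
    lines.append(b"end_header")
    with open(path, "wb") as fh:
        fh.write(b"\n".join(lines) + b"\n")
        fh.write(records.tobytes())
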