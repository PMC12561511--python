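"""Readers and writers for standard point-cloud formats and transform files.

Supported formats
-----------------
PLY
    ascii and binary_little_endian 1.0. Only the ``vertex`` element is used
    (mesh elements, if present, are ignored — vertex extraction only). The
    first floating-point vertex property that is not ``x``/``y``/``z`` is
    loaded into the cloud's scalar feature channel; on write the channel is
    stored as a ``float32`` property named ``curvature``.
PCD
    ascii DATA only, fields ``x y z`` plus one optional scalar field.
XYZ
    whitespace-separated rows of 3 (or 4, the 4th read as the scalar feature)
    numbers; lines starting with ``#`` are comments.

Rigid transforms are serialized as plain-text 4x4 row-major homogeneous
matrices (``save_transform`` / ``load_transform``).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .types import PointCloud, RigidTransform

__all__ = [
    "read_point_cloud",
    "write_point_cloud",
    "load_transform",
    "save_transform",
]

_PLY_DTYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


def _infer_format(path: str | os.PathLike, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
    else:
        fmt = Path(path).suffix.lstrip(".").lower()
    if fmt not in ("ply", "pcd", "xyz"):
        raise ValueError(f"unsupported point-cloud format {fmt!r} (expected ply, pcd or xyz)")
    return fmt


def read_point_cloud(path: str | os.PathLike, format: str | None = None,
                     source_tag: str = "synthetic") -> PointCloud:
    """Load a point cloud from a PLY, PCD or XYZ file (coordinates in mm).

    ``format`` defaults to the file extension. A per-point scalar channel is
    loaded into :attr:`PointCloud.features` when the file carries one.
    """
    fmt = _infer_format(path, format)
    if not Path(path).exists():
        raise FileNotFoundError(f"no such point-cloud file: {path}")
    if fmt == "ply":
        points, features = _read_ply(path)
    elif fmt == "pcd":
        points, features = _read_pcd(path)
    else:
        points, features = _read_xyz(path)
    if len(points) == 0:
        raise ValueError(f"{path}: empty point cloud")
    return PointCloud(points, features, source_tag)


def write_point_cloud(cloud: PointCloud, path: str | os.PathLike,
                      format: str | None = None, binary: bool = False) -> None:
    """Write a cloud to PLY (ascii or binary little-endian), PCD or XYZ."""
    fmt = _infer_format(path, format)
    if fmt == "ply":
        _write_ply(cloud, path, binary=binary)
    elif fmt == "pcd":
        _write_pcd(cloud, path)
    else:
        _write_xyz(cloud, path)


# ---------------------------------------------------------------- PLY

def _read_ply(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray | None]:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise ValueError(f"{path}: not a PLY file (missing 'ply' magic)")
        fmt = None
        elements: list[tuple[str, int, list[tuple[str, str]]]] = []
        while True:
            raw = fh.readline()
            if not raw:
                raise ValueError(f"{path}: unexpected end of PLY header")
            line = raw.decode("ascii", errors="replace").strip()
            if line == "" or line.startswith("comment") or line.startswith("obj_info"):
                continue
            if line == "end_header":
                break
            tokens = line.split()
            if tokens[0] == "format":
                if tokens[1] not in ("ascii", "binary_little_endian"):
                    raise ValueError(f"{path}: unsupported PLY format {tokens[1]!r}")
                fmt = tokens[1]
            elif tokens[0] == "element":
                elements.append((tokens[1], int(tokens[2]), []))
            elif tokens[0] == "property":
                if not elements:
                    raise ValueError(f"{path}: property before any element in header")
                if tokens[1] == "list":
                    elements[-1][2].append((tokens[-1], f"list:{tokens[2]}:{tokens[3]}"))
                else:
                    if tokens[1] not in _PLY_DTYPES:
                        raise ValueError(f"{path}: unknown PLY property type {tokens[1]!r}")
                    elements[-1][2].append((tokens[-1], _PLY_DTYPES[tokens[1]]))
            else:
                raise ValueError(f"{path}: malformed PLY header line {line!r}")
        if fmt is None:
            raise ValueError(f"{path}: PLY header has no 'format' line")
        vertex = next((e for e in elements if e[0] == "vertex"), None)
        if vertex is None:
            raise ValueError(f"{path}: PLY file has no vertex element")
        if elements[0][0] != "vertex":
            raise ValueError(f"{path}: only PLY files with vertex as first element are supported")
        name, count, props = vertex
        if any(code.startswith("list:") for _, code in props):
            raise ValueError(f"{path}: list properties on the vertex element are not supported")
        names = [p for p, _ in props]
        for axis in ("x", "y", "z"):
            if axis not in names:
                raise ValueError(f"{path}: vertex element lacks coordinate property {axis!r}")
        dtype = np.dtype([(p, "<" + code) for p, code in props])
        if fmt == "ascii":
            rows = []
            for i in range(count):
                raw = fh.readline()
                if not raw:
                    raise ValueError(f"{path}: vertex record {i + 1} missing (expected {count})")
                fields = raw.split()
                if len(fields) != len(props):
                    raise ValueError(
                        f"{path}: vertex record {i + 1} has {len(fields)} fields, "
                        f"expected {len(props)}"
                    )
                try:
                    rows.append(tuple(float(v) for v in fields))
                except ValueError as exc:
                    raise ValueError(f"{path}: vertex record {i + 1}: {exc}") from None
            data = np.array(rows, dtype=dtype) if rows else np.empty(0, dtype=dtype)
        else:
            buf = fh.read(dtype.itemsize * count)
            if len(buf) < dtype.itemsize * count:
                raise ValueError(f"{path}: binary vertex block truncated")
            data = np.frombuffer(buf, dtype=dtype, count=count)
    points = np.column_stack([data["x"], data["y"], data["z"]]).astype(np.float64)
    features = None
    for p, code in props:
        if p not in ("x", "y", "z") and code in ("f4", "f8"):
            features = data[p].astype(np.float64)
            break
    return points, features


def _write_ply(cloud: PointCloud, path: str | os.PathLike, binary: bool) -> None:
    n = len(cloud)
    props = ["property float x", "property float y", "property float z"]
    fields = [("x", "<f4"), ("y", "<f4"), ("z", "<f4")]
    if cloud.features is not None:
        props.append("property float curvature")
        fields.append(("curvature", "<f4"))
    header = "\n".join(
        ["ply",
         f"format {'binary_little_endian' if binary else 'ascii'} 1.0",
         f"element vertex {n}",
         *props,
         "end_header", ""]
    )
    data = np.empty(n, dtype=np.dtype(fields))
    data["x"], data["y"], data["z"] = cloud.points.T.astype(np.float32)
    if cloud.features is not None:
        data["curvature"] = cloud.features.astype(np.float32)
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            fh.write(data.tobytes())
        else:
            cols = [data[name] for name, _ in fields]
            for row in zip(*cols):
                fh.write((" ".join(format(float(v), ".9g") for v in row) + "\n").encode("ascii"))


# ---------------------------------------------------------------- PCD

def _read_pcd(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray | None]:
    fields: list[str] | None = None
    count = None
    data_start = None
    with open(path, "r", encoding="ascii", errors="replace") as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        line = line.strip()
        if line.startswith("#") or not line:
            continue
        tokens = line.split()
        key = tokens[0].upper()
        if key == "FIELDS":
            fields = tokens[1:]
        elif key == "POINTS":
            count = int(tokens[1])
        elif key == "DATA":
            if tokens[1].lower() != "ascii":
                raise ValueError(f"{path}: only DATA ascii PCD files are supported")
            data_start = i + 1
            break
    if fields is None or data_start is None:
        raise ValueError(f"{path}: malformed PCD header (missing FIELDS or DATA)")
    for axis in ("x", "y", "z"):
        if axis not in fields:
            raise ValueError(f"{path}: PCD FIELDS lack coordinate {axis!r}")
    rows = []
    for lineno, line in enumerate(lines[data_start:], start=data_start + 1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != len(fields):
            raise ValueError(
                f"{path}: line {lineno} has {len(parts)} values, expected {len(fields)}"
            )
        try:
            rows.append([float(v) for v in parts])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from None
    if count is not None and count != len(rows):
        raise ValueError(f"{path}: POINTS says {count} but {len(rows)} data rows found")
    if not rows:
        return np.empty((0, 3)), None
    arr = np.asarray(rows, dtype=np.float64)
    ix, iy, iz = (fields.index(a) for a in ("x", "y", "z"))
    points = arr[:, [ix, iy, iz]]
    features = None
    extra = [i for i in range(len(fields)) if i not in (ix, iy, iz)]
    if extra:
        features = arr[:, extra[0]]
    return points, features


def _write_pcd(cloud: PointCloud, path: str | os.PathLike) -> None:
    has_feat = cloud.features is not None
    fields = "x y z" + (" curvature" if has_feat else "")
    nf = 4 if has_feat else 3
    n = len(cloud)
    header = (
        "# .PCD v0.7 - Point Cloud Data file format\n"
        "VERSION 0.7\n"
        f"FIELDS {fields}\n"
        f"SIZE {' '.join(['4'] * nf)}\n"
        f"TYPE {' '.join(['F'] * nf)}\n"
        f"COUNT {' '.join(['1'] * nf)}\n"
        f"WIDTH {n}\nHEIGHT 1\nVIEWPOINT 0 0 0 1 0 0 0\nPOINTS {n}\nDATA ascii\n"
    )
    body = cloud.points if not has_feat else np.column_stack([cloud.points, cloud.features])
    with open(path, "w", encoding="ascii") as fh:
        fh.write(header)
        for row in body:
            fh.write(" ".join(format(float(v), ".9g") for v in row) + "\n")


# ---------------------------------------------------------------- XYZ

def _read_xyz(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray | None]:
    rows = []
    ncols = None
    with open(path, "r", encoding="ascii", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (3, 4):
                raise ValueError(
                    f"{path}: line {lineno} has {len(parts)} columns (expected 3 or 4)"
                )
            if ncols is None:
                ncols = len(parts)
            elif len(parts) != ncols:
                raise ValueError(f"{path}: line {lineno} changes column count to {len(parts)}")
            try:
                rows.append([float(v) for v in parts])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    if not rows:
        return np.empty((0, 3)), None
    arr = np.asarray(rows, dtype=np.float64)
    return arr[:, :3], (arr[:, 3] if arr.shape[1] == 4 else None)


def _write_xyz(cloud: PointCloud, path: str | os.PathLike) -> None:
    body = cloud.points if cloud.features is None \
        else np.column_stack([cloud.points, cloud.features])
    with open(path, "w", encoding="ascii") as fh:
        fh.write("# x y z" + (" feature" if cloud.features is not None else "") + "\n")
        for row in body:
            fh.write(" ".join(format(float(v), ".17g") for v in row) + "\n")


# ---------------------------------------------------------------- transforms

def save_transform(t: RigidTransform, path: str | os.PathLike) -> None:
    """Write a transform as a plain-text 4x4 row-major homogeneous matrix."""
    np.savetxt(path, t.matrix, fmt="%.17g")


def load_transform(path: str | os.PathLike) -> RigidTransform:
    mat = np.loadtxt(path)
    return RigidTransform.from_matrix(mat)
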