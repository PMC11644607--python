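"""Reading and writing point clouds and label sidecars.

Supported containers: PLY (ASCII and binary little-endian, vertex element
with arbitrary scalar properties), ASCII PCD, and whitespace-separated XYZ
text.  Labeled clouds travel as a single PLY whose vertex element carries
extra integer properties ``organ`` (0=stem, 1=leaf, 2=noise, 3=unassigned)
and ``leaf_id``, or as a CSV sidecar aligned row-for-row with the cloud.

Readers never reorder points: every downstream per-point array relies on
file order being preserved.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .cloud import ORGAN_CODES, ORGAN_NAMES, EmptyCloudError, LabeledCloud, PointCloud

_PLY_TYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


class PlyParseError(ValueError):
    """Raised on a malformed PLY header or truncated body."""


def _sniff_format(path: str | Path) -> str:
    ext = Path(path).suffix.lower().lstrip(".")
    if ext in ("ply", "pcd", "xyz"):
        return ext
    if ext in ("txt", "pts"):
        return "xyz"
    raise ValueError(f"cannot infer point-cloud format from extension {ext!r}")


# ---------------------------------------------------------------------------
# PLY
# ---------------------------------------------------------------------------

def _read_ply_header(fh) -> tuple[str, int, list[tuple[str, str]], int]:
    """Parse a vertex-element PLY header from a binary file handle.

    Returns (storage, n_vertices, [(name, numpy dtype)], header_end_offset).
    """
    magic = fh.readline().strip()
    if magic != b"ply":
        raise PlyParseError("not a PLY file (missing 'ply' magic)")
    storage = None
    n_vertices = None
    props: list[tuple[str, str]] = []
    in_vertex = False
    while True:
        line = fh.readline()
        if not line:
            raise PlyParseError("unterminated PLY header")
        tokens = line.decode("ascii", "replace").strip().split()
        if not tokens or tokens[0] == "comment":
            continue
        if tokens[0] == "format":
            storage = tokens[1]
        elif tokens[0] == "element":
            in_vertex = tokens[1] == "vertex"
            if in_vertex:
                n_vertices = int(tokens[2])
            elif n_vertices is None:
                raise PlyParseError("vertex element must come first")
            elif int(tokens[2]) > 0:
                raise PlyParseError("non-vertex elements are not supported")
        elif tokens[0] == "property" and in_vertex:
            if tokens[1] == "list":
                raise PlyParseError("list properties are not supported on vertices")
            props.append((tokens[-1], _PLY_TYPES[tokens[1]]))
        elif tokens[0] == "end_header":
            break
    if storage is None or n_vertices is None:
        raise PlyParseError("incomplete PLY header")
    return storage, n_vertices, props, fh.tell()


def _read_ply(path: str | Path) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Read a vertex-only PLY; returns (points, {property: column})."""
    with open(path, "rb") as fh:
        storage, n, props, offset = _read_ply_header(fh)
        names = [p[0] for p in props]
        if not {"x", "y", "z"}.issubset(names):
            raise PlyParseError("PLY vertex element lacks x/y/z")
        if storage == "ascii":
            raw = np.loadtxt(fh, dtype=np.float64, ndmin=2) if n else np.empty((0, len(props)))
            if raw.shape[0] != n or (n and raw.shape[1] != len(props)):
                raise PlyParseError("PLY body does not match declared vertex count")
            columns = {name: raw[:, i] for i, (name, _) in enumerate(props)}
        elif storage == "binary_little_endian":
            dtype = np.dtype([(name, "<" + t) for name, t in props])
            body = fh.read(dtype.itemsize * n)
            if len(body) != dtype.itemsize * n:
                raise PlyParseError("truncated binary PLY body")
            rec = np.frombuffer(body, dtype=dtype)
            columns = {name: np.asarray(rec[name]) for name, _ in props}
        else:
            raise PlyParseError(f"unsupported PLY storage {storage!r}")
    points = np.column_stack([columns["x"], columns["y"], columns["z"]]).astype(np.float64)
    return points, columns


def _ply_color_columns(columns: dict[str, np.ndarray]) -> np.ndarray | None:
    if {"red", "green", "blue"}.issubset(columns):
        rgb = np.column_stack([columns["red"], columns["green"], columns["blue"]])
        return np.clip(rgb.astype(np.float64) / 255.0, 0.0, 1.0)
    return None


def _write_ply(
    path: str | Path,
    points: np.ndarray,
    colors: np.ndarray | None,
    extra: dict[str, np.ndarray] | None,
    binary: bool,
) -> None:
    extra = extra or {}
    header = ["ply"]
    header.append("format binary_little_endian 1.0" if binary else "format ascii 1.0")
    header.append(f"element vertex {len(points)}")
    fields: list[tuple[str, str, np.ndarray]] = [
        ("x", "double", points[:, 0]),
        ("y", "double", points[:, 1]),
        ("z", "double", points[:, 2]),
    ]
    if colors is not None:
        rgb = np.rint(np.clip(colors, 0, 1) * 255).astype(np.uint8)
        fields += [("red", "uchar", rgb[:, 0]), ("green", "uchar", rgb[:, 1]),
                   ("blue", "uchar", rgb[:, 2])]
    for name, col in extra.items():
        fields.append((name, "int", np.asarray(col, dtype=np.int32)))
    for name, ply_t, _ in fields:
        header.append(f"property {ply_t} {name}")
    header.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            dtype = np.dtype([(name, "<" + _PLY_TYPES[t]) for name, t, _ in fields])
            rec = np.empty(len(points), dtype=dtype)
            for name, t, col in fields:
                rec[name] = col.astype(_PLY_TYPES[t])
            fh.write(rec.tobytes())
        else:
            cols = []
            for name, t, col in fields:
                if t == "double":
                    cols.append([f"{v:.17g}" for v in col])
                else:
                    cols.append([str(int(v)) for v in col])
            lines = (" ".join(row) for row in zip(*cols))
            fh.write(("\n".join(lines) + "\n").encode("ascii"))


# ---------------------------------------------------------------------------
# PCD / XYZ
# ---------------------------------------------------------------------------

def _read_pcd(path: str | Path) -> tuple[np.ndarray, np.ndarray | None]:
    fields: list[str] = []
    n = None
    data = None
    with open(path, "rb") as fh:
        while True:
            line = fh.readline()
            if not line:
                raise ValueError("unterminated PCD header")
            tokens = line.decode("ascii", "replace").strip().split()
            if not tokens or tokens[0] == "#":
                continue
            key = tokens[0].upper()
            if key == "FIELDS":
                fields = tokens[1:]
            elif key == "POINTS":
                n = int(tokens[1])
            elif key == "DATA":
                data = tokens[1]
                break
        if data != "ascii":
            raise ValueError("only DATA ascii PCD files are supported")
        raw = np.loadtxt(fh, dtype=np.float64, ndmin=2)
    if n is not None and len(raw) != n:
        raise ValueError("PCD body does not match declared point count")
    idx = {f: i for i, f in enumerate(fields)}
    if not {"x", "y", "z"}.issubset(idx):
        raise ValueError("PCD lacks x/y/z fields")
    points = raw[:, [idx["x"], idx["y"], idx["z"]]]
    colors = None
    if {"r", "g", "b"}.issubset(idx):
        colors = np.clip(raw[:, [idx["r"], idx["g"], idx["b"]]] / 255.0, 0, 1)
    return points, colors


def _write_pcd(path: str | Path, points: np.ndarray, colors: np.ndarray | None) -> None:
    fields = "x y z" + (" r g b" if colors is not None else "")
    count = len(fields.split())
    header = (
        "# .PCD v0.7 - Point Cloud Data file format\n"
        "VERSION 0.7\n"
        f"FIELDS {fields}\n"
        f"SIZE {' '.join(['8'] * count)}\n"
        f"TYPE {' '.join(['F'] * count)}\n"
        f"COUNT {' '.join(['1'] * count)}\n"
        f"WIDTH {len(points)}\nHEIGHT 1\n"
        "VIEWPOINT 0 0 0 1 0 0 0\n"
        f"POINTS {len(points)}\nDATA ascii\n"
    )
    body = points
    if colors is not None:
        body = np.column_stack([points, np.rint(np.clip(colors, 0, 1) * 255)])
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.17g")


def _read_xyz(path: str | Path) -> tuple[np.ndarray, np.ndarray | None]:
    raw = np.loadtxt(path, dtype=np.float64, ndmin=2)
    if raw.size == 0:
        return np.empty((0, 3)), None
    points = raw[:, :3]
    colors = None
    if raw.shape[1] >= 6:
        rgb = raw[:, 3:6]
        colors = np.clip(rgb / 255.0 if rgb.max(initial=0) > 1 else rgb, 0, 1)
    return points, colors


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_point_cloud(path: str | Path, format: str = "auto") -> PointCloud:
    """Read a point cloud, preserving file order.

    Parameters
    ----------
    path
        Input file.
    format
        ``"ply"``, ``"pcd"``, ``"xyz"`` or ``"auto"`` (infer from extension).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = _sniff_format(path) if format == "auto" else format
    if fmt == "ply":
        points, columns = _read_ply(path)
        colors = _ply_color_columns(columns)
    elif fmt == "pcd":
        points, colors = _read_pcd(path)
    elif fmt == "xyz":
        points, colors = _read_xyz(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if len(points) == 0:
        raise EmptyCloudError(f"{path}: file contains no points")
    return PointCloud(points, colors, source=str(path))


def write_point_cloud(cloud: PointCloud, path: str | Path, format: str = "auto",
                      binary: bool = False) -> None:
    """Write a cloud; the output re-reads to identical coordinates.

    ASCII encodings use 17 significant digits (round-trip exact for float64);
    binary PLY is bitwise exact.  Colors are quantized to 8 bits per channel.
    """
    if len(cloud) == 0:
        raise EmptyCloudError("refusing to write an empty cloud")
    fmt = _sniff_format(path) if format == "auto" else format
    if fmt == "ply":
        _write_ply(path, cloud.points, cloud.colors, None, binary=binary)
    elif fmt == "pcd":
        _write_pcd(path, cloud.points, cloud.colors)
    elif fmt == "xyz":
        body = cloud.points
        if cloud.colors is not None:
            body = np.column_stack([body, np.rint(cloud.colors * 255)])
        np.savetxt(path, body, fmt="%.17g")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_labels(labeled: LabeledCloud, path: str | Path, binary: bool = False) -> None:
    """Write organ/leaf-instance labels.

    ``.ply`` targets get a self-contained labeled cloud (coordinates plus
    integer ``organ`` and ``leaf_id`` vertex properties); ``.csv`` targets get
    a sidecar table (``organ`` token, ``leaf_id``) aligned with the cloud.
    """
    ext = Path(path).suffix.lower()
    if ext == ".ply":
        _write_ply(path, labeled.points, labeled.cloud.colors,
                   {"organ": labeled.organ, "leaf_id": labeled.leaf_id}, binary=binary)
    elif ext == ".csv":
        with open(path, "w") as fh:
            fh.write("organ,leaf_id\n")
            for code, lid in zip(labeled.organ, labeled.leaf_id):
                fh.write(f"{ORGAN_NAMES[int(code)]},{int(lid)}\n")
    else:
        raise ValueError(f"label files must be .ply or .csv, got {ext!r}")


def read_labels(path: str | Path, cloud: PointCloud | None = None) -> LabeledCloud:
    """Read labels back into a :class:`LabeledCloud`.

    For a labeled PLY the cloud itself comes from the file (``cloud`` may be
    omitted); for a CSV sidecar the matching ``cloud`` is required and its
    point count must equal the sidecar row count.
    """
    ext = Path(path).suffix.lower()
    if ext == ".ply":
        points, columns = _read_ply(path)
        if "organ" not in columns or "leaf_id" not in columns:
            raise ValueError(f"{path}: PLY lacks organ/leaf_id vertex properties")
        base = cloud if cloud is not None else PointCloud(
            points, _ply_color_columns(columns), source=str(path))
        if len(base) != len(points):
            raise ValueError("label file row count does not match cloud")
        return LabeledCloud(base, columns["organ"].astype(np.int32),
                            columns["leaf_id"].astype(np.int32))
    if ext == ".csv":
        if cloud is None:
            raise ValueError("a CSV label sidecar needs the matching cloud")
        organs, leaf_ids = [], []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("organ"):
                raise ValueError("label CSV must start with an 'organ,leaf_id' header")
            for ln, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                token, lid = line.strip().split(",")
                if token not in ORGAN_CODES:
                    raise ValueError(f"{path}:{ln}: unknown organ token {token!r}")
                organs.append(ORGAN_CODES[token])
                leaf_ids.append(int(lid))
        if len(organs) != len(cloud):
            raise ValueError(
                f"label rows ({len(organs)}) do not match point count ({len(cloud)})")
        return LabeledCloud(cloud, np.array(organs), np.array(leaf_ids))
    raise ValueError(f"label files must be .ply or .csv, got {ext!r}")
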