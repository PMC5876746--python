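"""Point-cloud container, PLY input/output, voxel downsampling and normal estimation.

Coordinates are millimetres throughout; the vertical axis of a hanging bunch
is y.  Supported PLY dialects are ``ascii 1.0`` and ``binary_little_endian
1.0`` with a vertex element carrying float ``x y z`` properties, optional
``nx ny nz`` normals and optional uchar ``red green blue`` colors.  Face
elements are skipped: the pipeline operates on points only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "PointCloud",
    "PlyParseError",
    "UnsupportedPlyError",
    "read_ply",
    "write_ply",
    "downsample",
    "estimate_normals",
]


class PlyParseError(ValueError):
    """Malformed PLY header or truncated payload."""


class UnsupportedPlyError(ValueError):
    """PLY dialect outside ascii / binary_little_endian 1.0."""


@dataclass
class PointCloud:
    """N points in mm with optional unit normals, RGB colors and curvature.

    Invariants (checked by :meth:`validate`): coordinates are finite;
    ``normals`` and ``colors``, when present, match ``points`` in length;
    normals are unit vectors to 1e-6.
    """

    points: np.ndarray
    normals: np.ndarray | None = None
    colors: np.ndarray | None = None
    curvature: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.points = np.ascontiguousarray(self.points, dtype=np.float64).reshape(-1, 3)
        if self.normals is not None:
            self.normals = np.ascontiguousarray(self.normals, dtype=np.float64).reshape(-1, 3)
        if self.colors is not None:
            self.colors = np.ascontiguousarray(self.colors, dtype=np.uint8).reshape(-1, 3)
        if self.curvature is not None:
            self.curvature = np.asarray(self.curvature, dtype=np.float64).ravel()

    def __len__(self) -> int:
        return len(self.points)

    @property
    def has_normals(self) -> bool:
        return self.normals is not None

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated container invariant."""
        if not np.isfinite(self.points).all():
            raise ValueError("point coordinates must be finite")
        for name in ("normals", "colors", "curvature"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != len(self.points):
                raise ValueError(f"{name} length {len(arr)} != point count {len(self.points)}")
        if self.normals is not None and len(self.normals):
            norms = np.linalg.norm(self.normals, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("normals must be unit vectors (|norm - 1| <= 1e-6)")

    def translated(self, offset) -> "PointCloud":
        return PointCloud(self.points + np.asarray(offset, dtype=np.float64),
                          normals=self.normals, colors=self.colors, curvature=self.curvature)


# ---------------------------------------------------------------------------
# PLY reading

_PLY_SCALARS = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


def _parse_header(fh):
    """Parse the PLY header, returning (format, elements, header_end_offset).

    ``elements`` is a list of (name, count, properties) where each property is
    ("scalar", name, dtype) or ("list", name, count_dtype, item_dtype).
    """
    magic = fh.readline()
    if magic.strip() != b"ply":
        raise PlyParseError("not a PLY file: missing 'ply' magic on line 1")
    fmt = None
    elements: list[tuple[str, int, list]] = []
    lineno = 1
    while True:
        raw = fh.readline()
        lineno += 1
        if not raw:
            raise PlyParseError(f"unexpected end of header at line {lineno}")
        tokens = raw.decode("ascii", errors="replace").split()
        if not tokens:
            continue
        kw = tokens[0]
        if kw == "comment" or kw == "obj_info":
            continue
        if kw == "format":
            if len(tokens) != 3:
                raise PlyParseError(f"malformed format line {lineno}")
            fmt = tokens[1]
            if fmt == "binary_big_endian":
                raise UnsupportedPlyError("binary_big_endian PLY is not supported")
            if fmt not in ("ascii", "binary_little_endian"):
                raise UnsupportedPlyError(f"unsupported PLY format {fmt!r}")
            if tokens[2] != "1.0":
                raise UnsupportedPlyError(f"unsupported PLY version {tokens[2]!r}")
        elif kw == "element":
            if len(tokens) != 3:
                raise PlyParseError(f"malformed element line {lineno}")
            try:
                count = int(tokens[2])
            except ValueError:
                raise PlyParseError(f"bad element count on line {lineno}") from None
            elements.append((tokens[1], count, []))
        elif kw == "property":
            if not elements:
                raise PlyParseError(f"property before any element at line {lineno}")
            props = elements[-1][2]
            if tokens[1] == "list":
                if len(tokens) != 5:
                    raise PlyParseError(f"malformed list property at line {lineno}")
                props.append(("list", tokens[4], _PLY_SCALARS[tokens[2]], _PLY_SCALARS[tokens[3]]))
            else:
                if len(tokens) != 3 or tokens[1] not in _PLY_SCALARS:
                    raise PlyParseError(f"malformed property at line {lineno}")
                props.append(("scalar", tokens[2], _PLY_SCALARS[tokens[1]]))
        elif kw == "end_header":
            break
        else:
            raise PlyParseError(f"unknown header keyword {kw!r} at line {lineno}")
    if fmt is None:
        raise PlyParseError("header missing 'format' line")
    return fmt, elements


def read_ply(path) -> PointCloud:
    """Read a PLY point cloud (ascii or binary little-endian).

    One point per vertex record; ``nx ny nz`` and ``red green blue`` vertex
    properties are loaded when present; any face element is ignored.

    Raises ``FileNotFoundError``, :class:`PlyParseError` on malformed input
    and :class:`UnsupportedPlyError` on big-endian or non-1.0 files.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        fmt, elements = _parse_header(fh)
        vertex = next((e for e in elements if e[0] == "vertex"), None)
        if vertex is None:
            raise PlyParseError("no 'vertex' element in header")
        if any(p[0] == "list" for p in vertex[2]):
            raise PlyParseError("list properties on the vertex element are not supported")
        names = [p[1] for p in vertex[2]]
        for axis in "xyz":
            if axis not in names:
                raise PlyParseError(f"vertex element lacks property {axis!r}")
        if fmt == "ascii":
            data = _read_ascii_elements(fh, elements)["vertex"]
        else:
            data = _read_binary_elements(fh, elements)["vertex"]
        points = np.column_stack([data["x"], data["y"], data["z"]]).astype(np.float64)
        normals = None
        if all(n in data for n in ("nx", "ny", "nz")):
            normals = np.column_stack([data["nx"], data["ny"], data["nz"]]).astype(np.float64)
            lengths = np.linalg.norm(normals, axis=1)
            nz = lengths > 0
            normals[nz] /= lengths[nz, None]
        colors = None
        if all(c in data for c in ("red", "green", "blue")):
            colors = np.column_stack([data["red"], data["green"], data["blue"]]).astype(np.uint8)
        return PointCloud(points, normals=normals, colors=colors)


def _read_ascii_elements(fh, elements):
    out = {}
    text = fh.read().decode("ascii", errors="replace").split("\n")
    cursor = 0
    for name, count, props in elements:
        has_list = any(p[0] == "list" for p in props)
        rows = {p[1]: [] for p in props if p[0] == "scalar"}
        for i in range(count):
            while cursor < len(text) and not text[cursor].strip():
                cursor += 1
            if cursor >= len(text):
                raise PlyParseError(f"truncated payload: element {name!r} row {i} missing")
            tokens = text[cursor].split()
            cursor += 1
            if has_list:
                continue  # faces etc.: consumed, not stored
            if len(tokens) < len(props):
                raise PlyParseError(f"short row for element {name!r} at data line {cursor}")
            for (kind, pname, dtype), tok in zip(props, tokens):
                rows[pname].append(float(tok))
        out[name] = {k: np.asarray(v) for k, v in rows.items()}
    return out


def _read_binary_elements(fh, elements):
    out = {}
    for name, count, props in elements:
        if any(p[0] == "list" for p in props):
            # variable-length rows (faces): walk them record by record
            for i in range(count):
                for p in props:
                    if p[0] == "scalar":
                        fh.read(np.dtype(p[2]).itemsize)
                    else:
                        _, _, cnt_dt, item_dt = p
                        raw = fh.read(np.dtype(cnt_dt).itemsize)
                        if len(raw) < np.dtype(cnt_dt).itemsize:
                            raise PlyParseError(
                                f"truncated payload in element {name!r} record {i} at byte {fh.tell()}")
                        n = int(np.frombuffer(raw, dtype="<" + cnt_dt)[0])
                        fh.read(n * np.dtype(item_dt).itemsize)
            out[name] = {}
            continue
        dtype = np.dtype([(p[1], "<" + p[2]) for p in props])
        raw = fh.read(count * dtype.itemsize)
        if len(raw) < count * dtype.itemsize:
            raise PlyParseError(
                f"truncated payload: element {name!r} needs {count * dtype.itemsize} bytes, "
                f"got {len(raw)} (at byte {fh.tell()})")
        rec = np.frombuffer(raw, dtype=dtype)
        out[name] = {p[1]: rec[p[1]] for p in props}
    return out


# ---------------------------------------------------------------------------
# PLY writing

def write_ply(cloud: PointCloud, path, binary: bool = False) -> None:
    """Write ``cloud`` as PLY, ascii or binary_little_endian per ``binary``.

    Coordinates (and normals) are written as float64 so a binary round trip
    is bit-identical; ascii uses %.17g which round-trips float64 exactly.
    """
    cloud.validate()
    path = Path(path)
    n = len(cloud)
    header = ["ply",
              f"format {'binary_little_endian' if binary else 'ascii'} 1.0",
              f"element vertex {n}",
              "property double x", "property double y", "property double z"]
    if cloud.normals is not None:
        header += ["property double nx", "property double ny", "property double nz"]
    if cloud.colors is not None:
        header += ["property uchar red", "property uchar green", "property uchar blue"]
    header.append("end_header")

    columns: list[np.ndarray] = [cloud.points]
    if cloud.normals is not None:
        columns.append(cloud.normals)
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fields = [(f"f{i}", "<f8") for i in range(3 * len(columns))]
            if cloud.colors is not None:
                fields += [("red", "u1"), ("green", "u1"), ("blue", "u1")]
            rec = np.empty(n, dtype=np.dtype(fields))
            flat = np.hstack(columns) if columns else np.empty((n, 0))
            for i in range(flat.shape[1]):
                rec[f"f{i}"] = flat[:, i]
            if cloud.colors is not None:
                rec["red"], rec["green"], rec["blue"] = cloud.colors.T
            fh.write(rec.tobytes())
        else:
            flat = np.hstack(columns)
            for i in range(n):
                parts = ["%.17g" % v for v in flat[i]]
                if cloud.colors is not None:
                    parts += [str(int(v)) for v in cloud.colors[i]]
                fh.write((" ".join(parts) + "\n").encode("ascii"))


# ---------------------------------------------------------------------------
# Downsampling

def downsample(cloud: PointCloud, resolution: float) -> PointCloud:
    """Voxel-grid downsample to one centroid point per occupied cubic voxel.

    Voxels have edge ``resolution`` (mm) with bins ``floor(coord/resolution)``
    anchored at the origin; each occupied voxel is replaced by the centroid of
    its members (normals/colors averaged, normals renormalized).  Deterministic
    and order-independent.  Curvature, being neighborhood-dependent, is
    dropped; re-run :func:`estimate_normals` afterwards if needed.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    n = len(cloud)
    if n == 0:
        return PointCloud(np.empty((0, 3)))
    keys = np.floor(cloud.points / resolution).astype(np.int64)
    # lexicographic unique over rows; inverse maps each point to its voxel id
    _, inverse = np.unique(keys, axis=0, return_inverse=True)
    inverse = inverse.ravel()
    n_vox = inverse.max() + 1
    counts = np.bincount(inverse, minlength=n_vox).astype(np.float64)

    def _mean(arr):
        acc = np.zeros((n_vox, arr.shape[1]))
        np.add.at(acc, inverse, arr.astype(np.float64))
        return acc / counts[:, None]

    points = _mean(cloud.points)
    normals = None
    if cloud.normals is not None:
        normals = _mean(cloud.normals)
        lengths = np.linalg.norm(normals, axis=1)
        lengths[lengths == 0] = 1.0  # cancelled normals: leave degenerate direction
        normals /= lengths[:, None]
        bad = np.abs(np.linalg.norm(normals, axis=1) - 1) > 1e-9
        normals[bad] = np.array([0.0, 1.0, 0.0])
    colors = None
    if cloud.colors is not None:
        colors = np.clip(np.rint(_mean(cloud.colors)), 0, 255).astype(np.uint8)
    return PointCloud(points, normals=normals, colors=colors)


# ---------------------------------------------------------------------------
# Normal estimation

def estimate_normals(cloud: PointCloud, k: int = 30) -> PointCloud:
    """Estimate per-point unit normals and a curvature score by local PCA.

    For each point the covariance of its k nearest neighbors (self included)
    is eigendecomposed; the normal is the eigenvector of the smallest
    eigenvalue and curvature = lambda_0 / (lambda_0+lambda_1+lambda_2),
    bounded in [0, 1/3] (0 for a perfect plane).  Normals are oriented away
    from the local neighborhood centroid, i.e. outward on convex surfaces
    such as berries.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    n = len(cloud)
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} points, have {n}")
    tree = cKDTree(cloud.points)
    _, idx = tree.query(cloud.points, k=k + 1, workers=-1)
    neigh = cloud.points[idx]                       # (n, k+1, 3)
    centroid = neigh.mean(axis=1)                   # (n, 3)
    centered = neigh - centroid[:, None, :]
    cov = np.einsum("nki,nkj->nij", centered, centered) / (k + 1)
    evals, evecs = np.linalg.eigh(cov)              # ascending eigenvalues
    normals = evecs[:, :, 0]
    total = evals.sum(axis=1)
    total[total == 0] = 1.0
    curvature = np.clip(evals[:, 0] / total, 0.0, 1.0 / 3.0)

    # orient outward: away from the local centroid; deterministic sign for
    # near-planar patches where the centroid offset vanishes
    outward = cloud.points - centroid
    sign = np.einsum("ij,ij->i", normals, outward)
    planar = np.abs(sign) < 1e-12
    if planar.any():
        lead = np.argmax(np.abs(normals[planar]), axis=1)
        sign[planar] = normals[planar, lead]
    normals = np.where(sign[:, None] < 0, -normals, normals)
    lengths = np.linalg.norm(normals, axis=1)
    normals /= lengths[:, None]
    return PointCloud(cloud.points, normals=normals, colors=cloud.colors, curvature=curvature)
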