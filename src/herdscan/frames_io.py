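"""Core data model and file I/O for RGB-D frames, point clouds and meshes.

Conventions
-----------
* Pixel ``(u, v)`` refers to the pixel centre; the image origin is top-left,
  ``u`` runs along the width, ``v`` along the height.  The camera looks down
  +z with x right and y down (standard pinhole convention).
* Depth maps are metric metres; values that are non-positive or NaN mark
  invalid pixels.  On disk depth is a single-channel 16-bit PNG in
  millimetres with 0 = invalid.
* Point clouds travel as binary little-endian PLY with properties
  ``x,y,z,red,green,blue`` and optionally ``nx,ny,nz``; meshes as PLY or
  OBJ (chosen by extension).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import trimesh

from .errors import DimensionError, ParameterError, ParseError, SchemaError

__all__ = [
    "CameraIntrinsics",
    "RGBDFrame",
    "RigidTransform",
    "ColoredPointCloud",
    "TriangleMesh",
    "Mask",
    "read_frame",
    "write_frame",
    "read_pointcloud",
    "write_pointcloud",
    "read_mesh",
    "write_mesh",
    "read_intrinsics",
    "write_intrinsics",
]


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole camera intrinsics (focal lengths and principal point in pixels)."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int

    def __post_init__(self):
        if self.fx <= 0 or self.fy <= 0:
            raise ParameterError("focal lengths must be positive")
        if self.width < 1 or self.height < 1:
            raise ParameterError("image size must be at least 1x1")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ParameterError("principal point must lie inside the image")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 calibration matrix K."""
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )


class RigidTransform:
    """An SE(3) pose stored as a 4x4 homogeneous matrix.

    The rotation block must be orthonormal with determinant +1 (checked to
    1e-9 on construction); composition uses ``@`` and inversion exploits the
    rigid structure (transpose, no general inverse).
    """

    __slots__ = ("matrix",)

    def __init__(self, matrix: np.ndarray):
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise DimensionError(f"expected 4x4 matrix, got {m.shape}")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=1e-12):
            raise ParameterError("last row of a rigid transform must be (0,0,0,1)")
        r = m[:3, :3]
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-9):
            raise ParameterError("rotation block is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ParameterError("rotation block has negative determinant")
        self.matrix = m

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(cls, rotation, translation) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = rotation
        m[:3, 3] = translation
        return cls(m)

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return RigidTransform(self.matrix @ other.matrix)

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        m = np.eye(4)
        m[:3, :3] = rt
        m[:3, 3] = -rt @ self.translation
        return RigidTransform(m)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (N,3) array of points (or a single 3-vector)."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def rotate(self, vectors: np.ndarray) -> np.ndarray:
        """Rotate direction vectors (no translation)."""
        return np.asarray(vectors, dtype=float) @ self.rotation.T

    def __repr__(self):
        return f"RigidTransform(\n{self.matrix!r})"


@dataclass
class RGBDFrame:
    """One camera's colour image, metric depth map and intrinsics."""

    color: np.ndarray  # (H, W, 3) in [0, 1]
    depth: np.ndarray  # (H, W) metres; <=0 or NaN invalid
    intrinsics: CameraIntrinsics
    camera_id: int = 1

    def __post_init__(self):
        self.color = np.asarray(self.color, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        if self.color.ndim != 3 or self.color.shape[2] != 3:
            raise DimensionError("color must be (H, W, 3)")
        if self.depth.shape != self.color.shape[:2]:
            raise DimensionError(
                f"depth shape {self.depth.shape} does not match color "
                f"{self.color.shape[:2]}"
            )
        h, w = self.depth.shape
        if (h, w) != (self.intrinsics.height, self.intrinsics.width):
            raise DimensionError("image size does not match intrinsics")
        if self.camera_id < 1:
            raise ParameterError("camera_id must be >= 1")

    @property
    def valid(self) -> np.ndarray:
        """Boolean map of valid depth pixels."""
        return np.isfinite(self.depth) & (self.depth > 0)


@dataclass
class ColoredPointCloud:
    """3-D points with per-point colour, optional normals and colour gradients."""

    points: np.ndarray  # (N, 3) metres
    colors: np.ndarray  # (N, 3) in [0, 1]
    normals: np.ndarray | None = None  # (N, 3) unit vectors
    color_gradients: np.ndarray | None = None  # (N, 3)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.colors = np.asarray(self.colors, dtype=float).reshape(-1, 3)
        n = len(self.points)
        if len(self.colors) != n:
            raise DimensionError("colors must match point count")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)
            if len(self.normals) != n:
                raise DimensionError("normals must match point count")
        if self.color_gradients is not None:
            self.color_gradients = np.asarray(
                self.color_gradients, dtype=float
            ).reshape(-1, 3)
            if len(self.color_gradients) != n:
                raise DimensionError("color_gradients must match point count")

    def __len__(self) -> int:
        return len(self.points)

    def transformed(self, pose: RigidTransform) -> "ColoredPointCloud":
        """Return a copy with points (and normals/gradients) rigidly moved."""
        return ColoredPointCloud(
            points=pose.apply(self.points),
            colors=self.colors.copy(),
            normals=None if self.normals is None else pose.rotate(self.normals),
            color_gradients=None
            if self.color_gradients is None
            else pose.rotate(self.color_gradients),
        )

    @property
    def intensity(self) -> np.ndarray:
        """Grayscale intensity: mean of the RGB channels."""
        return self.colors.mean(axis=1)


@dataclass
class TriangleMesh:
    """Triangle mesh; faces are counter-clockwise viewed from outside."""

    vertices: np.ndarray  # (V, 3)
    faces: np.ndarray  # (F, 3) int

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise DimensionError("face indices out of vertex range")


@dataclass
class Mask:
    """Per-frame boolean segmentation mask."""

    values: np.ndarray  # (H, W) bool
    frame_id: int = 1

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise DimensionError("mask must be 2-D")

    def __invert__(self) -> "Mask":
        return Mask(~self.values, self.frame_id)


# ---------------------------------------------------------------------------
# Frame I/O: PNG pair + JSON intrinsics sidecar
# ---------------------------------------------------------------------------

_INTRINSICS_FIELDS = ("fx", "fy", "cx", "cy", "width", "height")


def read_intrinsics(path) -> CameraIntrinsics:
    with open(path) as fh:
        doc = json.load(fh)
    missing = [k for k in _INTRINSICS_FIELDS if k not in doc]
    if missing:
        raise SchemaError(f"intrinsics file {path} missing fields: {missing}")
    return CameraIntrinsics(
        fx=float(doc["fx"]),
        fy=float(doc["fy"]),
        cx=float(doc["cx"]),
        cy=float(doc["cy"]),
        width=int(doc["width"]),
        height=int(doc["height"]),
    )


def write_intrinsics(intr: CameraIntrinsics, path) -> None:
    doc = {k: getattr(intr, k) for k in _INTRINSICS_FIELDS}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_frame(color_path, depth_path, intrinsics_path, camera_id: int = 1) -> RGBDFrame:
    """Read an RGB-D frame from an 8-bit colour PNG + 16-bit mm depth PNG.

    Depth is converted to metres (value / 1000); zero depth pixels become
    invalid (encoded as 0.0 m which :attr:`RGBDFrame.valid` treats as invalid).
    """
    intr = read_intrinsics(intrinsics_path)
    color_raw = iio.imread(color_path)
    depth_raw = iio.imread(depth_path)
    if color_raw.ndim != 3 or color_raw.shape[2] < 3:
        raise DimensionError("color PNG must have 3 channels")
    color = color_raw[..., :3].astype(float) / 255.0
    if depth_raw.ndim != 2:
        raise DimensionError("depth PNG must be single-channel")
    if color.shape[:2] != depth_raw.shape:
        raise DimensionError(
            f"color {color.shape[:2]} and depth {depth_raw.shape} sizes differ"
        )
    depth = depth_raw.astype(float) / 1000.0
    return RGBDFrame(color=color, depth=depth, intrinsics=intr, camera_id=camera_id)


def write_frame(frame: RGBDFrame, color_path, depth_path, intrinsics_path=None) -> None:
    """Write a frame as 8-bit colour PNG + 16-bit millimetre depth PNG."""
    color8 = np.clip(np.round(frame.color * 255.0), 0, 255).astype(np.uint8)
    depth_mm = np.where(frame.valid, np.round(frame.depth * 1000.0), 0.0)
    depth16 = np.clip(depth_mm, 0, np.iinfo(np.uint16).max).astype(np.uint16)
    iio.imwrite(color_path, color8)
    iio.imwrite(depth_path, depth16)
    if intrinsics_path is not None:
        write_intrinsics(frame.intrinsics, intrinsics_path)


# ---------------------------------------------------------------------------
# Point-cloud PLY codec (binary little-endian)
# ---------------------------------------------------------------------------


def write_pointcloud(pc: ColoredPointCloud, path) -> None:
    """Write a cloud as binary little-endian PLY (x,y,z,rgb[,nx,ny,nz])."""
    with_normals = pc.normals is not None
    n = len(pc)
    header = ["ply", "format binary_little_endian 1.0", f"element vertex {n}"]
    header += [f"property float {c}" for c in ("x", "y", "z")]
    if with_normals:
        header += [f"property float {c}" for c in ("nx", "ny", "nz")]
    header += [f"property uchar {c}" for c in ("red", "green", "blue")]
    header.append("end_header")

    fields = [("x", "<f4"), ("y", "<f4"), ("z", "<f4")]
    if with_normals:
        fields += [("nx", "<f4"), ("ny", "<f4"), ("nz", "<f4")]
    fields += [("red", "u1"), ("green", "u1"), ("blue", "u1")]
    rec = np.empty(n, dtype=fields)
    rec["x"], rec["y"], rec["z"] = pc.points.T.astype("<f4")
    if with_normals:
        rec["nx"], rec["ny"], rec["nz"] = pc.normals.T.astype("<f4")
    col8 = np.clip(np.round(pc.colors * 255.0), 0, 255).astype(np.uint8)
    rec["red"], rec["green"], rec["blue"] = col8.T
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        fh.write(rec.tobytes())


_PLY_DTYPES = {
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


def read_pointcloud(path) -> ColoredPointCloud:
    """Read a binary little-endian (or ASCII) PLY vertex cloud."""
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise ParseError(f"{path}: not a PLY file")
        fmt = None
        n_vertex = None
        props: list[tuple[str, str]] = []
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise ParseError(f"{path}: unterminated PLY header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens:
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "comment":
                continue
            elif tokens[0] == "element":
                in_vertex = tokens[1] == "vertex"
                if in_vertex:
                    n_vertex = int(tokens[2])
            elif tokens[0] == "property" and in_vertex:
                if tokens[1] == "list":
                    raise ParseError(f"{path}: list property on vertex element")
                if tokens[1] not in _PLY_DTYPES:
                    raise ParseError(f"{path}: unsupported property type {tokens[1]}")
                props.append((tokens[2], _PLY_DTYPES[tokens[1]]))
            elif tokens[0] == "end_header":
                break
        if fmt is None or n_vertex is None:
            raise ParseError(f"{path}: malformed PLY header")
        dtype = np.dtype([(name, dt) for name, dt in props])
        if fmt == "binary_little_endian":
            rec = np.frombuffer(fh.read(dtype.itemsize * n_vertex), dtype=dtype)
        elif fmt == "ascii":
            rec = np.loadtxt(fh, dtype=dtype, max_rows=n_vertex, ndmin=1)
        else:
            raise ParseError(f"{path}: unsupported PLY format {fmt}")

    names = {name for name, _ in props}
    for c in ("x", "y", "z"):
        if c not in names:
            raise ParseError(f"{path}: missing vertex coordinate '{c}'")
    points = np.column_stack([rec["x"], rec["y"], rec["z"]]).astype(float)
    if {"red", "green", "blue"} <= names:
        colors = (
            np.column_stack([rec["red"], rec["green"], rec["blue"]]).astype(float)
            / 255.0
        )
    else:
        colors = np.full((n_vertex, 3), 0.5)
    normals = None
    if {"nx", "ny", "nz"} <= names:
        normals = np.column_stack([rec["nx"], rec["ny"], rec["nz"]]).astype(float)
    return ColoredPointCloud(points=points, colors=colors, normals=normals)


# ---------------------------------------------------------------------------
# Mesh I/O via trimesh (PLY binary / OBJ ascii by extension)
# ---------------------------------------------------------------------------


def write_mesh(mesh: TriangleMesh, path) -> None:
    path = Path(path)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(path)


def read_mesh(path, quad_policy: str = "triangulate") -> TriangleMesh:
    """Read a PLY/OBJ mesh.

    Non-triangular faces are fan-triangulated when ``quad_policy`` is
    ``"triangulate"`` (trimesh's default load behaviour) or rejected when it
    is ``"error"``.
    """
    path = Path(path)
    if quad_policy not in ("triangulate", "error"):
        raise ParameterError(f"unknown quad policy {quad_policy!r}")
    if quad_policy == "error":
        # inspect raw face arity before trimesh triangulates
        raw = trimesh.load(path, process=False, force="mesh")
        if _had_polygon_faces(path):
            raise ParseError(f"{path}: non-triangular faces present")
        tm = raw
    else:
        tm = trimesh.load(path, process=False, force="mesh")
    return TriangleMesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces))


def _had_polygon_faces(path: Path) -> bool:
    if path.suffix.lower() != ".obj":
        return False
    with open(path) as fh:
        for line in fh:
            if line.startswith("f ") and len(line.split()) > 4:
                return True
    return False
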