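"""Poisson surface reconstruction and morphometric trait extraction.

An oriented point cloud is turned into a watertight triangle mesh by
recovering a smoothed indicator-like implicit function X from the normal
field: the oriented normals are splatted into a regular grid vector field V
and the Poisson equation ``lap X = div V`` is solved with zero-Dirichlet
boundary conditions by a fast discrete sine transform.  The isosurface at
the mean sampled value of X is extracted with marching cubes, and surface
area / volume follow from the triangle sum and the divergence theorem.

A regular grid replaces the adaptive octree of the classical formulation:
desk-scale targets fit comfortably in a <=128^3 lattice and the contract —
smooth, watertight, iso level at the mean sample value — is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage
from skimage.measure import marching_cubes

from .errors import HerdscanError, InsufficientPointsError, ParameterError, WatertightnessError
from .frames_io import ColoredPointCloud, TriangleMesh

__all__ = [
    "ImplicitField",
    "TraitReport",
    "solve_poisson_dirichlet",
    "compute_indicator_field",
    "poisson_reconstruct",
    "mesh_surface_area",
    "mesh_volume",
    "check_watertight",
    "extract_traits",
]


@dataclass
class ImplicitField:
    """Scalar field on a regular lattice over the cloud's padded bounding box."""

    grid: np.ndarray  # (R, R, R), axis order (x, y, z)
    origin: np.ndarray  # (3,) world position of node (0,0,0)
    spacing: np.ndarray  # (3,) per-axis node spacing, metres

    def __post_init__(self):
        if self.grid.shape[0] < 16:
            raise ParameterError("field resolution must be >= 16")
        if np.any(self.spacing <= 0):
            raise ParameterError("spacing must be positive")

    @property
    def resolution(self) -> int:
        return self.grid.shape[0]

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Trilinear samples of the field at world points."""
        gc = (points - self.origin) / self.spacing
        # map_coordinates expects (axis, n) index coordinates
        return ndimage.map_coordinates(self.grid, gc.T, order=1, mode="nearest")


@dataclass
class TraitReport:
    """Morphometric output of one scan."""

    surface_area: float  # m^2
    volume: float  # m^3
    watertight: bool
    point_count: int
    vertex_count: int
    face_count: int
    timings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "surface_area_m2": self.surface_area,
            "volume_m3": self.volume,
            "watertight": self.watertight,
            "point_count": self.point_count,
            "vertex_count": self.vertex_count,
            "face_count": self.face_count,
            "timings_s": self.timings,
        }


def solve_poisson_dirichlet(rhs: np.ndarray, spacing) -> np.ndarray:
    """Solve ``lap X = rhs`` on a grid with X = 0 on the boundary.

    ``rhs`` holds the interior nodes only; the 7-point Laplacian with
    per-axis spacing is diagonalized by the type-I discrete sine transform,
    so the solve is exact (to round-off) and O(N log N).
    """
    spacing = np.asarray(spacing, dtype=float)
    n = rhs.shape
    rhat = sp_fft.dstn(rhs, type=1)
    eig = np.zeros(n)
    for ax in range(3):
        k = np.arange(1, n[ax] + 1)
        lam = (2.0 * np.cos(np.pi * k / (n[ax] + 1)) - 2.0) / spacing[ax] ** 2
        shape = [1, 1, 1]
        shape[ax] = n[ax]
        eig = eig + lam.reshape(shape)
    xhat = rhat / eig
    return sp_fft.idstn(xhat, type=1)


def compute_indicator_field(
    pc: ColoredPointCloud,
    resolution: int = 128,
    padding: float = 0.1,
    smoothing_m: float = 0.005,
) -> ImplicitField:
    """Build the smoothed indicator-like field X from an oriented cloud.

    Normals are splatted trilinearly into the grid vector field V, V is
    smoothed with a Gaussian of physical width ``smoothing_m`` (the splat
    kernel), the divergence is taken by central differences, and
    ``lap X = div V`` is solved spectrally with zero-Dirichlet boundaries.
    """
    if pc.normals is None:
        raise HerdscanError("indicator field requires oriented normals")
    if len(pc) < 50:
        raise InsufficientPointsError(f"{len(pc)} points; need at least 50")
    if resolution < 16:
        raise ParameterError("resolution must be >= 16")
    pts = pc.points
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    extent = np.maximum(hi - lo, 1e-6)
    lo = lo - padding * extent
    hi = hi + padding * extent
    spacing = (hi - lo) / (resolution - 1)
    origin = lo

    gc = (pts - origin) / spacing
    i0 = np.floor(gc).astype(np.int64)
    frac = gc - i0
    acc = np.zeros((resolution**3, 3))
    dens = np.zeros(resolution**3)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (frac[:, 0] if dx else 1 - frac[:, 0])
                    * (frac[:, 1] if dy else 1 - frac[:, 1])
                    * (frac[:, 2] if dz else 1 - frac[:, 2])
                )
                ix = np.clip(i0[:, 0] + dx, 0, resolution - 1)
                iy = np.clip(i0[:, 1] + dy, 0, resolution - 1)
                iz = np.clip(i0[:, 2] + dz, 0, resolution - 1)
                flat = (ix * resolution + iy) * resolution + iz
                np.add.at(acc, flat, w[:, None] * pc.normals)
                np.add.at(dens, flat, w)
    v_field = acc.reshape(resolution, resolution, resolution, 3)
    density = dens.reshape(resolution, resolution, resolution)
    sigma_vox = smoothing_m / spacing
    for c in range(3):
        v_field[..., c] = ndimage.gaussian_filter(v_field[..., c], sigma=sigma_vox)
    density = ndimage.gaussian_filter(density, sigma=sigma_vox)
    # density normalization: unit-magnitude transition regardless of local
    # sampling density, else sparsely seen patches get a weaker field and the
    # global iso level cuts them at an offset position
    occupied = density > 0.05 * density[
        tuple(np.clip(np.round(gc).astype(int), 0, resolution - 1).T)
    ].mean()
    v_field[occupied] /= density[occupied][:, None]
    v_field[~occupied] = 0.0

    div = np.zeros((resolution, resolution, resolution))
    div[1:-1, :, :] += (v_field[2:, :, :, 0] - v_field[:-2, :, :, 0]) / (2 * spacing[0])
    div[:, 1:-1, :] += (v_field[:, 2:, :, 1] - v_field[:, :-2, :, 1]) / (2 * spacing[1])
    div[:, :, 1:-1] += (v_field[:, :, 2:, 2] - v_field[:, :, :-2, 2]) / (2 * spacing[2])

    x = np.zeros((resolution, resolution, resolution))
    x[1:-1, 1:-1, 1:-1] = solve_poisson_dirichlet(div[1:-1, 1:-1, 1:-1], spacing)
    return ImplicitField(grid=x, origin=origin, spacing=spacing)


def poisson_reconstruct(
    pc: ColoredPointCloud,
    resolution: int = 128,
    padding: float = 0.1,
    smoothing_m: float = 0.005,
) -> TriangleMesh:
    """Reconstruct a watertight, consistently oriented mesh from oriented points.

    The iso level is the mean of the implicit function sampled at the input
    points (the convention of the classical method); the marching-cubes
    output is welded, cleaned of degenerate faces, and oriented so the
    enclosed volume is positive (outward normals).  Raises
    :class:`WatertightnessError` if the extracted surface is open.
    """
    fld = compute_indicator_field(pc, resolution, padding, smoothing_m)
    iso = float(np.mean(fld.sample(pc.points)))
    verts, faces, _, _ = marching_cubes(fld.grid, level=iso, spacing=tuple(fld.spacing))
    verts = verts + fld.origin
    mesh = _clean_mesh(verts, faces)
    if mesh_signed_volume(mesh) < 0:
        mesh = TriangleMesh(mesh.vertices, mesh.faces[:, ::-1])
    ok, boundary = check_watertight(mesh)
    if not ok:
        raise WatertightnessError(boundary)
    return mesh


def _clean_mesh(verts: np.ndarray, faces: np.ndarray) -> TriangleMesh:
    uniq, inverse = np.unique(verts, axis=0, return_inverse=True)
    faces = inverse[faces]
    good = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 2] != faces[:, 0])
    )
    return TriangleMesh(uniq, faces[good])


def mesh_surface_area(mesh: TriangleMesh) -> float:
    """Sum of triangle areas (m^2)."""
    a = mesh.vertices[mesh.faces[:, 0]]
    b = mesh.vertices[mesh.faces[:, 1]]
    c = mesh.vertices[mesh.faces[:, 2]]
    cross = np.cross(b - a, c - a)
    return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def mesh_signed_volume(mesh: TriangleMesh) -> float:
    a = mesh.vertices[mesh.faces[:, 0]]
    b = mesh.vertices[mesh.faces[:, 1]]
    c = mesh.vertices[mesh.faces[:, 2]]
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def mesh_volume(mesh: TriangleMesh) -> float:
    """Enclosed volume (m^3) by the divergence theorem.

    Requires a watertight, consistently oriented mesh — an open mesh would
    yield a silently wrong number, so it raises instead.
    """
    ok, boundary = check_watertight(mesh)
    if not ok:
        raise WatertightnessError(boundary)
    return abs(mesh_signed_volume(mesh))


def check_watertight(mesh: TriangleMesh) -> tuple[bool, int]:
    """Closed-manifold check: every undirected edge on exactly 2 faces with
    opposite winding.  Returns (is_watertight, boundary_edge_count)."""
    f = mesh.faces
    if len(f) == 0:
        return False, 0
    directed = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    und = np.sort(directed, axis=1)
    _, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    boundary = int((counts == 1).sum())
    if not np.all(counts == 2):
        return False, boundary
    # consistent orientation: each directed edge must be unique
    _, dcounts = np.unique(directed, axis=0, return_counts=True)
    if not np.all(dcounts == 1):
        return False, boundary
    return True, 0


def extract_traits(
    mesh: TriangleMesh, point_count: int = 0, timings: dict | None = None
) -> TraitReport:
    """Surface area + volume report for a reconstructed mesh."""
    ok, _ = check_watertight(mesh)
    return TraitReport(
        surface_area=mesh_surface_area(mesh),
        volume=mesh_volume(mesh) if ok else float("nan"),
        watertight=ok,
        point_count=point_count,
        vertex_count=len(mesh.vertices),
        face_count=len(mesh.faces),
        timings=timings or {},
    )
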