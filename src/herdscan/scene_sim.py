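"""Synthetic multi-camera RGB-D scene generator.

Stands in for a physical rig of time-of-flight cameras surrounding a target
(an animal in a chute, or a calibration object of known dimensions).  Scenes
are unions of textured geometric primitives; depth is rendered by analytic
ray casting, colour by unlit procedural albedo textures, and sensor defects
(Gaussian depth noise, flying pixels at depth discontinuities, interference
dropout) are injected by an explicit noise model.

Depth semantics: the stored value is z-depth — the projection of the first
ray hit onto the camera's optical axis — not ray range, so the pinhole
backprojection ``x=(u-cx)z/fx`` inverts rendering exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ParameterError
from .frames_io import CameraIntrinsics, Mask, RGBDFrame, RigidTransform

__all__ = [
    "Box",
    "Cylinder",
    "Sphere",
    "Primitive",
    "SceneSpec",
    "NoiseModel",
    "RigCamera",
    "CameraRig",
    "NoiseInfo",
    "make_ring_rig",
    "render_depth",
    "render_color",
    "render_frame",
    "ground_truth_mask",
    "apply_noise",
    "flying_pixel_candidates",
    "perturb_pose",
    "random_rotation",
    "default_intrinsics",
    "default_rig",
    "default_noise",
    "cylinder_primitive",
    "box_primitive",
    "validation_scene",
]

_EPS = 1e-9


# ---------------------------------------------------------------------------
# Shapes (local frames: box centred at origin, cylinder axis along local z)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Box:
    size: tuple[float, float, float]  # full extents (w, d, h), metres

    def __post_init__(self):
        if min(self.size) <= 0:
            raise ParameterError("box extents must be positive")

    @property
    def bounding_radius(self) -> float:
        return 0.5 * math.sqrt(sum(s * s for s in self.size))

    def surface_area(self) -> float:
        w, d, h = self.size
        return 2.0 * (w * d + w * h + d * h)

    def volume(self) -> float:
        w, d, h = self.size
        return w * d * h


@dataclass(frozen=True)
class Cylinder:
    radius: float
    length: float  # along local z

    def __post_init__(self):
        if self.radius <= 0 or self.length <= 0:
            raise ParameterError("cylinder dimensions must be positive")

    @property
    def bounding_radius(self) -> float:
        return math.hypot(self.radius, 0.5 * self.length)

    def surface_area(self) -> float:
        # closed cylinder: 2*pi*r*(r + h)
        return 2.0 * math.pi * self.radius * (self.radius + self.length)

    def volume(self) -> float:
        return math.pi * self.radius**2 * self.length


@dataclass(frozen=True)
class Sphere:
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ParameterError("sphere radius must be positive")

    @property
    def bounding_radius(self) -> float:
        return self.radius

    def surface_area(self) -> float:
        return 4.0 * math.pi * self.radius**2

    def volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius**3


@dataclass
class Primitive:
    """A posed, textured shape with a semantic role.

    ``texture`` is a dict: ``{"kind": "constant", "color": (r,g,b)}``,
    ``{"kind": "checker", "scale": m, "color_a": .., "color_b": ..}`` or
    ``{"kind": "noise", "scale": m, "octaves": k, "color_a": .., "color_b": ..}``.
    ``role`` is ``"target"`` (the scanned object) or ``"clutter"`` (chute
    bars, ground — anything segmentation must reject).
    """

    shape: Box | Cylinder | Sphere
    pose: RigidTransform = field(default_factory=RigidTransform.identity)
    texture: dict = field(default_factory=lambda: {"kind": "constant", "color": (0.7, 0.7, 0.7)})
    role: str = "target"

    def __post_init__(self):
        if self.role not in ("target", "clutter"):
            raise ParameterError(f"unknown primitive role {self.role!r}")


@dataclass
class SceneSpec:
    """Declarative scene: primitives + optional ground plane + seed."""

    primitives: list[Primitive]
    ground_plane: bool = False
    ground_height: float = 0.0  # world z of the plane
    ground_texture: dict = field(
        default_factory=lambda: {"kind": "checker", "scale": 0.25,
                                 "color_a": (0.35, 0.3, 0.25), "color_b": (0.2, 0.18, 0.15)}
    )
    rng_seed: int = 0

    def __post_init__(self):
        targets = [p for p in self.primitives if p.role == "target"]
        if not targets:
            raise ConfigurationError("scene must contain a target primitive")
        if not _connected(targets):
            raise ConfigurationError(
                "target primitives must form one connected group"
            )

    def target_indices(self) -> list[int]:
        return [i for i, p in enumerate(self.primitives) if p.role == "target"]


def _connected(prims: list[Primitive]) -> bool:
    # bounding-sphere overlap graph connectivity (conservative proxy)
    n = len(prims)
    if n == 1:
        return True
    centers = np.array([p.pose.translation for p in prims])
    radii = np.array([p.shape.bounding_radius for p in prims])
    seen = {0}
    frontier = [0]
    while frontier:
        i = frontier.pop()
        for j in range(n):
            if j in seen:
                continue
            if np.linalg.norm(centers[i] - centers[j]) <= radii[i] + radii[j]:
                seen.add(j)
                frontier.append(j)
    return len(seen) == n


@dataclass(frozen=True)
class NoiseModel:
    """ToF-style sensor defects, all reproducible from ``rng_seed``."""

    depth_sigma: float = 0.003  # m, per-pixel Gaussian
    flying_pixel_rate: float = 0.2  # fraction of discontinuity pixels replaced
    dropout_rate: float = 0.0  # interference mode: fraction invalidated
    discontinuity_threshold: float = 0.1  # m, neighbourhood spread that flags an edge
    rng_seed: int = 0

    def __post_init__(self):
        if self.depth_sigma < 0:
            raise ParameterError("depth_sigma must be >= 0")
        for r in (self.flying_pixel_rate, self.dropout_rate):
            if not 0.0 <= r <= 1.0:
                raise ParameterError("noise rates must lie in [0,1]")


@dataclass
class RigCamera:
    intrinsics: CameraIntrinsics
    pose: RigidTransform  # world-from-camera
    camera_id: int


@dataclass
class CameraRig:
    cameras: list[RigCamera]

    def __post_init__(self):
        ids = [c.camera_id for c in self.cameras]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("camera ids must be unique")
        if ids and min(ids) != 1:
            raise ConfigurationError("camera ids must be numbered from 1")

    def __len__(self):
        return len(self.cameras)

    def __iter__(self):
        return iter(self.cameras)


# ---------------------------------------------------------------------------
# Rig construction
# ---------------------------------------------------------------------------


def _look_at(position: np.ndarray, target: np.ndarray) -> RigidTransform:
    """World-from-camera pose looking from position at target (x right, y down, z forward)."""
    z = target - position
    nz = np.linalg.norm(z)
    if nz < _EPS:
        raise ConfigurationError("camera position coincides with look-at target")
    z = z / nz
    up = np.array([0.0, 0.0, 1.0])
    x = np.cross(z, up)
    nx = np.linalg.norm(x)
    if nx < 1e-6:  # looking straight up/down; pick arbitrary right vector
        x = np.array([1.0, 0.0, 0.0])
        x = x - z * (x @ z)
        nx = np.linalg.norm(x)
    x = x / nx
    y = np.cross(z, x)
    r = np.column_stack([x, y, z])
    return RigidTransform.from_rotation_translation(r, position)


def make_ring_rig(
    n_cameras: int,
    radius_m: float,
    height_m,
    intrinsics: CameraIntrinsics,
    look_at=(0.0, 0.0, 0.0),
) -> CameraRig:
    """Evenly spaced ring of cameras looking at a common point.

    Camera 1 sits at azimuth 0 (+x); ids increase counter-clockwise.
    ``height_m`` may be a scalar or a per-camera sequence — alternating
    elevations give the rig views of both the upper and lower surfaces of
    the target, the role the top/bottom placements of a physical frame play.
    """
    if n_cameras < 2:
        raise ConfigurationError("a rig needs at least 2 cameras")
    if radius_m <= 0:
        raise ConfigurationError("ring radius must be positive")
    heights = (
        [float(height_m)] * n_cameras
        if np.isscalar(height_m)
        else [float(h) for h in height_m]
    )
    if len(heights) != n_cameras:
        raise ConfigurationError("height_m sequence must match n_cameras")
    target = np.asarray(look_at, dtype=float)
    cams = []
    for i in range(n_cameras):
        phi = 2.0 * math.pi * i / n_cameras
        pos = np.array(
            [radius_m * math.cos(phi), radius_m * math.sin(phi), heights[i]]
        ) + np.array([target[0], target[1], 0.0])
        cams.append(RigCamera(intrinsics, _look_at(pos, target), camera_id=i + 1))
    return CameraRig(cams)


# ---------------------------------------------------------------------------
# Ray casting
# ---------------------------------------------------------------------------


def _camera_rays(cam: RigCamera) -> tuple[np.ndarray, np.ndarray]:
    """World-space ray origin and per-pixel directions scaled so the ray
    parameter equals z-depth in the camera frame."""
    k = cam.intrinsics
    u, v = np.meshgrid(np.arange(k.width), np.arange(k.height))
    d_cam = np.stack(
        [(u - k.cx) / k.fx, (v - k.cy) / k.fy, np.ones_like(u, dtype=float)], axis=-1
    )
    d_world = d_cam.reshape(-1, 3) @ cam.pose.rotation.T
    return cam.pose.translation, d_world


def _intersect_box(shape: Box, o: np.ndarray, d: np.ndarray) -> np.ndarray:
    h = np.asarray(shape.size) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (-h - o) / d
        t2 = (h - o) / d
    # where d ~ 0: slab test degenerates to inside check
    tiny = np.abs(d) < 1e-14
    lo = np.where(tiny, np.where(np.abs(o) <= h, -np.inf, np.inf), np.minimum(t1, t2))
    hi = np.where(tiny, np.where(np.abs(o) <= h, np.inf, -np.inf), np.maximum(t1, t2))
    near = lo.max(axis=1)
    far = hi.min(axis=1)
    s = np.where((near <= far) & (near > 1e-8), near, np.inf)
    return s


def _intersect_sphere(shape: Sphere, o: np.ndarray, d: np.ndarray) -> np.ndarray:
    a = np.einsum("ij,ij->i", d, d)
    b = 2.0 * d @ o
    c = o @ o - shape.radius**2
    disc = b * b - 4.0 * a * c
    s = np.full(len(d), np.inf)
    hit = disc >= 0
    sq = np.sqrt(np.where(hit, disc, 0.0))
    s1 = (-b - sq) / (2.0 * a)
    s2 = (-b + sq) / (2.0 * a)
    cand = np.where(s1 > 1e-8, s1, np.where(s2 > 1e-8, s2, np.inf))
    s[hit] = cand[hit]
    s[~hit] = np.inf
    return s


def _intersect_cylinder(shape: Cylinder, o: np.ndarray, d: np.ndarray) -> np.ndarray:
    r, hl = shape.radius, shape.length / 2.0
    n = len(d)
    best = np.full(n, np.inf)
    # lateral surface
    a = d[:, 0] ** 2 + d[:, 1] ** 2
    b = 2.0 * (o[0] * d[:, 0] + o[1] * d[:, 1])
    c = o[0] ** 2 + o[1] ** 2 - r * r
    disc = b * b - 4.0 * a * c
    ok = (disc >= 0) & (a > 1e-14)
    sq = np.sqrt(np.where(ok, disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        for sign in (-1.0, 1.0):
            s = (-b + sign * sq) / (2.0 * a)
            z = o[2] + s * d[:, 2]
            valid = ok & (s > 1e-8) & (np.abs(z) <= hl)
            best = np.where(valid & (s < best), s, best)
    # caps
    with np.errstate(divide="ignore", invalid="ignore"):
        for zc in (-hl, hl):
            s = (zc - o[2]) / d[:, 2]
            x = o[0] + s * d[:, 0]
            y = o[1] + s * d[:, 1]
            valid = (np.abs(d[:, 2]) > 1e-14) & (s > 1e-8) & (x * x + y * y <= r * r)
            best = np.where(valid & (s < best), s, best)
    return best


_INTERSECTORS = {Box: _intersect_box, Sphere: _intersect_sphere, Cylinder: _intersect_cylinder}

GROUND_INDEX = -1  # pseudo-primitive index for the ground plane


def _first_hit(
    scene: SceneSpec, cam: RigCamera, far: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel first-hit distance (z-depth) and primitive index (-2 = miss)."""
    origin, dirs = _camera_rays(cam)
    n = len(dirs)
    best = np.full(n, np.inf)
    idx = np.full(n, -2, dtype=np.int64)
    for i, prim in enumerate(scene.primitives):
        inv = prim.pose.inverse()
        o_l = inv.apply(origin)
        d_l = inv.rotate(dirs)
        s = _INTERSECTORS[type(prim.shape)](prim.shape, o_l, d_l)
        closer = s < best
        best = np.where(closer, s, best)
        idx = np.where(closer, i, idx)
    if scene.ground_plane:
        dz = dirs[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            s = (scene.ground_height - origin[2]) / dz
        s = np.where((np.abs(dz) > 1e-14) & (s > 1e-8), s, np.inf)
        closer = s < best
        best = np.where(closer, s, best)
        idx = np.where(closer, GROUND_INDEX, idx)
    beyond = best > far
    best = np.where(beyond, np.inf, best)
    idx = np.where(beyond, -2, idx)
    return best, idx


def render_depth(scene: SceneSpec, cam: RigCamera, far: float = 10.0) -> np.ndarray:
    """Render the z-depth map (metres); invalid pixels are 0."""
    k = cam.intrinsics
    s, _ = _first_hit(scene, cam, far)
    depth = np.where(np.isfinite(s), s, 0.0)
    return depth.reshape(k.height, k.width)


def ground_truth_mask(scene: SceneSpec, cam: RigCamera, far: float = 10.0) -> Mask:
    """True exactly where the first ray hit is a target-role primitive."""
    k = cam.intrinsics
    _, idx = _first_hit(scene, cam, far)
    targets = set(scene.target_indices())
    m = np.isin(idx, list(targets))
    return Mask(m.reshape(k.height, k.width), frame_id=cam.camera_id)


# ---------------------------------------------------------------------------
# Procedural textures (evaluated at local-frame surface points)
# ---------------------------------------------------------------------------


def _hash_noise(ix, iy, iz, seed: int) -> np.ndarray:
    """Deterministic lattice hash -> [0,1)."""
    with np.errstate(over="ignore"):
        h = (
            ix.astype(np.uint32) * np.uint32(73856093)
            ^ iy.astype(np.uint32) * np.uint32(19349663)
            ^ iz.astype(np.uint32) * np.uint32(83492791)
            ^ np.uint32(seed & 0xFFFFFFFF) * np.uint32(2654435761)
        )
        h ^= h >> np.uint32(13)
        h *= np.uint32(0x5BD1E995)
        h ^= h >> np.uint32(15)
    return h.astype(np.float64) / 4294967296.0


def _value_noise(p: np.ndarray, scale: float, seed: int) -> np.ndarray:
    """Trilinearly interpolated lattice value noise, values in [0,1]."""
    q = p / scale
    q0 = np.floor(q).astype(np.int64)
    f = q - q0
    f = f * f * (3.0 - 2.0 * f)  # smoothstep
    out = np.zeros(len(p))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (f[:, 0] if dx else 1.0 - f[:, 0])
                    * (f[:, 1] if dy else 1.0 - f[:, 1])
                    * (f[:, 2] if dz else 1.0 - f[:, 2])
                )
                out += w * _hash_noise(
                    q0[:, 0] + dx, q0[:, 1] + dy, q0[:, 2] + dz, seed
                )
    return out


def _eval_texture(tex: dict, pts: np.ndarray, seed: int) -> np.ndarray:
    kind = tex.get("kind", "constant")
    if kind == "constant":
        return np.tile(np.asarray(tex.get("color", (0.7, 0.7, 0.7)), float), (len(pts), 1))
    if kind == "checker":
        scale = float(tex.get("scale", 0.1))
        parity = np.floor(pts / scale).astype(np.int64).sum(axis=1) % 2
        ca = np.asarray(tex.get("color_a", (0.9, 0.9, 0.9)), float)
        cb = np.asarray(tex.get("color_b", (0.1, 0.1, 0.1)), float)
        return np.where(parity[:, None] == 0, ca, cb)
    if kind == "noise":
        scale = float(tex.get("scale", 0.05))
        octaves = int(tex.get("octaves", 3))
        val = np.zeros(len(pts))
        amp, norm = 1.0, 0.0
        for k in range(octaves):
            val += amp * _value_noise(pts, scale / (2**k), seed + 101 * k)
            norm += amp
            amp *= 0.5
        val = val / norm
        ca = np.asarray(tex.get("color_a", (0.95, 0.85, 0.6)), float)
        cb = np.asarray(tex.get("color_b", (0.2, 0.1, 0.05)), float)
        return ca[None, :] * val[:, None] + cb[None, :] * (1.0 - val[:, None])
    raise ParameterError(f"unknown texture kind {kind!r}")


def render_color(scene: SceneSpec, cam: RigCamera, far: float = 10.0) -> np.ndarray:
    """Render the unlit albedo colour image, deterministic given rng_seed."""
    k = cam.intrinsics
    origin, dirs = _camera_rays(cam)
    s, idx = _first_hit(scene, cam, far)
    color = np.zeros((len(dirs), 3))
    for i, prim in enumerate(scene.primitives):
        sel = idx == i
        if not sel.any():
            continue
        hit_w = origin + s[sel, None] * dirs[sel]
        hit_l = prim.pose.inverse().apply(hit_w)
        color[sel] = _eval_texture(prim.texture, hit_l, scene.rng_seed + 7919 * i)
    if scene.ground_plane:
        sel = idx == GROUND_INDEX
        if sel.any():
            hit_w = origin + s[sel, None] * dirs[sel]
            color[sel] = _eval_texture(scene.ground_texture, hit_w, scene.rng_seed - 1)
    return np.clip(color, 0.0, 1.0).reshape(k.height, k.width, 3)


def render_frame(scene: SceneSpec, cam: RigCamera, far: float = 10.0) -> RGBDFrame:
    """Render a noise-free RGB-D frame for one rig camera."""
    return RGBDFrame(
        color=render_color(scene, cam, far),
        depth=render_depth(scene, cam, far),
        intrinsics=cam.intrinsics,
        camera_id=cam.camera_id,
    )


# ---------------------------------------------------------------------------
# Sensor noise
# ---------------------------------------------------------------------------


def _neighbor_minmax(depth: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Min/max over the valid 8-neighbourhood of each pixel (self excluded)."""
    h, w = depth.shape
    valid = depth > 0
    mn = np.full((h, w), np.inf)
    mx = np.full((h, w), -np.inf)
    cnt = np.zeros((h, w), dtype=int)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dx == 0 and dy == 0:
                continue
            src = depth[
                max(0, -dy) : h - max(0, dy), max(0, -dx) : w - max(0, dx)
            ]
            vsrc = valid[
                max(0, -dy) : h - max(0, dy), max(0, -dx) : w - max(0, dx)
            ]
            dst = (slice(max(0, dy), h - max(0, -dy)), slice(max(0, dx), w - max(0, -dx)))
            mn[dst] = np.where(vsrc & (src < mn[dst]), src, mn[dst])
            mx[dst] = np.where(vsrc & (src > mx[dst]), src, mx[dst])
            cnt[dst] += vsrc
    return mn, mx, cnt


def flying_pixel_candidates(depth: np.ndarray, threshold: float) -> np.ndarray:
    """Valid pixels adjacent to a true depth edge.

    A pixel is a candidate when, along some axis of its 8-neighbourhood, the
    opposite-neighbour second difference ``|d(p+o) + d(p-o) - 2 d(p)|``
    exceeds ``threshold``.  Second differences vanish on smooth ramps
    (steeply viewed surfaces), so only genuine discontinuities — the
    mixed-pixel sites of a ToF sensor — are flagged.
    """
    h, w = depth.shape
    valid = depth > 0
    d = np.where(valid, depth, 0.0)
    cand = np.zeros((h, w), dtype=bool)
    for dy, dx in ((0, 1), (1, 0), (1, 1), (1, -1)):
        plus = np.zeros((h, w))
        minus = np.zeros((h, w))
        vplus = np.zeros((h, w), dtype=bool)
        vminus = np.zeros((h, w), dtype=bool)
        src_p = (slice(max(0, dy), h), slice(max(0, dx), w - max(0, -dx)))
        dst_p = (slice(0, h - max(0, dy)), slice(max(0, -dx), w - max(0, dx)))
        plus[dst_p] = d[src_p]
        vplus[dst_p] = valid[src_p]
        src_m = (slice(0, h - max(0, dy)), slice(max(0, -dx), w - max(0, dx)))
        dst_m = (slice(max(0, dy), h), slice(max(0, dx), w - max(0, -dx)))
        minus[dst_m] = d[src_m]
        vminus[dst_m] = valid[src_m]
        second = np.abs(plus + minus - 2.0 * d)
        cand |= vplus & vminus & (second > threshold)
    return valid & cand


@dataclass
class NoiseInfo:
    """Ground-truth bookkeeping of what :func:`apply_noise` injected."""

    flying_injected: np.ndarray  # bool map
    dropped: np.ndarray  # bool map


def apply_noise(
    frame: RGBDFrame, model: NoiseModel, return_info: bool = False
) -> RGBDFrame | tuple[RGBDFrame, NoiseInfo]:
    """Inject Gaussian depth noise, flying pixels, and interference dropout.

    Flying pixels: at valid pixels whose 8-neighbourhood depth spread exceeds
    ``model.discontinuity_threshold``, a Bernoulli(``flying_pixel_rate``)
    subset gets its depth replaced by a uniform draw between the nearest and
    farthest neighbouring depth — the mixed-pixel signature of ToF edges.
    Deterministic for a fixed ``model.rng_seed``.
    """
    rng = np.random.default_rng(model.rng_seed)
    depth = frame.depth.copy()
    valid = frame.valid
    # classify discontinuity pixels on the clean map
    cand = flying_pixel_candidates(np.where(valid, depth, 0.0), model.discontinuity_threshold)
    mn, mx, _ = _neighbor_minmax(np.where(valid, depth, 0.0))
    # Gaussian perturbation of every valid pixel
    if model.depth_sigma > 0:
        depth[valid] += rng.normal(0.0, model.depth_sigma, valid.sum())
    # flying pixel injection
    inject = cand & (rng.random(depth.shape) < model.flying_pixel_rate)
    if inject.any():
        lo = mn[inject]
        hi = mx[inject]
        depth[inject] = lo + rng.random(inject.sum()) * (hi - lo)
    # interference dropout
    dropped = valid & (rng.random(depth.shape) < model.dropout_rate)
    depth[dropped] = 0.0
    depth[~valid] = 0.0
    depth[depth < 0] = 0.0
    out = RGBDFrame(
        color=frame.color.copy(),
        depth=depth,
        intrinsics=frame.intrinsics,
        camera_id=frame.camera_id,
    )
    if return_info:
        return out, NoiseInfo(flying_injected=inject & ~dropped, dropped=dropped)
    return out


# ---------------------------------------------------------------------------
# Pose perturbation (stand-in for fiducial-based initial alignment error)
# ---------------------------------------------------------------------------


def random_rotation(angle_rad: float, rng: np.random.Generator) -> np.ndarray:
    """Rotation matrix of exactly ``angle_rad`` about a uniform random axis."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle_rad) * k + (1 - math.cos(angle_rad)) * (k @ k)


def perturb_pose(
    pose: RigidTransform, rot_deg: float, trans_m: float, seed: int
) -> RigidTransform:
    """Compose ``pose`` with a random rotation of exactly ``rot_deg`` degrees
    (uniform axis) and a random translation of exactly ``trans_m`` metres."""
    if rot_deg < 0 or trans_m < 0:
        raise ParameterError("perturbation magnitudes must be >= 0")
    rng = np.random.default_rng(seed)
    r = random_rotation(math.radians(rot_deg), rng)
    t = rng.normal(size=3)
    norm = np.linalg.norm(t)
    t = t / norm * trans_m if norm > 0 else np.zeros(3)
    delta = RigidTransform.from_rotation_translation(r, t)
    return delta @ pose


# ---------------------------------------------------------------------------
# Study conditions: default rig, noise, and validation objects
# ---------------------------------------------------------------------------
# The validation cylinder (r=0.088 m, h=1.233 m) and 0.5 m cube reproduce
# closed-form surface areas / volumes of 0.730 m^2 / 0.030 m^3 and
# 1.5 m^2 / 0.125 m^3 used in the known-object experiments.

CYLINDER_RADIUS = 0.088
CYLINDER_LENGTH = 1.233
DEFAULT_IMAGE = (320, 240)  # (width, height)
DEFAULT_RING_RADIUS = 1.9
DEFAULT_RING_HEIGHT = 0.55
DEFAULT_GROUND_Z = -1.2
DEPTH_BAND = (0.8, 3.0)  # default segmentation band: covers any target pose
# in the rig; scenes with a ground plane need a tighter scene-specific band


def default_intrinsics() -> CameraIntrinsics:
    w, h = DEFAULT_IMAGE
    return CameraIntrinsics(fx=260.0, fy=260.0, cx=(w - 1) / 2.0, cy=(h - 1) / 2.0,
                            width=w, height=h)


def default_rig(n_cameras: int = 10) -> CameraRig:
    """The study rig: a ring with alternating camera elevations so both the
    upper and lower surfaces of the target are observed."""
    heights = [
        DEFAULT_RING_HEIGHT if i % 2 == 0 else -DEFAULT_RING_HEIGHT
        for i in range(n_cameras)
    ]
    return make_ring_rig(
        n_cameras, DEFAULT_RING_RADIUS, heights, default_intrinsics()
    )


def default_noise(seed: int = 0) -> NoiseModel:
    return NoiseModel(rng_seed=seed)


def _target_texture(seed: int) -> dict:
    return {
        "kind": "noise",
        "scale": 0.06,
        "octaves": 3,
        "color_a": (0.95, 0.8, 0.55),
        "color_b": (0.25, 0.12, 0.06),
    }


def cylinder_primitive(pose: RigidTransform | None = None, seed: int = 0) -> Primitive:
    return Primitive(
        shape=Cylinder(CYLINDER_RADIUS, CYLINDER_LENGTH),
        pose=pose or RigidTransform.identity(),
        texture=_target_texture(seed),
        role="target",
    )


def box_primitive(side, pose: RigidTransform | None = None, seed: int = 0) -> Primitive:
    size = (side, side, side) if np.isscalar(side) else tuple(side)
    return Primitive(
        shape=Box(size),
        pose=pose or RigidTransform.identity(),
        texture=_target_texture(seed),
        role="target",
    )


def validation_scene(primitive: Primitive, seed: int = 0, ground: bool = False) -> SceneSpec:
    """A single known object suspended at the rig centre.

    The ground plane defaults to off: the known-object experiments measure
    the full closed surface, which requires the rig's low cameras to see the
    underside unobstructed.
    """
    return SceneSpec(
        primitives=[primitive],
        ground_plane=ground,
        ground_height=DEFAULT_GROUND_Z,
        rng_seed=seed,
    )
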