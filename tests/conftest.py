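"""Shared fixtures: analytic surface samplings, small rigs and scenes.

Everything is generated programmatically and seeded; heavy fixtures are
session-scoped so expensive renders happen once.
"""

import math

import numpy as np
import pytest

from herdscan import scene_sim as ss
from herdscan.frames_io import CameraIntrinsics, ColoredPointCloud, RigidTransform
from herdscan.scene_sim import _eval_texture


def cylinder_surface_sample(n: int, seed: int, texture: dict | None = None) -> ColoredPointCloud:
    """Uniform-by-area sampling of the validation cylinder with analytic
    outward normals and procedural texture colours."""
    rng = np.random.default_rng(seed)
    r, length = ss.CYLINDER_RADIUS, ss.CYLINDER_LENGTH
    a_side = 2 * math.pi * r * length
    a_cap = math.pi * r * r
    n_side = int(n * a_side / (a_side + 2 * a_cap))
    th = rng.uniform(0, 2 * math.pi, n_side)
    z = rng.uniform(-length / 2, length / 2, n_side)
    pts = [np.column_stack([r * np.cos(th), r * np.sin(th), z])]
    nrm = [np.column_stack([np.cos(th), np.sin(th), np.zeros(n_side)])]
    for sgn in (1.0, -1.0):
        m = (n - n_side) // 2
        rr = r * np.sqrt(rng.uniform(0, 1, m))
        tt = rng.uniform(0, 2 * math.pi, m)
        pts.append(
            np.column_stack([rr * np.cos(tt), rr * np.sin(tt), np.full(m, sgn * length / 2)])
        )
        nrm.append(np.tile([0.0, 0.0, sgn], (m, 1)))
    p = np.vstack(pts)
    texture = texture or {
        "kind": "noise",
        "scale": 0.06,
        "octaves": 3,
        "color_a": (0.95, 0.8, 0.55),
        "color_b": (0.25, 0.12, 0.06),
    }
    return ColoredPointCloud(p, _eval_texture(texture, p, 0), normals=np.vstack(nrm))


def sphere_surface_sample(n: int, radius: float, seed: int) -> ColoredPointCloud:
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return ColoredPointCloud(radius * v, np.full((n, 3), 0.5), normals=v)


def rotation_about(axis, angle_rad) -> np.ndarray:
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    k = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + math.sin(angle_rad) * k + (1 - math.cos(angle_rad)) * (k @ k)


def pose_error(t: RigidTransform, gt: RigidTransform) -> tuple[float, float]:
    """(rotation degrees, translation metres) between two poses."""
    d = t.inverse() @ gt
    ang = math.degrees(math.acos(np.clip((np.trace(d.rotation) - 1) / 2, -1, 1)))
    return ang, float(np.linalg.norm(d.translation))


@pytest.fixture(scope="session")
def small_intrinsics():
    return CameraIntrinsics(fx=40.0, fy=40.0, cx=23.5, cy=15.5, width=48, height=32)


@pytest.fixture(scope="session")
def cylinder_fixture_pair():
    """Two independent uniform samplings of the textured validation cylinder
    (full overlap) — the parameter-recovery fixture for registration."""
    return cylinder_surface_sample(8000, 1), cylinder_surface_sample(8000, 2)


@pytest.fixture(scope="session")
def sphere_cloud():
    return sphere_surface_sample(2000, 0.5, seed=0)


@pytest.fixture(scope="session")
def rendered_box_views():
    """Adjacent rendered views of the 0.5 m cube from the default rig, with
    per-view estimated and oriented normals (camera frames)."""
    from herdscan.pointcloud import backproject, estimate_normals, orient_normals

    rig = ss.default_rig()
    scene = ss.validation_scene(ss.box_primitive(0.5))
    out = []
    for k in (0, 1):
        cam = rig.cameras[k]
        fr = ss.render_frame(scene, cam)
        pc = backproject(fr, ss.ground_truth_mask(scene, cam))
        pc = estimate_normals(pc, 16)
        pc = orient_normals(pc, np.zeros(3))
        out.append((cam, pc))
    return out


@pytest.fixture(scope="session")
def unit_cube_mesh():
    """Closed unit cube (12 triangles, outward orientation) via trimesh."""
    import trimesh

    from herdscan.frames_io import TriangleMesh

    tm = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
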