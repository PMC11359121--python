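"""Simulator correctness: rig geometry, rendering vs a brute-force
ray-marching oracle, texture determinism, and the sensor noise model."""

import math
from dataclasses import replace

import numpy as np
import pytest

from herdscan import scene_sim as ss
from herdscan.errors import ConfigurationError, ParameterError
from herdscan.frames_io import CameraIntrinsics, RigidTransform
from herdscan.pointcloud import backproject
from herdscan.scene_sim import (
    Box,
    Cylinder,
    NoiseModel,
    Primitive,
    SceneSpec,
    Sphere,
    apply_noise,
    flying_pixel_candidates,
    ground_truth_mask,
    make_ring_rig,
    perturb_pose,
    render_color,
    render_depth,
    render_frame,
)

from conftest import pose_error, rotation_about


# ---------------------------------------------------------------------------
# Brute-force oracle: interval stepping + bisection on inside/outside tests
# ---------------------------------------------------------------------------


def _inside(scene: SceneSpec, pts: np.ndarray) -> np.ndarray:
    out = np.zeros(len(pts), dtype=bool)
    for prim in scene.primitives:
        local = prim.pose.inverse().apply(pts)
        s = prim.shape
        if isinstance(s, Box):
            h = np.asarray(s.size) / 2
            out |= np.all(np.abs(local) <= h, axis=1)
        elif isinstance(s, Sphere):
            out |= np.einsum("ij,ij->i", local, local) <= s.radius**2
        elif isinstance(s, Cylinder):
            out |= (local[:, 0] ** 2 + local[:, 1] ** 2 <= s.radius**2) & (
                np.abs(local[:, 2]) <= s.length / 2
            )
    return out


def oracle_depth(scene: SceneSpec, cam, far=6.0, step=2.5e-4):
    """March every pixel ray in small intervals; bisect the first
    outside->inside crossing to 1e-9.  Independent of the analytic
    intersection code (shares only the pinhole ray definition)."""
    k = cam.intrinsics
    u, v = np.meshgrid(np.arange(k.width), np.arange(k.height))
    d_cam = np.stack(
        [(u - k.cx) / k.fx, (v - k.cy) / k.fy, np.ones_like(u, float)], axis=-1
    ).reshape(-1, 3)
    dirs = d_cam @ cam.pose.rotation.T
    origin = cam.pose.translation
    n = len(dirs)
    ts = np.arange(step, far, step)
    lo = np.full(n, np.nan)
    hi = np.full(n, np.nan)
    found = np.zeros(n, dtype=bool)
    for t0, t1 in zip(ts[:-1], ts[1:]):
        todo = ~found
        if not todo.any():
            break
        pts = origin + t1 * dirs[todo]
        inside = _inside(scene, pts)
        idx = np.nonzero(todo)[0][inside]
        lo[idx], hi[idx] = t0, t1
        found[idx] = True
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        sel = found
        pts = origin + mid[sel, None] * dirs[sel]
        inside = _inside(scene, pts)
        hi[sel] = np.where(inside, mid[sel], hi[sel])
        lo[sel] = np.where(inside, lo[sel], mid[sel])
    depth = np.where(found, 0.5 * (lo + hi), 0.0)
    return depth.reshape(k.height, k.width)


@pytest.fixture(scope="module")
def oracle_cam(small_intrinsics):
    pos = np.array([1.2, 0.3, 0.4])
    rig = make_ring_rig(2, 1.0, 0.0, small_intrinsics)
    cam = rig.cameras[0]
    return replace(cam, pose=_look_at_from(pos))


def _look_at_from(pos):
    from herdscan.scene_sim import _look_at

    return _look_at(np.asarray(pos, float), np.zeros(3))


class TestRingRig:
    def test_four_camera_geometry(self, small_intrinsics):
        rig = make_ring_rig(4, 2.0, 0.0, small_intrinsics)
        centers = np.array([c.pose.translation for c in rig])
        assert np.allclose(np.linalg.norm(centers, axis=1), 2.0)
        for i in range(4):
            cosang = centers[i] @ centers[(i + 1) % 4] / 4.0
            assert cosang == pytest.approx(0.0, abs=1e-12)  # 90 deg apart

    def test_optical_axes_pass_through_origin(self, small_intrinsics):
        rig = make_ring_rig(5, 1.7, 0.4, small_intrinsics)
        for cam in rig:
            c = cam.pose.translation
            z = cam.pose.rotation[:, 2]  # optical axis in world
            # distance from origin to the line c + t z
            d = np.linalg.norm(c - (c @ z) * z)
            assert d < 1e-9

    def test_ten_camera_default_rig(self):
        rig = ss.default_rig()
        assert len(rig) == 10
        assert [c.camera_id for c in rig] == list(range(1, 11))

    def test_too_few_cameras(self, small_intrinsics):
        with pytest.raises(ConfigurationError):
            make_ring_rig(1, 2.0, 0.0, small_intrinsics)


class TestRenderDepth:
    def test_frontal_plane_depth_exact(self, small_intrinsics):
        # thin box facing a camera on the +x axis at distance 2
        scene = SceneSpec(
            primitives=[Primitive(shape=Box((0.02, 2.0, 2.0)))], rng_seed=0
        )
        cam = replace(
            make_ring_rig(2, 2.01, 0.0, small_intrinsics).cameras[0],
        )
        depth = render_depth(scene, cam)
        covered = depth > 0
        assert covered.sum() > 100
        assert np.allclose(depth[covered], 2.0, atol=1e-9)

    def test_sphere_center_pixel_closed_form(self):
        intr = CameraIntrinsics(fx=40, fy=40, cx=24.0, cy=16.0, width=49, height=33)
        scene = SceneSpec(primitives=[Primitive(shape=Sphere(0.5))], rng_seed=0)
        cam = make_ring_rig(2, 3.0, 0.0, intr).cameras[0]
        depth = render_depth(scene, cam)
        # principal ray hits the sphere head-on: depth = d - r
        assert depth[16, 24] == pytest.approx(3.0 - 0.5, abs=1e-9)

    def test_matches_bruteforce_oracle_all_primitives(self, oracle_cam):
        scene = SceneSpec(
            primitives=[
                Primitive(shape=Sphere(0.25),
                          pose=RigidTransform.from_rotation_translation(np.eye(3), [0, 0.3, 0.1])),
                Primitive(shape=Box((0.3, 0.2, 0.4)),
                          pose=RigidTransform.from_rotation_translation(
                              rotation_about([0.2, 1, 0.5], 0.7), [0, -0.35, 0])),
                Primitive(shape=Cylinder(0.12, 0.5),
                          pose=RigidTransform.from_rotation_translation(
                              rotation_about([1, 0.1, 0], 1.1), [0.1, 0, -0.3])),
            ],
            rng_seed=0,
        )
        rendered = render_depth(scene, oracle_cam)
        oracle = oracle_depth(scene, oracle_cam)
        hit_r, hit_o = rendered > 0, oracle > 0
        # hit/miss maps agree everywhere at this step size
        assert (hit_r == hit_o).all()
        assert np.abs(rendered[hit_r] - oracle[hit_r]).max() < 1e-6

    def test_empty_view_is_all_invalid(self, small_intrinsics):
        scene = SceneSpec(primitives=[Primitive(shape=Sphere(0.1))], rng_seed=0)
        cam = make_ring_rig(2, 2.0, 0.0, small_intrinsics).cameras[0]
        # look away from the object
        away = replace(cam, pose=_look_at_from([-2.0, 0, 0]) @ RigidTransform.from_rotation_translation(rotation_about([0, 1, 0], math.pi), [0, 0, 0]))
        assert (render_depth(scene, away) == 0).all()


class TestRenderColor:
    def test_constant_texture_single_color(self, small_intrinsics):
        scene = SceneSpec(
            primitives=[Primitive(shape=Sphere(0.5),
                                  texture={"kind": "constant", "color": (0.2, 0.4, 0.6)})],
            rng_seed=0,
        )
        cam = make_ring_rig(2, 2.0, 0.0, small_intrinsics).cameras[0]
        color = render_color(scene, cam)
        depth = render_depth(scene, cam)
        hit = depth > 0
        assert np.allclose(color[hit], (0.2, 0.4, 0.6))
        assert np.allclose(color[~hit], 0.0)

    def test_checker_plane_two_alternating_colors(self, small_intrinsics):
        scene = SceneSpec(
            primitives=[Primitive(
                shape=Box((4.0, 4.0, 0.02)),
                pose=RigidTransform.from_rotation_translation(
                    rotation_about([0, 1, 0], math.pi / 2), [0, 0, 0]),
                texture={"kind": "checker", "scale": 0.5,
                         "color_a": (1, 1, 1), "color_b": (0, 0, 0)})],
            rng_seed=0,
        )
        cam = make_ring_rig(2, 2.0, 0.0, small_intrinsics).cameras[0]
        color = render_color(scene, cam)
        hit = render_depth(scene, cam) > 0
        vals = np.unique(np.round(color[hit], 6), axis=0)
        assert len(vals) == 2
        # both colors well represented
        whites = (color[hit][:, 0] > 0.5).mean()
        assert 0.2 < whites < 0.8

    def test_same_seed_bit_identical(self, small_intrinsics):
        scene = ss.validation_scene(ss.cylinder_primitive(), seed=7)
        cam = make_ring_rig(4, 1.9, 0.5, small_intrinsics).cameras[1]
        a = render_color(scene, cam)
        b = render_color(scene, cam)
        assert (a == b).all()

    def test_texture_gradient_covers_target(self):
        # the photometric ICP term needs spatial intensity gradient on most
        # of the target surface
        scene = ss.validation_scene(ss.cylinder_primitive())
        cam = ss.default_rig().cameras[0]
        fr = render_frame(scene, cam)
        mask = ground_truth_mask(scene, cam).values
        inten = fr.color.mean(axis=2)
        gy, gx = np.gradient(inten)
        grad = np.hypot(gx, gy)
        interior = mask & np.roll(mask, 1, 0) & np.roll(mask, -1, 0) \
            & np.roll(mask, 1, 1) & np.roll(mask, -1, 1)
        frac = (grad[interior] > 1e-4).mean()
        assert frac >= 0.5


class TestGroundTruthMask:
    def test_no_clutter_mask_equals_valid(self, small_intrinsics):
        scene = ss.validation_scene(ss.box_primitive(0.5))
        cam = make_ring_rig(4, 1.9, 0.5, small_intrinsics).cameras[0]
        mask = ground_truth_mask(scene, cam)
        depth = render_depth(scene, cam)
        assert (mask.values == (depth > 0)).all()

    def test_occluding_bar_pixels_excluded(self, small_intrinsics):
        bar = Primitive(
            shape=Box((0.05, 3.0, 0.05)),
            pose=RigidTransform.from_rotation_translation(np.eye(3), [0.6, 0, 0]),
            role="clutter",
        )
        scene = SceneSpec(primitives=[ss.box_primitive(0.5), bar], rng_seed=0)
        cam = make_ring_rig(4, 1.9, 0.0, small_intrinsics).cameras[0]
        mask = ground_truth_mask(scene, cam)
        depth = render_depth(scene, cam)
        assert mask.values.sum() > 0
        bar_pixels = (depth > 0) & ~mask.values
        assert bar_pixels.sum() > 0  # the bar carves pixels out of the mask

    def test_mask_matches_oracle_first_hit_role(self, oracle_cam):
        target = Primitive(shape=Sphere(0.3))
        clutter = Primitive(
            shape=Box((0.1, 0.8, 0.8)),
            pose=RigidTransform.from_rotation_translation(np.eye(3), [0.6, 0.2, 0.1]),
            role="clutter",
        )
        scene = SceneSpec(primitives=[target, clutter], rng_seed=0)
        mask = ground_truth_mask(scene, oracle_cam).values
        # oracle: march, find first hit, test membership of the hit point
        depth = oracle_depth(scene, oracle_cam)
        k = oracle_cam.intrinsics
        u, v = np.meshgrid(np.arange(k.width), np.arange(k.height))
        d_cam = np.stack([(u - k.cx) / k.fx, (v - k.cy) / k.fy,
                          np.ones_like(u, float)], axis=-1).reshape(-1, 3)
        dirs = d_cam @ oracle_cam.pose.rotation.T
        hits = oracle_cam.pose.translation + depth.reshape(-1, 1) * dirs
        only_target = SceneSpec(primitives=[target], rng_seed=0)
        # nudge slightly inside along the ray to make the inside test robust
        probe = hits + 1e-7 * dirs
        on_target = _inside(only_target, probe) & (depth.reshape(-1) > 0)
        assert (mask.reshape(-1) == on_target).all()


class TestApplyNoise:
    def _frame(self, small_intrinsics):
        scene = SceneSpec(
            primitives=[ss.box_primitive(0.5)],
            ground_plane=True,
            ground_height=ss.DEFAULT_GROUND_Z,
            rng_seed=0,
        )
        cam = make_ring_rig(4, 1.9, 0.55, small_intrinsics).cameras[0]
        return render_frame(scene, cam)

    def test_zero_noise_is_identity(self, small_intrinsics):
        fr = self._frame(small_intrinsics)
        model = NoiseModel(depth_sigma=0, flying_pixel_rate=0, dropout_rate=0)
        out = apply_noise(fr, model)
        assert (out.depth == fr.depth).all()
        assert (out.color == fr.color).all()

    def test_dropout_binomial_bound(self):
        intr = CameraIntrinsics(fx=80, fy=80, cx=49.5, cy=49.5, width=100, height=100)
        frame = ss.RGBDFrame(
            color=np.zeros((100, 100, 3)), depth=np.full((100, 100), 2.0),
            intrinsics=intr,
        )
        model = NoiseModel(depth_sigma=0, flying_pixel_rate=0, dropout_rate=0.5,
                           rng_seed=5)
        out = apply_noise(frame, model)
        # 10,000 valid pixels, p=0.5: 3 sigma = 150
        assert abs(out.valid.sum() - 5000) <= 150

    def test_flying_count_matches_candidates_times_rate(self, small_intrinsics):
        fr = self._frame(small_intrinsics)
        cand = flying_pixel_candidates(fr.depth, 0.1).sum()
        assert cand > 30
        model = NoiseModel(depth_sigma=0, flying_pixel_rate=0.5, dropout_rate=0,
                           rng_seed=9)
        _, info = apply_noise(fr, model, return_info=True)
        n = info.flying_injected.sum()
        sd = math.sqrt(cand * 0.25)
        assert abs(n - 0.5 * cand) <= 3 * sd

    def test_injected_depths_between_neighbors(self, small_intrinsics):
        fr = self._frame(small_intrinsics)
        model = NoiseModel(depth_sigma=0, flying_pixel_rate=1.0, dropout_rate=0,
                           rng_seed=2)
        out, info = apply_noise(fr, model, return_info=True)
        inj = info.flying_injected
        lo, hi = fr.depth[fr.valid].min(), fr.depth[fr.valid].max()
        assert inj.sum() > 0
        assert (out.depth[inj] >= lo - 1e-12).all()
        assert (out.depth[inj] <= hi + 1e-12).all()

    def test_deterministic_per_seed(self, small_intrinsics):
        fr = self._frame(small_intrinsics)
        model = NoiseModel(rng_seed=123)
        a = apply_noise(fr, model)
        b = apply_noise(fr, model)
        assert (a.depth == b.depth).all()

    def test_rates_validated(self):
        with pytest.raises(ParameterError):
            NoiseModel(flying_pixel_rate=1.5)
        with pytest.raises(ParameterError):
            NoiseModel(depth_sigma=-1)


class TestPerturbPose:
    def test_zero_perturbation_is_identity(self):
        t = RigidTransform.from_rotation_translation(
            rotation_about([1, 2, 3], 0.5), [0.1, 0.2, 0.3]
        )
        out = perturb_pose(t, 0.0, 0.0, seed=0)
        assert np.allclose(out.matrix, t.matrix, atol=1e-12)

    @pytest.mark.parametrize("rot_deg,trans_m", [(3.0, 0.0), (0.0, 0.05), (7.5, 0.02)])
    def test_exact_magnitudes(self, rot_deg, trans_m):
        t = RigidTransform.identity()
        out = perturb_pose(t, rot_deg, trans_m, seed=4)
        ang, _ = pose_error(out, t)
        assert ang == pytest.approx(rot_deg, abs=1e-9)
        delta = out.matrix[:3, 3]
        assert np.linalg.norm(delta) == pytest.approx(trans_m, abs=1e-12)

    def test_same_seed_same_perturbation(self):
        t = RigidTransform.identity()
        a = perturb_pose(t, 2.0, 0.02, seed=11)
        b = perturb_pose(t, 2.0, 0.02, seed=11)
        assert (a.matrix == b.matrix).all()


class TestSceneSpecValidation:
    def test_needs_a_target(self):
        with pytest.raises(ConfigurationError):
            SceneSpec(primitives=[Primitive(shape=Sphere(0.1), role="clutter")])

    def test_disconnected_targets_rejected(self):
        far = RigidTransform.from_rotation_translation(np.eye(3), [5.0, 0, 0])
        with pytest.raises(ConfigurationError):
            SceneSpec(primitives=[
                Primitive(shape=Sphere(0.1)),
                Primitive(shape=Sphere(0.1), pose=far),
            ])


def test_backprojected_noise_free_points_lie_on_surface(small_intrinsics):
    """Loop closure: render -> backproject -> transform by GT extrinsics
    lands every point on the analytic primitive surface."""
    scene = ss.validation_scene(ss.cylinder_primitive())
    rig = make_ring_rig(4, 1.9, 0.5, small_intrinsics)
    r, hl = ss.CYLINDER_RADIUS, ss.CYLINDER_LENGTH / 2
    for cam in rig:
        fr = render_frame(scene, cam)
        pc = backproject(fr, ground_truth_mask(scene, cam))
        w = cam.pose.apply(pc.points)
        rad = np.hypot(w[:, 0], w[:, 1])
        on_side = np.abs(rad - r) < 1e-6
        on_cap = (np.abs(np.abs(w[:, 2]) - hl) < 1e-6) & (rad <= r + 1e-6)
        assert (on_side | on_cap).all()
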