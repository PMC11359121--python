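"""End-to-end scan orchestration: frames -> filtered, segmented clouds ->
registered merge -> cleaned cloud -> watertight mesh -> surface area/volume.

The stages mirror the scanning software pipeline of the physical rig:
flying-pixel filtering, per-frame segmentation, masked backprojection,
pairwise multi-scale colored ICP chained into camera 1's frame, a merge
downsample, DBSCAN cluster cleanup, Poisson reconstruction and trait
extraction.  Every stage is seeded and the whole run is deterministic for a
fixed configuration and seed.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import stats as sp_stats

from . import scene_sim
from .depth_filter import FlyingPixelParams, flying_pixel_filter
from .errors import ConfigurationError, HerdscanError, StageError
from .frames_io import (
    ColoredPointCloud,
    Mask,
    RGBDFrame,
    RigidTransform,
    read_frame,
    write_mesh,
    write_pointcloud,
)
from .meshing_traits import TraitReport, extract_traits, poisson_reconstruct
from .pointcloud import (
    backproject,
    dbscan_largest_cluster,
    estimate_normals,
    orient_normals,
)
from .registration import (
    RegistrationParams,
    colored_icp_multiscale,
    merge_registered,
    pairwise_chain,
)
from .segmentation import geometric_segmenter

__all__ = [
    "PipelineConfig",
    "ScanResult",
    "SuiteReport",
    "scan_frames",
    "run_scan",
    "simulate_views",
    "perturbed_guesses",
    "simulate_and_scan",
    "run_known_object_suite",
    "ring_pair_edges",
]


@dataclass
class PipelineConfig:
    """Every tunable of the scan pipeline with its default.

    Defaults reflect the synthetic study conditions: 160x120 frames from a
    10-camera ring, 3 mm depth noise, and a 128^3 reconstruction grid.
    """

    use_depth_filter: bool = True
    filter_params: FlyingPixelParams = field(default_factory=FlyingPixelParams)
    depth_band: tuple = scene_sim.DEPTH_BAND  # geometric segmenter band, m
    min_component_px: int = 50
    normals_k: int = 16
    registration: RegistrationParams = field(default_factory=RegistrationParams)
    merge_voxel: float = 0.005  # m
    cleanup_eps: float | None = None  # default 5 * merge_voxel
    cleanup_min_pts: int = 10
    mesh_resolution: int = 128
    mesh_smoothing_m: float = 0.005
    perturb_rot_deg: float = 2.0  # initial-alignment error stand-in
    perturb_trans_m: float = 0.02
    seed: int = 0

    @property
    def eps(self) -> float:
        return self.cleanup_eps if self.cleanup_eps is not None else 5.0 * self.merge_voxel


@dataclass
class ScanResult:
    merged_cloud: ColoredPointCloud
    cleaned_cloud: ColoredPointCloud
    mesh: object  # TriangleMesh
    report: TraitReport
    poses: dict  # camera_id -> world-from-camera (camera 1 frame)
    logs: list = field(default_factory=list)
    view_clouds: dict = field(default_factory=dict)  # masked, per camera
    unmasked_clouds: dict = field(default_factory=dict)


def ring_pair_edges(camera_ids: list[int]) -> list[tuple[int, int]]:
    """Adjacent-camera registration pairs as a two-armed tree rooted at the
    first id, walking the ring both ways (halves the chain length of a
    single arm)."""
    ids = sorted(camera_ids)
    n = len(ids)
    half = n // 2
    edges = [(ids[k], ids[k + 1]) for k in range(half)]
    back = [ids[0]] + ids[:half:-1]
    edges += [(back[k], back[k + 1]) for k in range(len(back) - 1)]
    return edges


def scan_frames(
    frames: list[RGBDFrame],
    initial_guesses: dict[int, RigidTransform],
    config: PipelineConfig = PipelineConfig(),
    masks: dict[int, Mask] | None = None,
) -> ScanResult:
    """Run the full pipeline on in-memory frames.

    ``initial_guesses`` are approximate world-from-camera poses (from
    fiducial calibration or the simulator's perturbed ground truth) used
    only to initialize pairwise ICP.  ``masks`` optionally overrides the
    geometric segmenter per camera.
    """
    if len(frames) < 2:
        raise ConfigurationError("need at least 2 frames to scan")
    logs: list[dict] = []
    t_start = time.perf_counter()

    def _stage(name):
        logs.append({"stage": name, "t": time.perf_counter() - t_start})

    try:
        view_clouds: dict[int, ColoredPointCloud] = {}
        unmasked: dict[int, ColoredPointCloud] = {}
        for fr in frames:
            cid = fr.camera_id
            n_before = int(fr.valid.sum())
            if config.use_depth_filter:
                depth = flying_pixel_filter(fr.depth, config.filter_params)
                fr = RGBDFrame(fr.color, depth, fr.intrinsics, cid)
            n_after = int(fr.valid.sum())
            if masks is not None and cid in masks:
                mask = masks[cid]
            else:
                mask = geometric_segmenter(fr, config.depth_band, config.min_component_px)
            unmasked[cid] = backproject(fr)
            pc = backproject(fr, mask)
            if len(pc) < config.normals_k:
                raise HerdscanError(
                    f"camera {cid}: only {len(pc)} masked points"
                )
            pc = estimate_normals(pc, config.normals_k)
            pc = orient_normals(pc, np.zeros(3))  # camera centre in its own frame
            view_clouds[cid] = pc
            logs.append(
                {
                    "stage": "per_view",
                    "camera_id": cid,
                    "valid_before_filter": n_before,
                    "valid_after_filter": n_after,
                    "masked_points": len(pc),
                }
            )
        _stage("views_done")
    except HerdscanError as exc:
        raise StageError("filter/segment/backproject", exc) from exc

    try:
        ids = sorted(view_clouds)
        pair_results = []
        for i, j in ring_pair_edges(ids):
            t0 = initial_guesses[i].inverse() @ initial_guesses[j]
            res = colored_icp_multiscale(
                view_clouds[j], view_clouds[i], t0, config.registration
            )
            pair_results.append((i, j, res))
            logs.append(
                {
                    "stage": "register_pair",
                    "pair": (i, j),
                    "rmse": res.inlier_rmse,
                    "correspondences": res.correspondence_count,
                }
            )
        poses = pairwise_chain(pair_results, reference_id=ids[0])
        _stage("registration_done")
    except HerdscanError as exc:
        raise StageError("registration", exc) from exc

    try:
        merged = merge_registered(
            [(cid, view_clouds[cid]) for cid in ids], poses, config.merge_voxel
        )
        cleaned = dbscan_largest_cluster(merged, config.eps, config.cleanup_min_pts)
        _stage("merge_cleanup_done")
    except HerdscanError as exc:
        raise StageError("merge/cleanup", exc) from exc

    try:
        mesh = poisson_reconstruct(
            cleaned,
            resolution=config.mesh_resolution,
            smoothing_m=config.mesh_smoothing_m,
        )
        report = extract_traits(mesh, point_count=len(cleaned))
        report.timings = {"total": time.perf_counter() - t_start}
        _stage("meshing_done")
    except HerdscanError as exc:
        raise StageError("meshing", exc) from exc

    return ScanResult(
        merged_cloud=merged,
        cleaned_cloud=cleaned,
        mesh=mesh,
        report=report,
        poses=poses,
        logs=logs,
        view_clouds=view_clouds,
        unmasked_clouds=unmasked,
    )


# ---------------------------------------------------------------------------
# Manifest-driven entry point (used by the CLI)
# ---------------------------------------------------------------------------


def run_scan(
    manifest_path,
    config: PipelineConfig = PipelineConfig(),
    out_dir=None,
    keep_intermediates: bool = False,
) -> ScanResult:
    """Scan from a rig manifest on disk (see the simulator's output layout).

    The manifest is a JSON document with a ``cameras`` list; each entry has
    ``camera_id``, paths to ``color``/``depth``/``intrinsics`` files and a
    row-major 4x4 ``extrinsics_guess``.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        doc = json.load(fh)
    base = manifest_path.parent
    frames = []
    guesses = {}
    for cam in doc.get("cameras", []):
        cid = int(cam["camera_id"])
        frames.append(
            read_frame(
                base / cam["color"], base / cam["depth"], base / cam["intrinsics"], cid
            )
        )
        guesses[cid] = RigidTransform(
            np.asarray(cam["extrinsics_guess"], dtype=float).reshape(4, 4)
        )
    result = scan_frames(frames, guesses, config)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_mesh(result.mesh, out_dir / "mesh.ply")
        with open(out_dir / "traits.json", "w") as fh:
            json.dump(result.report.to_dict(), fh, indent=1)
        if keep_intermediates:
            write_pointcloud(result.merged_cloud, out_dir / "merged.ply")
            write_pointcloud(result.cleaned_cloud, out_dir / "cleaned.ply")
            for cid, pc in result.unmasked_clouds.items():
                write_pointcloud(pc, out_dir / f"unmasked_{cid:02d}.ply")
    return result


# ---------------------------------------------------------------------------
# Simulator-backed experiments
# ---------------------------------------------------------------------------


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def simulate_views(
    scene: scene_sim.SceneSpec,
    rig: scene_sim.CameraRig,
    noise: scene_sim.NoiseModel | None,
    seed: int = 0,
) -> tuple[list[RGBDFrame], dict[int, Mask]]:
    """Render noisy frames plus ground-truth masks for every rig camera."""
    seeds = _spawn_seeds(seed, len(rig))
    frames, gt_masks = [], {}
    for cam, s in zip(rig, seeds):
        fr = scene_sim.render_frame(scene, cam)
        if noise is not None:
            fr = scene_sim.apply_noise(fr, replace(noise, rng_seed=s))
        frames.append(fr)
        gt_masks[cam.camera_id] = scene_sim.ground_truth_mask(scene, cam)
    return frames, gt_masks


def perturbed_guesses(
    rig: scene_sim.CameraRig, rot_deg: float, trans_m: float, seed: int
) -> dict[int, RigidTransform]:
    """Ground-truth extrinsics corrupted by a fixed-magnitude random pose
    error — the stand-in for fiducial-based initial calibration."""
    seeds = _spawn_seeds(seed, len(rig))
    return {
        cam.camera_id: scene_sim.perturb_pose(cam.pose, rot_deg, trans_m, s)
        for cam, s in zip(rig, seeds)
    }


def simulate_and_scan(
    scene: scene_sim.SceneSpec,
    rig: scene_sim.CameraRig | None = None,
    noise: scene_sim.NoiseModel | None = None,
    config: PipelineConfig = PipelineConfig(),
    seed: int = 0,
) -> ScanResult:
    """Render a scene with the (default) rig, corrupt it with noise and
    initial-pose error, and run the full pipeline."""
    rig = rig or scene_sim.default_rig()
    s_noise, s_pose = _spawn_seeds(seed + 1, 2)
    frames, _ = simulate_views(scene, rig, noise, seed=s_noise)
    guesses = perturbed_guesses(
        rig, config.perturb_rot_deg, config.perturb_trans_m, s_pose
    )
    return scan_frames(frames, guesses, config)


@dataclass
class SuiteReport:
    """Regression of predicted vs analytic traits over a set of known objects."""

    object_names: list
    true_sa: np.ndarray
    true_volume: np.ndarray
    mean_sa: np.ndarray
    mean_volume: np.ndarray
    sa_slope: float
    sa_intercept: float
    sa_r2: float
    volume_slope: float
    volume_intercept: float
    volume_r2: float
    failures: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "objects": list(self.object_names),
            "true_surface_area_m2": self.true_sa.tolist(),
            "true_volume_m3": self.true_volume.tolist(),
            "mean_surface_area_m2": self.mean_sa.tolist(),
            "mean_volume_m3": self.mean_volume.tolist(),
            "surface_area": {
                "slope": self.sa_slope,
                "intercept": self.sa_intercept,
                "r2": self.sa_r2,
            },
            "volume": {
                "slope": self.volume_slope,
                "intercept": self.volume_intercept,
                "r2": self.volume_r2,
            },
            "failures": self.failures,
        }


def _analytic_traits(scene: scene_sim.SceneSpec) -> tuple[float, float]:
    targets = [p for p in scene.primitives if p.role == "target"]
    if len(targets) != 1:
        raise ConfigurationError(
            "known-object suite needs scenes with a single target primitive"
        )
    return targets[0].shape.surface_area(), targets[0].shape.volume()


def run_known_object_suite(
    scenes: list[tuple[str, scene_sim.SceneSpec]],
    reps: int = 10,
    seed: int = 0,
    config: PipelineConfig = PipelineConfig(),
    noise: scene_sim.NoiseModel | None = None,
) -> SuiteReport:
    """Scan each known object ``reps`` times under noise, average predicted
    traits per object, and regress predictions against analytic values.

    Failed scans are recorded and excluded; fewer than 3 surviving objects
    aborts the suite.
    """
    if len(scenes) < 3:
        raise ConfigurationError("suite needs at least 3 distinct objects")
    noise = noise or scene_sim.default_noise()
    seeds = _spawn_seeds(seed, len(scenes) * reps)
    names, t_sa, t_v, m_sa, m_v = [], [], [], [], []
    failures = []
    k = 0
    for name, scene in scenes:
        sa_true, v_true = _analytic_traits(scene)
        sas, vols = [], []
        for rep in range(reps):
            try:
                res = simulate_and_scan(scene, noise=noise, config=config, seed=seeds[k])
            except (HerdscanError, StageError) as exc:
                failures.append({"object": name, "rep": rep, "error": str(exc)})
            else:
                sas.append(res.report.surface_area)
                vols.append(res.report.volume)
            k += 1
        if sas:
            names.append(name)
            t_sa.append(sa_true)
            t_v.append(v_true)
            m_sa.append(float(np.mean(sas)))
            m_v.append(float(np.mean(vols)))
        else:
            failures.append({"object": name, "rep": "all", "error": "every scan failed"})
    if len(names) < 3:
        raise ConfigurationError(
            f"only {len(names)} objects scanned successfully; need >= 3"
        )
    sa_fit = sp_stats.linregress(t_sa, m_sa)
    v_fit = sp_stats.linregress(t_v, m_v)
    return SuiteReport(
        object_names=names,
        true_sa=np.array(t_sa),
        true_volume=np.array(t_v),
        mean_sa=np.array(m_sa),
        mean_volume=np.array(m_v),
        sa_slope=float(sa_fit.slope),
        sa_intercept=float(sa_fit.intercept),
        sa_r2=float(sa_fit.rvalue**2),
        volume_slope=float(v_fit.slope),
        volume_intercept=float(v_fit.intercept),
        volume_r2=float(v_fit.rvalue**2),
        failures=failures,
    )


def random_object_poses(
    n_poses: int, seed: int = 0, trans_range: float = 0.15
) -> list[RigidTransform]:
    """Uniformly random orientations with bounded random translations, for
    pose-invariance experiments (the object stays inside every camera's
    view for translations up to ~0.15 m in the default rig)."""
    rng = np.random.default_rng(seed)
    poses = []
    for _ in range(n_poses):
        angle = rng.uniform(0.0, np.pi)
        r = scene_sim.random_rotation(angle, rng)
        t = rng.uniform(-trans_range, trans_range, 3)
        poses.append(RigidTransform.from_rotation_translation(r, t))
    return poses


def default_suite_scenes(seed: int = 0) -> list[tuple[str, scene_sim.SceneSpec]]:
    """The four known validation objects: the cylinder and three boxes."""
    return [
        ("cylinder", scene_sim.validation_scene(scene_sim.cylinder_primitive(), seed=seed)),
        ("box_small", scene_sim.validation_scene(scene_sim.box_primitive(0.3), seed=seed + 1)),
        ("box_medium", scene_sim.validation_scene(scene_sim.box_primitive(0.4), seed=seed + 2)),
        ("box_large", scene_sim.validation_scene(scene_sim.box_primitive(0.5), seed=seed + 3)),
    ]
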