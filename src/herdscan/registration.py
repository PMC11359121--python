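"""Multi-scale colored ICP registration and pairwise chaining.

Pairs of per-camera point clouds are aligned by the colored variant of
iterative closest point: the estimated rigid motion T minimizes

    E(T) = (1 - delta) * E_C(T) + delta * E_G(T)

where the geometric term ``E_G = sum ((p - Tq) . n_p)^2`` is the classic
point-to-plane residual over the correspondence set K and the photometric
term ``E_C = sum (C_p(f(Tq)) - C(q))^2`` compares the source intensity with
the target's locally linearized intensity function on p's tangent plane
(``C_p(x) = I(p) + g_p . (x - p)`` with the precomputed tangent-plane
gradient ``g_p``; the projection f is absorbed because ``g_p . n_p = 0``).
Minimization is Gauss-Newton on an se(3) parametrization with step halving
to enforce descent, run coarse-to-fine over a voxel pyramid to widen the
convergence basin.  Pairwise results are chained into the reference
camera's (camera 1) world frame along a tree of pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    AmbiguityError,
    ConnectivityError,
    DegenerateCorrespondenceError,
    HerdscanError,
    ParameterError,
)
from .frames_io import ColoredPointCloud, RigidTransform
from .pointcloud import voxel_downsample

__all__ = [
    "RegistrationParams",
    "RegistrationResult",
    "precompute_color_gradients",
    "colored_icp_single_scale",
    "colored_icp_multiscale",
    "pairwise_chain",
    "merge_registered",
    "se3_exp",
    "residuals_and_jacobian",
]


@dataclass(frozen=True)
class RegistrationParams:
    """Weight, scale schedule and convergence tolerance for colored ICP.

    ``delta`` weights the geometric term (0.968 follows the colored-ICP
    literature); ``scales`` is a coarse-to-fine list of
    (voxel_size m, max_iterations, max_correspondence_distance m).  The
    finest scale should match the sensor's surface sampling density —
    stopping coarser leaves tangential slide on texture-symmetric surfaces.
    """

    delta: float = 0.968
    scales: tuple = (
        (0.04, 50, 0.12),
        (0.02, 30, 0.06),
        (0.01, 30, 0.03),
        (0.005, 30, 0.015),
    )
    convergence_tol: float = 1e-6

    def __post_init__(self):
        if not 0.0 <= self.delta <= 1.0:
            raise ParameterError("delta must lie in [0,1]")
        if not self.scales:
            raise ParameterError("scale schedule must be nonempty")
        voxels = [s[0] for s in self.scales]
        if any(b >= a for a, b in zip(voxels, voxels[1:])):
            raise ParameterError("voxel sizes must be strictly decreasing")


@dataclass
class RegistrationResult:
    transform: RigidTransform  # target-from-source
    final_objective: float
    inlier_rmse: float
    correspondence_count: int
    converged: bool
    # (objective before, objective after) per iteration, both evaluated on
    # that iteration's correspondence set: after <= before on accepted steps
    objective_history: list = field(default_factory=list)


def precompute_color_gradients(
    pc: ColoredPointCloud, k_neighbors: int = 16
) -> ColoredPointCloud:
    """Fit the tangent-plane intensity gradient g_p at every point.

    g_p is the least-squares solution of ``g . d_j = I_j - I_p`` over the
    neighbour offsets d_j projected onto p's tangent plane, constrained to
    ``g . n_p = 0`` by Tikhonov penalty along the normal; it linearizes the
    target's intensity field for the photometric ICP residual.
    """
    if pc.normals is None:
        raise HerdscanError("color gradients require normals")
    pts = pc.points
    n = len(pc)
    k = min(k_neighbors, n)
    intens = pc.intensity
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k)
    offsets = pts[idx] - pts[:, None, :]  # (N, k, 3)
    normals = pc.normals
    # project offsets onto tangent planes
    along = np.einsum("nkj,nj->nk", offsets, normals)
    proj = offsets - along[..., None] * normals[:, None, :]
    rhs_i = intens[idx] - intens[:, None]
    ata = np.einsum("nki,nkj->nij", proj, proj)
    scale = np.einsum("nii->n", ata) + 1e-12
    # penalty pinning the normal component to zero + small isotropic damping
    ata += (scale[:, None, None]) * np.einsum("ni,nj->nij", normals, normals)
    ata += (1e-6 * scale)[:, None, None] * np.eye(3)[None, :, :]
    atb = np.einsum("nki,nk->ni", proj, rhs_i)
    grads = np.linalg.solve(ata, atb[..., None])[..., 0]
    grads -= np.einsum("ni,ni->n", grads, normals)[:, None] * normals
    return ColoredPointCloud(
        points=pts.copy(),
        colors=pc.colors.copy(),
        normals=normals.copy(),
        color_gradients=grads,
    )


def se3_exp(xi: np.ndarray) -> RigidTransform:
    """Exponential of a 6-vector (omega, t): exact Rodrigues rotation, raw
    translation (first-order twist, adequate for damped Gauss-Newton steps)."""
    omega, t = xi[:3], xi[3:]
    theta = np.linalg.norm(omega)
    if theta < 1e-12:
        r = np.eye(3)
    else:
        a = omega / theta
        k = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
        r = np.eye(3) + np.sin(theta) * k + (1 - np.cos(theta)) * (k @ k)
    return RigidTransform.from_rotation_translation(r, t)


def residuals_and_jacobian(
    src_pts: np.ndarray,
    src_intens: np.ndarray,
    tgt_pts: np.ndarray,
    tgt_normals: np.ndarray,
    tgt_intens: np.ndarray,
    tgt_grads: np.ndarray,
    transform: np.ndarray,
    delta: float,
):
    """Stacked weighted residuals [r_G; r_C] and their Jacobian w.r.t. a
    left-multiplied se(3) perturbation (omega, t).

    For a correspondence (p, q): q' = T q,
    r_G = sqrt(delta) * (p - q') . n_p,
    r_C = sqrt(1-delta) * (I_p + g_p . (q' - p) - I_q).
    """
    q = src_pts @ transform[:3, :3].T + transform[:3, 3]
    rg = np.einsum("ij,ij->i", tgt_pts - q, tgt_normals)
    rc = tgt_intens + np.einsum("ij,ij->i", tgt_grads, q - tgt_pts) - src_intens
    wg, wc = np.sqrt(delta), np.sqrt(1.0 - delta)
    res = np.concatenate([wg * rg, wc * rc])
    # d q' = dtheta x q' + dt  =>  d r_G = -(q' x n).dtheta - n.dt
    jg = np.hstack([-np.cross(q, tgt_normals), -tgt_normals])
    jc = np.hstack([np.cross(q, tgt_grads), tgt_grads])
    jac = np.vstack([wg * jg, wc * jc])
    return res, jac, q


def _objective(res: np.ndarray) -> float:
    return float(res @ res)


_NORMAL_GATE_COS = 0.5  # reject pairs whose normals disagree by more than 60 deg


def colored_icp_single_scale(
    source: ColoredPointCloud,
    target: ColoredPointCloud,
    init: RigidTransform,
    delta: float = 0.968,
    max_corr_dist: float = 0.03,
    max_iter: int = 30,
    tol: float = 1e-6,
) -> RegistrationResult:
    """One scale of colored ICP (Gauss-Newton with step halving).

    Returns the target-from-source transform.  The objective evaluated on
    each iteration's correspondence set is non-increasing over accepted
    steps; iteration stops on relative objective change < ``tol``, on
    ``max_iter``, or when no descent step is found.  When the source carries
    normals, correspondences whose rotated source normal disagrees with the
    target normal by more than 60 degrees are rejected — partial view
    overlap otherwise lets front surfaces latch onto back surfaces.
    """
    if target.normals is None:
        raise HerdscanError("target must carry normals")
    if target.color_gradients is None:
        raise HerdscanError("target must carry color gradients (precompute them)")
    if not 0.0 <= delta <= 1.0:
        raise ParameterError("delta must lie in [0,1]")
    tree = cKDTree(target.points)
    t_mat = init.matrix.copy()
    src_intens_all = source.intensity
    tgt_intens_all = target.intensity
    converged = False
    history: list[float] = []
    n_corr = 0
    for _ in range(max_iter):
        q = source.points @ t_mat[:3, :3].T + t_mat[:3, 3]
        dist, j = tree.query(q, distance_upper_bound=max_corr_dist)
        matched = np.isfinite(dist)
        if source.normals is not None:
            rot_n = source.normals @ t_mat[:3, :3].T
            safe_j = np.where(matched, j, 0)
            agree = (
                np.einsum("ij,ij->i", rot_n, target.normals[safe_j])
                > _NORMAL_GATE_COS
            )
            matched = matched & agree
        n_corr = int(matched.sum())
        if n_corr < 6:
            raise DegenerateCorrespondenceError(
                f"only {n_corr} correspondences within {max_corr_dist} m"
            )
        si = np.nonzero(matched)[0]
        ti = j[matched]
        args = (
            source.points[si],
            src_intens_all[si],
            target.points[ti],
            target.normals[ti],
            tgt_intens_all[ti],
            target.color_gradients[ti],
        )
        res, jac, _ = residuals_and_jacobian(*args, t_mat, delta)
        obj = _objective(res)
        if not np.isfinite(obj):
            raise HerdscanError("registration objective is not finite")
        h = jac.T @ jac
        g = jac.T @ res
        try:
            xi = np.linalg.solve(h + 1e-12 * np.trace(h) * np.eye(6), -g)
        except np.linalg.LinAlgError as exc:
            raise DegenerateCorrespondenceError(str(exc)) from exc
        accepted = False
        new_obj = obj
        for halving in range(9):
            step = se3_exp(xi / (2.0**halving))
            cand = step.matrix @ t_mat
            res_c, _, _ = residuals_and_jacobian(*args, cand, delta)
            new_obj = _objective(res_c)
            if new_obj <= obj:
                t_mat = cand
                accepted = True
                break
        history.append((obj, new_obj if accepted else obj))
        if not accepted:
            converged = True
            break
        if abs(obj - new_obj) <= tol * max(obj, 1e-30):
            converged = True
            break
    # final bookkeeping on the converged transform
    q = source.points @ t_mat[:3, :3].T + t_mat[:3, 3]
    dist, j = tree.query(q, distance_upper_bound=max_corr_dist)
    matched = np.isfinite(dist)
    si = np.nonzero(matched)[0]
    ti = j[matched]
    res, _, _ = residuals_and_jacobian(
        source.points[si],
        src_intens_all[si],
        target.points[ti],
        target.normals[ti],
        tgt_intens_all[ti],
        target.color_gradients[ti],
        t_mat,
        delta,
    )
    rmse = float(np.sqrt(np.mean(dist[matched] ** 2))) if matched.any() else 0.0
    return RegistrationResult(
        transform=RigidTransform(t_mat),
        final_objective=_objective(res),
        inlier_rmse=rmse,
        correspondence_count=int(matched.sum()),
        converged=converged,
        objective_history=history,
    )


def colored_icp_multiscale(
    source: ColoredPointCloud,
    target: ColoredPointCloud,
    init: RigidTransform,
    params: RegistrationParams = RegistrationParams(),
) -> RegistrationResult:
    """Coarse-to-fine colored ICP over the voxel pyramid in ``params``.

    Each scale voxel-downsamples both clouds, re-estimates the target's
    tangent-plane colour gradients at that sampling density, and warm-starts
    from the previous scale's transform.
    """
    if target.normals is None:
        raise HerdscanError("target must carry normals")
    t = init
    result = None
    for voxel, max_iter, max_corr in params.scales:
        src_d = voxel_downsample(source, voxel)
        tgt_d = voxel_downsample(target, voxel)
        tgt_d = precompute_color_gradients(tgt_d)
        result = colored_icp_single_scale(
            src_d,
            tgt_d,
            t,
            delta=params.delta,
            max_corr_dist=max_corr,
            max_iter=max_iter,
            tol=params.convergence_tol,
        )
        t = result.transform
    return result


def pairwise_chain(
    pair_results: list[tuple[int, int, RegistrationResult]],
    reference_id: int = 1,
) -> dict[int, RigidTransform]:
    """Chain pairwise transforms into world-from-camera poses.

    A pair ``(i, j, result)`` carries the transform mapping camera-j
    coordinates into camera-i coordinates.  The reference camera defines the
    world frame (pose = identity); every other camera's world pose is the
    composition along its unique path.  The pair set must be a tree —
    cycles are rejected rather than averaged.
    """
    camera_ids = {reference_id}
    for i, j, _ in pair_results:
        camera_ids.update((i, j))
    poses: dict[int, RigidTransform] = {reference_id: RigidTransform.identity()}
    edges = list(pair_results)
    if len(edges) > len(camera_ids) - 1:
        raise AmbiguityError("pair graph contains a cycle; chaining is ambiguous")
    progress = True
    while edges and progress:
        progress = False
        remaining = []
        for i, j, res in edges:
            h_ij = res.transform if isinstance(res, RegistrationResult) else res
            if i in poses and j in poses:
                raise AmbiguityError(
                    f"pair ({i},{j}) closes a cycle; chaining is ambiguous"
                )
            if i in poses:
                poses[j] = poses[i] @ h_ij
                progress = True
            elif j in poses:
                poses[i] = poses[j] @ h_ij.inverse()
                progress = True
            else:
                remaining.append((i, j, res))
        edges = remaining
    missing = camera_ids - set(poses)
    if missing:
        raise ConnectivityError(
            f"cameras {sorted(missing)} are not connected to reference {reference_id}"
        )
    return poses


def merge_registered(
    clouds: list[tuple[int, ColoredPointCloud]],
    poses: dict[int, RigidTransform],
    merge_voxel: float = 0.005,
) -> ColoredPointCloud:
    """Transform every per-camera cloud into the world frame, concatenate,
    and consolidate with a merge-voxel downsample (normals rotated and
    re-averaged)."""
    parts = []
    for camera_id, pc in clouds:
        if camera_id not in poses:
            raise KeyError(f"no pose for camera {camera_id}")
        parts.append(pc.transformed(poses[camera_id]))
    merged = ColoredPointCloud(
        points=np.vstack([p.points for p in parts]),
        colors=np.vstack([p.colors for p in parts]),
        normals=np.vstack([p.normals for p in parts])
        if all(p.normals is not None for p in parts)
        else None,
        color_gradients=None,
    )
    return voxel_downsample(merged, merge_voxel)
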