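"""Point-cloud operations: backprojection, normals, downsampling, clustering.

These are the per-view and merged-cloud steps between segmentation and
surface reconstruction: valid depth pixels are backprojected through the
inverse pinhole model, surface normals are estimated from local covariance
and oriented toward the observing camera, clouds are voxel-downsampled for
the registration scale pyramid, and density clustering discards small stray
clusters before meshing.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

from .errors import DimensionError, EmptyClusterError, HerdscanError, InsufficientPointsError, ParameterError
from .frames_io import ColoredPointCloud, Mask, RGBDFrame

__all__ = [
    "backproject",
    "estimate_normals",
    "orient_normals",
    "voxel_downsample",
    "dbscan_labels",
    "dbscan_largest_cluster",
]


def backproject(frame: RGBDFrame, mask: Mask | None = None) -> ColoredPointCloud:
    """Backproject valid (and masked-in) pixels to a colored cloud.

    Each pixel (u, v) with depth z maps to
    ``x=(u-cx)z/fx, y=(v-cy)z/fy, z=z`` in the camera frame; points are
    emitted in row-major pixel order.
    """
    k = frame.intrinsics
    keep = frame.valid
    if mask is not None:
        if mask.values.shape != frame.depth.shape:
            raise DimensionError("mask shape does not match frame")
        keep = keep & mask.values
    v, u = np.nonzero(keep)
    z = frame.depth[v, u]
    x = (u - k.cx) * z / k.fx
    y = (v - k.cy) * z / k.fy
    return ColoredPointCloud(
        points=np.column_stack([x, y, z]), colors=frame.color[v, u]
    )


def estimate_normals(pc: ColoredPointCloud, k_neighbors: int = 16) -> ColoredPointCloud:
    """Per-point normal = least eigenvector of the k-NN covariance.

    Normals are unit length with unresolved sign; call
    :func:`orient_normals` afterwards.  Degenerate neighbourhoods (all
    collinear) raise.
    """
    n = len(pc)
    if k_neighbors < 3:
        raise ParameterError("k_neighbors must be >= 3")
    if n < k_neighbors:
        raise InsufficientPointsError(
            f"{n} points < k_neighbors={k_neighbors}"
        )
    tree = cKDTree(pc.points)
    _, idx = tree.query(pc.points, k=k_neighbors)
    nbrs = pc.points[idx]  # (N, k, 3)
    centered = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / k_neighbors
    w, v = np.linalg.eigh(cov)
    # eigenvalues ascending: column 0 is the surface normal direction
    normals = v[:, :, 0]
    # collinear neighbourhood: two vanishing eigenvalues
    scale = np.einsum("nii->n", cov)
    degenerate = (w[:, 1] <= 1e-12 * np.maximum(scale, 1e-30)) & (scale > 0)
    if degenerate.any():
        raise HerdscanError(
            f"{int(degenerate.sum())} points have collinear neighbourhoods; "
            "normals are undefined there"
        )
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = normals / np.maximum(norms, 1e-30)
    return ColoredPointCloud(
        points=pc.points.copy(),
        colors=pc.colors.copy(),
        normals=normals,
        color_gradients=None
        if pc.color_gradients is None
        else pc.color_gradients.copy(),
    )


def orient_normals(pc: ColoredPointCloud, camera_center) -> ColoredPointCloud:
    """Flip normals so each points toward the observing camera.

    Applied per source view (with that view's camera centre) before merging,
    which makes normals outward on surfaces seen from outside.
    """
    if pc.normals is None:
        raise HerdscanError("cloud has no normals to orient")
    c = np.asarray(camera_center, dtype=float)
    toward = c[None, :] - pc.points
    flip = np.einsum("ij,ij->i", toward, pc.normals) < 0
    normals = pc.normals.copy()
    normals[flip] *= -1.0
    return ColoredPointCloud(
        points=pc.points.copy(),
        colors=pc.colors.copy(),
        normals=normals,
        color_gradients=None
        if pc.color_gradients is None
        else pc.color_gradients.copy(),
    )


def voxel_downsample(pc: ColoredPointCloud, voxel_size: float) -> ColoredPointCloud:
    """One centroid point (points/colors/normals averaged) per occupied voxel."""
    if voxel_size <= 0:
        raise ParameterError("voxel_size must be positive")
    if len(pc) == 0:
        return pc
    keys = np.floor(pc.points / voxel_size).astype(np.int64)
    _, inverse, counts = np.unique(
        keys, axis=0, return_inverse=True, return_counts=True
    )
    m = len(counts)

    def _mean(arr):
        out = np.zeros((m, arr.shape[1]))
        np.add.at(out, inverse, arr)
        return out / counts[:, None]

    points = _mean(pc.points)
    colors = _mean(pc.colors)
    normals = None
    if pc.normals is not None:
        normals = _mean(pc.normals)
        norms = np.linalg.norm(normals, axis=1, keepdims=True)
        # opposing normals in one voxel can cancel; fall back to +z
        bad = norms[:, 0] < 1e-12
        normals[bad] = [0.0, 0.0, 1.0]
        norms[bad] = 1.0
        normals = normals / norms
    gradients = _mean(pc.color_gradients) if pc.color_gradients is not None else None
    return ColoredPointCloud(points=points, colors=colors, normals=normals,
                             color_gradients=gradients)


def dbscan_labels(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Full DBSCAN labelling: -1 for noise, 0..k-1 cluster ids.

    Border points reachable from several clusters join the cluster expanded
    first, with expansion order fixed by ascending point index — the
    labelling is therefore deterministic for a given point order.
    """
    if eps <= 0:
        raise ParameterError("eps must be positive")
    if min_pts < 1:
        raise ParameterError("min_pts must be >= 1")
    return DBSCAN(eps=eps, min_samples=min_pts).fit_predict(points)


def dbscan_largest_cluster(
    pc: ColoredPointCloud, eps: float, min_pts: int = 10
) -> ColoredPointCloud:
    """Keep only the largest DBSCAN cluster (small stray clusters are sensor
    artifacts or residual background)."""
    labels = dbscan_labels(pc.points, eps, min_pts)
    valid = labels >= 0
    if not valid.any():
        raise EmptyClusterError("DBSCAN labelled every point as noise")
    counts = np.bincount(labels[valid])
    keep = labels == int(np.argmax(counts))
    return ColoredPointCloud(
        points=pc.points[keep],
        colors=pc.colors[keep],
        normals=None if pc.normals is None else pc.normals[keep],
        color_gradients=None
        if pc.color_gradients is None
        else pc.color_gradients[keep],
    )
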