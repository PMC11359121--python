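"""Flying-pixel removal from metric depth maps.

Time-of-flight cameras report mixed depths at object boundaries ("flying
pixels") that land between the foreground and background surfaces.  The
filter keeps a valid pixel only if enough of its valid window neighbours
agree with it in depth; disagreeing pixels are invalidated, never smoothed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, ParameterError

__all__ = ["FlyingPixelParams", "flying_pixel_filter"]


@dataclass(frozen=True)
class FlyingPixelParams:
    """Neighbourhood-support filter parameters.

    A valid pixel survives iff at least ``min_support`` of its valid
    neighbours in the ``(2*window_radius+1)^2`` window (centre excluded) lie
    within the depth tolerance of it.  A valid pixel with no valid
    neighbours is removed (an isolated depth sample is itself an artifact).

    The tolerance at a pixel of depth d is
    ``depth_tolerance + relative_tolerance * d``: the absolute part covers
    sensor noise (3*sigma + 2 cm at the default 3 mm noise) while the
    depth-proportional part covers the growth of the legitimate per-pixel
    depth step on obliquely viewed surfaces (the pixel footprint scales with
    d, so a plane at grazing incidence steps several centimetres per pixel).
    Flying pixels bridge decimetre-scale discontinuities and stay far above
    both terms.
    """

    window_radius: int = 1
    depth_tolerance: float = 0.029  # m, absolute part
    relative_tolerance: float = 0.025  # m per metre of depth
    min_support: float = 0.5

    def __post_init__(self):
        if self.window_radius < 1:
            raise ParameterError("window_radius must be >= 1")
        if self.depth_tolerance <= 0:
            raise ParameterError("depth_tolerance must be positive")
        if self.relative_tolerance < 0:
            raise ParameterError("relative_tolerance must be >= 0")
        if not 0.0 < self.min_support <= 1.0:
            raise ParameterError("min_support must lie in (0, 1]")


def flying_pixel_filter(
    depth: np.ndarray, params: FlyingPixelParams = FlyingPixelParams()
) -> np.ndarray:
    """Invalidate unsupported depth pixels; supported depths pass unchanged.

    Parameters
    ----------
    depth:
        (H, W) metric depth; non-positive or NaN marks invalid pixels.

    Returns
    -------
    (H, W) array equal to the input on kept pixels and 0 elsewhere.
    """
    depth = np.asarray(depth, dtype=float)
    if depth.ndim != 2 or depth.size == 0:
        raise DimensionError("depth map must be non-empty and 2-D")
    valid = np.isfinite(depth) & (depth > 0)
    d = np.where(valid, depth, 0.0)
    h, w = d.shape
    r = params.window_radius
    support = np.zeros((h, w), dtype=np.int64)
    n_valid = np.zeros((h, w), dtype=np.int64)
    tol = params.depth_tolerance + params.relative_tolerance * d
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            if dx == 0 and dy == 0:
                continue
            src = (slice(max(0, -dy), h - max(0, dy)), slice(max(0, -dx), w - max(0, dx)))
            dst = (slice(max(0, dy), h - max(0, -dy)), slice(max(0, dx), w - max(0, -dx)))
            nb_valid = valid[src]
            close = nb_valid & (np.abs(d[src] - d[dst]) <= tol[dst])
            support[dst] += close
            n_valid[dst] += nb_valid
    frac = support / np.maximum(n_valid, 1)
    keep = valid & (n_valid > 0) & (frac >= params.min_support)
    return np.where(keep, depth, 0.0)
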