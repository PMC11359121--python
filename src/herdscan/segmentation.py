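"""Per-frame target segmentation, mask fusion by voting arbitration, and scoring.

A learned instance segmenter (one model on RGB, one on depth) produced the
masks in the original cattle deployment; here the module defines the
mask-provider contract — any callable ``frame -> Mask`` can be registered per
modality — plus a deterministic geometric segmenter for synthetic scenes.
The two modality masks are fused by one of four arbitration modes
(RGB-only, depth-only, 1-vote OR, 2-vote AND) and scored with IOU and
false-positive / false-negative rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage

from .errors import DimensionError, ParameterError
from .frames_io import Mask, RGBDFrame

__all__ = [
    "ArbitrationMode",
    "SegScore",
    "geometric_segmenter",
    "fuse_masks",
    "score_mask",
    "apply_mask",
    "MaskProviderRegistry",
]


class ArbitrationMode(Enum):
    RGB_ONLY = "rgb"
    DEPTH_ONLY = "depth"
    ONE_VOTE_OR = "or"
    TWO_VOTE_AND = "and"


@dataclass(frozen=True)
class SegScore:
    iou: float
    fp_rate: float  # percent of ground-truth-negative pixels predicted positive
    fn_rate: float  # percent of ground-truth-positive pixels missed


_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


def geometric_segmenter(
    frame: RGBDFrame, depth_band: tuple[float, float], min_component_px: int = 50
) -> Mask:
    """Largest 8-connected component of valid depth inside ``depth_band``.

    A deterministic stand-in for a learned segmenter: on synthetic scenes
    where the target occupies a known depth band it reproduces the
    ground-truth mask up to band leakage.  Returns an empty mask when the
    largest component is smaller than ``min_component_px``.
    """
    z_near, z_far = depth_band
    if z_near >= z_far:
        raise ParameterError("depth band must satisfy z_near < z_far")
    in_band = frame.valid & (frame.depth >= z_near) & (frame.depth <= z_far)
    labels, n = ndimage.label(in_band, structure=_EIGHT_CONNECTED)
    if n == 0:
        return Mask(np.zeros_like(in_band), frame_id=frame.camera_id)
    counts = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(counts)) + 1
    if counts[best - 1] < min_component_px:
        return Mask(np.zeros_like(in_band), frame_id=frame.camera_id)
    return Mask(labels == best, frame_id=frame.camera_id)


def fuse_masks(m_rgb: Mask, m_depth: Mask, mode: ArbitrationMode) -> Mask:
    """Combine the two modality masks under a voting arbitration rule."""
    if m_rgb.values.shape != m_depth.values.shape:
        raise DimensionError("masks must share shape")
    if mode is ArbitrationMode.RGB_ONLY:
        v = m_rgb.values
    elif mode is ArbitrationMode.DEPTH_ONLY:
        v = m_depth.values
    elif mode is ArbitrationMode.ONE_VOTE_OR:
        v = m_rgb.values | m_depth.values
    elif mode is ArbitrationMode.TWO_VOTE_AND:
        v = m_rgb.values & m_depth.values
    else:  # pragma: no cover - enum is exhaustive
        raise ParameterError(f"unknown arbitration mode {mode!r}")
    return Mask(v.copy(), frame_id=m_rgb.frame_id)


def score_mask(pred: Mask, truth: Mask) -> SegScore:
    """IOU plus FP/FN percentages against a ground-truth mask.

    FP rate is referenced to ground-truth-negative pixels, FN rate to
    ground-truth-positive pixels (the denominators are isolated here so an
    alternative convention is a one-line change).
    """
    p, t = pred.values, truth.values
    if p.shape != t.shape:
        raise DimensionError("prediction and truth must share shape")
    n_pos = int(t.sum())
    n_neg = int((~t).sum())
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("truth must contain both positive and negative pixels")
    inter = int((p & t).sum())
    union = int((p | t).sum())
    iou = inter / union if union else 1.0
    fn = 100.0 * int((t & ~p).sum()) / n_pos
    fp = 100.0 * int((p & ~t).sum()) / n_neg
    return SegScore(iou=iou, fp_rate=fp, fn_rate=fn)


def apply_mask(frame: RGBDFrame, mask: Mask) -> RGBDFrame:
    """Zero colour and invalidate depth outside the mask; inside unchanged."""
    if mask.values.shape != frame.depth.shape:
        raise DimensionError("mask shape does not match frame")
    m = mask.values
    return RGBDFrame(
        color=np.where(m[..., None], frame.color, 0.0),
        depth=np.where(m, frame.depth, 0.0),
        intrinsics=frame.intrinsics,
        camera_id=frame.camera_id,
    )


class MaskProviderRegistry:
    """Pluggable per-modality mask providers (``frame -> Mask`` callables).

    Lets a learned segmenter replace the geometric stand-in for either
    modality without touching the pipeline.
    """

    def __init__(self):
        self._providers: dict[str, object] = {}

    def register(self, modality: str, provider) -> None:
        if modality not in ("rgb", "depth"):
            raise ParameterError("modality must be 'rgb' or 'depth'")
        self._providers[modality] = provider

    def predict(self, modality: str, frame: RGBDFrame) -> Mask:
        if modality not in self._providers:
            raise ParameterError(f"no mask provider registered for {modality!r}")
        return self._providers[modality](frame)

    def fused(self, frame: RGBDFrame, mode: ArbitrationMode) -> Mask:
        if mode is ArbitrationMode.RGB_ONLY:
            return self.predict("rgb", frame)
        if mode is ArbitrationMode.DEPTH_ONLY:
            return self.predict("depth", frame)
        return fuse_masks(self.predict("rgb", frame), self.predict("depth", frame), mode)
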