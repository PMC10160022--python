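"""Image-stack preprocessing: z-normalization, foreground masks, registration.

The contract mirrors standard live-cell phase-contrast preprocessing: each
frame is z-normalized (mean subtracted, divided by its standard deviation),
background pixels are then set exactly to 0, and the stack is registered
translationally only (no rotation or affine component) with subpixel
precision via phase cross-correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.registration import phase_cross_correlation

__all__ = [
    "FrameStack",
    "ForegroundMaskStack",
    "znormalize_stack",
    "register_stack_translational",
    "threshold_foreground",
]


@dataclass
class FrameStack:
    """A T x H x W grayscale image stack from one field of view."""

    pixels: np.ndarray
    frame_interval: float = 30.0  # minutes
    treatment: str = ""
    stack_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[0] < 1:
            raise ValueError("pixels must be a T x H x W array with T >= 1")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]


@dataclass
class ForegroundMaskStack:
    """Binary foreground (cell=1) masks matching a FrameStack frame-for-frame."""

    masks: np.ndarray

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks).astype(bool)
        if self.masks.ndim != 3:
            raise ValueError("masks must be T x H x W")


def znormalize_stack(
    stack: FrameStack,
    fg: ForegroundMaskStack,
    stats_on: str = "frame",
) -> FrameStack:
    """Z-normalize each frame, then zero the background exactly.

    Parameters
    ----------
    stats_on : {"frame", "foreground"}
        Support of the mean/SD statistics: the whole frame (default) or the
        foreground pixels only.  Background pixels are set to 0 afterwards in
        either mode.
    """
    if stack.pixels.shape != fg.masks.shape:
        raise ValueError("mask shape does not match stack shape")
    if stats_on not in ("frame", "foreground"):
        raise ValueError("stats_on must be 'frame' or 'foreground'")
    out = np.empty_like(stack.pixels)
    for t in range(stack.n_frames):
        frame = stack.pixels[t]
        sel = frame[fg.masks[t]] if stats_on == "foreground" else frame
        if sel.size == 0:
            out[t] = 0.0
            continue
        mu, sd = float(np.mean(sel)), float(np.std(sel))
        if sd == 0.0:
            raise ValueError(f"frame {t} has zero standard deviation; cannot z-normalize")
        out[t] = (frame - mu) / sd
        out[t][~fg.masks[t]] = 0.0
    return replace(stack, pixels=out)


def register_stack_translational(
    stack: FrameStack,
    mode: str = "consecutive",
    upsample_factor: int = 10,
) -> tuple[FrameStack, np.ndarray]:
    """Register a stack by per-frame subpixel translation only.

    In ``consecutive`` mode each frame is aligned to its predecessor and the
    shifts are accumulated (drift correction); in ``fixed`` mode every frame
    is aligned to frame 0.  Returns the registered stack and the applied
    shift vectors, one (row, col) pair per frame in pixels.
    """
    if stack.n_frames < 2:
        raise ValueError("registration requires at least 2 frames")
    if mode not in ("consecutive", "fixed"):
        raise ValueError("mode must be 'consecutive' or 'fixed'")
    px = stack.pixels
    shifts = np.zeros((stack.n_frames, 2), dtype=float)
    out = np.empty_like(px)
    out[0] = px[0]
    for t in range(1, stack.n_frames):
        ref = out[t - 1] if mode == "consecutive" else px[0]
        shift, _, _ = phase_cross_correlation(ref, px[t], upsample_factor=upsample_factor)
        shifts[t] = shift
        out[t] = ndi.shift(px[t], shift, order=1, mode="constant", cval=0.0)
    return replace(stack, pixels=out), shifts


def threshold_foreground(
    stack: FrameStack,
    threshold: float | None = None,
    min_area_px: int = 4,
    fill_holes: bool = True,
) -> ForegroundMaskStack:
    """Fallback intensity-threshold foreground detector with cleanup.

    Any segmentation backend can supply masks instead; this is the simplest
    pluggable default.  ``threshold=None`` uses Otsu's threshold per frame.
    """
    from skimage.filters import threshold_otsu

    masks = np.zeros(stack.pixels.shape, dtype=bool)
    for t in range(stack.n_frames):
        frame = stack.pixels[t]
        if threshold is None:
            if np.ptp(frame) == 0:
                continue
            thr = threshold_otsu(frame)
        else:
            thr = threshold
        m = frame > thr
        if fill_holes:
            m = ndi.binary_fill_holes(m)
        if min_area_px > 1:
            lab, n = ndi.label(m)
            if n:
                areas = np.bincount(lab.ravel())
                m = areas[lab] >= min_area_px
                m[lab == 0] = False
        masks[t] = m
    return ForegroundMaskStack(masks=masks)
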