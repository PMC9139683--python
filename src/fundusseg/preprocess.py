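"""Intensity normalization, resizing, augmentation and full-frame remapping.

Conventions: arrays are (row, col[, channel]) with the origin at the top
left; masks are binary and stay binary through every geometric operation
(nearest-neighbour resampling), while images are resampled bilinearly.
Regions exposed by rotation or border padding are filled with black.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize
from skimage.transform import rotate as _sk_rotate

__all__ = [
    "NormalizedImage", "normalize_image", "denormalize_image",
    "resize_pair", "augment", "map_back",
    "SEGMENTATION_ROTATIONS", "ROI_ROTATIONS",
]

#: rotation sets (degrees): segmentation-stage augmentation and the wider
#: ROI-detector-stage set (the latter kept for configuration completeness).
SEGMENTATION_ROTATIONS = (-10.0, -5.0, 0.0, 5.0, 10.0)
ROI_ROTATIONS = (-20.0, -10.0, 0.0, 10.0, 20.0)


@dataclass
class NormalizedImage:
    """Per-channel z-scored image with the moments needed to invert it."""

    data: np.ndarray  # float (H, W, 3)
    mean: np.ndarray  # (3,) per-channel mean of the source image
    std: np.ndarray   # (3,) per-channel standard deviation


def normalize_image(image: np.ndarray) -> NormalizedImage:
    """Z-score each channel: (I - m_k) / sigma_k for k in {R, G, B}.

    Raises
    ------
    ValueError
        If any channel is constant (zero standard deviation).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    mean = image.mean(axis=(0, 1))
    std = image.std(axis=(0, 1))
    if np.any(std == 0):
        bad = [ch for ch, s in zip("RGB", std) if s == 0]
        raise ValueError(f"degenerate image: zero-variance channel(s) {bad}")
    return NormalizedImage(data=(image - mean) / std, mean=mean, std=std)


def denormalize_image(norm: NormalizedImage) -> np.ndarray:
    """Invert :func:`normalize_image` exactly (up to float round-off)."""
    return norm.data * norm.std + norm.mean


def resize_pair(image: np.ndarray, masks, target: int):
    """Resize an image (bilinear) and its masks (nearest-neighbour) to target x target.

    ``masks`` may be a single mask or a sequence; binarity is preserved.
    """
    if target < 8:
        raise ValueError("target side must be >= 8")
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    out_img = _sk_resize(image, (target, target), order=1, anti_aliasing=True,
                         preserve_range=True)
    if image.dtype == np.uint8:
        out_img = np.clip(np.rint(out_img), 0, 255).astype(np.uint8)

    single = isinstance(masks, np.ndarray)
    mask_list = [masks] if single else list(masks)
    out_masks = []
    for m in mask_list:
        m = np.asarray(m)
        if m.size == 0:
            raise ValueError("empty mask")
        r = _sk_resize(m.astype(np.uint8), (target, target), order=0,
                       anti_aliasing=False, preserve_range=True)
        out_masks.append((r > 0).astype(m.dtype))
    return out_img, (out_masks[0] if single else out_masks)


def _rotate_image(image: np.ndarray, angle: float) -> np.ndarray:
    out = _sk_rotate(image.astype(np.float64), angle, resize=False, order=1,
                     cval=0.0, preserve_range=True)
    if image.dtype == np.uint8:
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return out.astype(image.dtype)


def _rotate_mask(mask: np.ndarray, angle: float) -> np.ndarray:
    out = _sk_rotate(mask.astype(np.uint8), angle, resize=False, order=0,
                     cval=0, preserve_range=True)
    return (out > 0).astype(mask.dtype)


def augment(image: np.ndarray, masks, rotations=SEGMENTATION_ROTATIONS,
            flip: bool = True) -> list[tuple[np.ndarray, list[np.ndarray]]]:
    """Rotation/vertical-flip augmentation applied identically to image and masks.

    Returns ``len(rotations) * (2 if flip else 1)`` pairs — 10 at defaults.
    The 0-degree, unflipped pair is the input itself, bit for bit.
    """
    rotations = list(rotations)
    if not rotations:
        raise ValueError("rotation list must be nonempty")
    single = isinstance(masks, np.ndarray)
    mask_list = [masks] if single else list(masks)

    variants = [(np.asarray(image), [np.asarray(m) for m in mask_list])]
    if flip:
        variants.append((np.flipud(image).copy(), [np.flipud(m).copy() for m in mask_list]))

    out = []
    for img_v, masks_v in variants:
        for angle in rotations:
            if angle == 0.0:
                pair_img, pair_masks = img_v, masks_v
            else:
                pair_img = _rotate_image(img_v, angle)
                pair_masks = [_rotate_mask(m, angle) for m in masks_v]
            out.append((pair_img, pair_masks[0] if single else pair_masks))
    return out


def map_back(crop_output: np.ndarray, window, full_shape: tuple[int, int]) -> np.ndarray:
    """Remap a square crop-level mask to full-frame coordinates.

    The mask is resized (nearest-neighbour) from the model side to the crop
    window's side and pasted into a black full-frame canvas at the window's
    location; portions of the window outside the frame are dropped.
    """
    crop_output = np.asarray(crop_output)
    if crop_output.ndim != 2 or crop_output.shape[0] != crop_output.shape[1]:
        raise ValueError("crop output must be a square 2-D mask")
    h, w = full_shape
    side = window.side
    r0, c0 = window.top_left
    if r0 >= h or c0 >= w or r0 + side <= 0 or c0 + side <= 0:
        raise ValueError("crop window lies entirely outside the full frame")
    if crop_output.shape[0] != side:
        r = _sk_resize(crop_output.astype(np.uint8), (side, side), order=0,
                       anti_aliasing=False, preserve_range=True)
        crop_output = (r > 0).astype(crop_output.dtype)
    full = np.zeros((h, w), dtype=crop_output.dtype)
    rr0, cc0 = max(r0, 0), max(c0, 0)
    rr1, cc1 = min(r0 + side, h), min(c0 + side, w)
    full[rr0:rr1, cc0:cc1] = crop_output[rr0 - r0:rr1 - r0, cc0 - c0:cc1 - c0]
    return full
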