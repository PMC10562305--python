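"""Training-time tile augmentation.

Geometric transforms (horizontal flip, small rotation) are applied
identically to image and label; photometric jitter (brightness, contrast,
saturation) and random erasing touch the image only. Rotations stay within
+-5 degrees: map symbology is orientation-sensitive (mire hatching is
horizontal), so only slight rotations are plausible scan variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["AugmentParams", "augment_tile"]


@dataclass(frozen=True)
class AugmentParams:
    p_flip: float = 0.5
    p_color: float = 0.8
    brightness: float = 0.15     # max relative shift
    contrast: float = 0.15       # max relative scale
    saturation: float = 0.15     # max relative scale
    p_rotate: float = 0.5
    max_rotation_deg: float = 5.0
    p_erase: float = 0.25
    erase_fraction: float = 0.06  # target erased area fraction

    @classmethod
    def identity(cls) -> "AugmentParams":
        return cls(p_flip=0.0, p_color=0.0, p_rotate=0.0, p_erase=0.0)


def _jitter_colors(img: np.ndarray, params: AugmentParams, rng) -> np.ndarray:
    out = img.astype(np.float64)
    b = rng.uniform(-params.brightness, params.brightness)
    out += 255.0 * b
    c = 1.0 + rng.uniform(-params.contrast, params.contrast)
    out = (out - out.mean()) * c + out.mean()
    s = 1.0 + rng.uniform(-params.saturation, params.saturation)
    gray = out.mean(axis=2, keepdims=True)
    out = gray + (out - gray) * s
    return np.clip(out, 0, 255)


def _erase(img: np.ndarray, fraction: float, rng) -> np.ndarray:
    h, w = img.shape[:2]
    area = fraction * h * w
    aspect = rng.uniform(0.5, 2.0)
    eh = min(h, max(1, int(round(np.sqrt(area * aspect)))))
    ew = min(w, max(1, int(round(area / eh))))
    r0 = rng.integers(0, h - eh + 1)
    c0 = rng.integers(0, w - ew + 1)
    out = img.copy()
    out[r0 : r0 + eh, c0 : c0 + ew] = rng.integers(0, 256, size=3)
    return out


def augment_tile(
    image: np.ndarray,
    label: np.ndarray,
    seed: int | np.random.Generator = 0,
    params: AugmentParams | None = None,
):
    """Return an augmented (image, label) pair; deterministic under seed."""
    if image.shape[0] != image.shape[1]:
        raise ValueError("tiles must be square")
    params = params or AugmentParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    img = image.astype(np.float64)
    lab = label.copy()

    if rng.random() < params.p_flip:
        img = img[:, ::-1]
        lab = lab[:, ::-1]
    if rng.random() < params.p_rotate:
        angle = rng.uniform(-params.max_rotation_deg, params.max_rotation_deg)
        img = ndimage.rotate(img, angle, axes=(0, 1), reshape=False,
                             order=1, mode="nearest")
        lab = ndimage.rotate(lab, angle, axes=(0, 1), reshape=False,
                             order=0, mode="nearest")
    if rng.random() < params.p_color:
        img = _jitter_colors(img, params, rng)
    img = np.clip(img, 0, 255).astype(np.uint8)
    if rng.random() < params.p_erase:
        img = _erase(img, params.erase_fraction, rng)
    return img, lab
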