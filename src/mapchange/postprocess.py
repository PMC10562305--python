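"""Per-class morphological cleanup of predicted label rasters.

Raw per-pixel predictions contain speckle: isolated pixels of a class,
remnants of map lettering, and ragged class edges. Each of the five classes
gets its own cleanup chain before vectorization:

* water bodies — opening with an 11x11 kernel, then a 7x7 majority filter;
* roads and watercourses — closing with a 7x7 kernel, then a 5x5 majority
  filter (closing bridges small gaps in linear features);
* fields and mires — the class mask is first unioned with watercourses so a
  ditch crossing a field does not split it, then eroded with an 11x11
  cross-shaped kernel (which eats 1-2 px wide watercourse lines outside the
  areal class), dilated with an 11x11 rectangular kernel, majority-filtered
  7x7, and finally clipped with the processed roads and water bodies.

The result is a five-band binary stack aligned with the input labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .georaster import GeoRaster

__all__ = [
    "StructuringElement",
    "BinaryClassStack",
    "CLASS_NAMES",
    "binary_morphology",
    "lowpass_filter",
    "postprocess_stack",
]

# label raster codes: 0 background, then these five classes
CLASS_NAMES = ("fields", "mires", "roads", "watercourses", "water_bodies")


@dataclass(frozen=True)
class StructuringElement:
    """Flat structuring element: a filled rectangle or a 1-px-arm cross."""

    shape: str = "rectangle"  # "rectangle" | "cross"
    size: int = 3

    def __post_init__(self) -> None:
        if self.shape not in ("rectangle", "cross"):
            raise ValueError("shape must be 'rectangle' or 'cross'")
        if self.size < 3 or self.size % 2 == 0:
            raise ValueError("size must be an odd integer >= 3")

    def footprint(self) -> np.ndarray:
        if self.shape == "rectangle":
            return np.ones((self.size, self.size), dtype=bool)
        fp = np.zeros((self.size, self.size), dtype=bool)
        mid = self.size // 2
        fp[mid, :] = True
        fp[:, mid] = True
        return fp


@dataclass
class BinaryClassStack:
    """Five aligned binary masks (fields, mires, roads, watercourses, water
    bodies) sharing one georeference."""

    fields: np.ndarray
    mires: np.ndarray
    roads: np.ndarray
    watercourses: np.ndarray
    water_bodies: np.ndarray

    def __post_init__(self) -> None:
        shapes = {band.shape for band in self.bands()}
        if len(shapes) != 1:
            raise ValueError("all bands must share one shape")

    def bands(self) -> tuple[np.ndarray, ...]:
        return (self.fields, self.mires, self.roads, self.watercourses,
                self.water_bodies)

    def band(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def as_array(self) -> np.ndarray:
        """(5, H, W) uint8 array in canonical band order."""
        return np.stack([b.astype(np.uint8) for b in self.bands()])


def _check_binary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.dtype != bool and not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    return mask.astype(bool)


def binary_morphology(
    mask: np.ndarray, op: str, se: StructuringElement
) -> np.ndarray:
    """Minkowski erosion/dilation and their compositions, zero-padded borders.

    ``open`` = erode then dilate (removes specks smaller than the element);
    ``close`` = dilate then erode (fills gaps smaller than the element).
    """
    mask = _check_binary(mask)
    fp = se.footprint()
    if op == "erode":
        return ndimage.binary_erosion(mask, structure=fp, border_value=0)
    if op == "dilate":
        return ndimage.binary_dilation(mask, structure=fp, border_value=0)
    if op in ("open", "close"):
        # compose on a zero-padded copy so the intermediate dilation is not
        # clipped at the raster edge; this keeps closing extensive and
        # opening anti-extensive everywhere
        p = se.size
        padded = np.pad(mask, p)
        first, second = ("erode", "dilate") if op == "open" else ("dilate", "erode")
        out = binary_morphology(
            binary_morphology(padded, first, se), second, se
        )
        return out[p:-p, p:-p]
    raise ValueError(f"unknown morphological op {op!r}")


def lowpass_filter(mask: np.ndarray, size: int) -> np.ndarray:
    """Majority vote in a size x size box (box mean thresholded at 0.5).

    Borders are zero-padded, so foreground touching the sheet edge is
    treated as bordered by background.
    """
    if size < 1 or size % 2 == 0:
        raise ValueError("size must be an odd integer")
    mask = _check_binary(mask)
    counts = ndimage.uniform_filter(
        mask.astype(np.float64), size=size, mode="constant", cval=0.0
    )
    # counts is an exact multiple of 1/size^2 up to fp error; strict majority
    return counts > 0.5 - 1e-9


def _areal_chain(areal: np.ndarray, watercourses: np.ndarray) -> np.ndarray:
    merged = areal | watercourses
    out = binary_morphology(merged, "erode", StructuringElement("cross", 11))
    out = binary_morphology(out, "dilate", StructuringElement("rectangle", 11))
    return lowpass_filter(out, 7)


def postprocess_stack(labels: GeoRaster | np.ndarray) -> BinaryClassStack:
    """Run the per-class cleanup chains on a 0-5 label raster."""
    data = labels.data if isinstance(labels, GeoRaster) else np.asarray(labels)
    if not np.isin(data, range(6)).all():
        raise ValueError("label raster must contain values 0..5 only")
    masks = {name: data == code for code, name in enumerate(CLASS_NAMES, start=1)}

    water = binary_morphology(
        masks["water_bodies"], "open", StructuringElement("rectangle", 11)
    )
    water = lowpass_filter(water, 7)

    linear = {}
    for name in ("roads", "watercourses"):
        band = binary_morphology(
            masks[name], "close", StructuringElement("rectangle", 7)
        )
        linear[name] = lowpass_filter(band, 5)

    fields = _areal_chain(masks["fields"], masks["watercourses"])
    mires = _areal_chain(masks["mires"], masks["watercourses"])
    # clip areal classes with processed roads, then water bodies (set
    # subtraction, so the order is immaterial)
    clip = linear["roads"] | water
    fields &= ~clip
    mires &= ~clip

    return BinaryClassStack(
        fields=fields,
        mires=mires,
        roads=linear["roads"],
        watercourses=linear["watercourses"],
        water_bodies=water,
    )
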