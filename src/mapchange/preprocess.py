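"""Map-sheet pre-processing: margin cropping, white balance, dislocation error.

Scanned map sheets carry wide margins (legends, coordinate ticks) and the
print colors drift with the age and storage of the sheet — some scans show a
yellow or reddish tint. Cropping keeps only map content; white balance
rescales each color band so a known white patch (sampled from the sheet
edge) becomes neutral gray; the dislocation error summarises georeferencing
quality as the RMSE of 2-D control-point residuals against a modern
reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .georaster import GeoRaster

__all__ = [
    "WhiteReference",
    "ControlPointSet",
    "crop_margins",
    "estimate_white_reference",
    "white_balance",
    "georeference_rmse",
]


@dataclass(frozen=True)
class WhiteReference:
    """Per-band mean values of the reference white patch, in [0, 255]."""

    r_ref: float
    g_ref: float
    b_ref: float

    def __post_init__(self) -> None:
        if min(self.r_ref, self.g_ref, self.b_ref) <= 0:
            raise ValueError("white reference bands must be strictly positive")

    @property
    def luminance(self) -> float:
        return (self.r_ref + self.g_ref + self.b_ref) / 3.0


@dataclass
class ControlPointSet:
    """2-D residuals (map position minus reference position) in meters."""

    residuals: np.ndarray  # shape (n, 2)

    def __post_init__(self) -> None:
        self.residuals = np.atleast_2d(np.asarray(self.residuals, dtype=float))
        if self.residuals.size == 0 or self.residuals.shape[1] != 2:
            raise ValueError("residuals must be a non-empty (n, 2) array")

    @property
    def n(self) -> int:
        return self.residuals.shape[0]

    @classmethod
    def from_csv(cls, path: str | Path) -> "ControlPointSet":
        """Load control points from columns x_map, y_map, x_ref, y_ref."""
        df = pd.read_csv(path)
        res = np.column_stack(
            [df["x_map"] - df["x_ref"], df["y_map"] - df["y_ref"]]
        )
        return cls(res)


def crop_margins(sheet: GeoRaster, content_window: tuple[int, int, int, int]) -> GeoRaster:
    """Crop to ``(row_off, col_off, height, width)``, keeping world coordinates.

    The returned raster's georeference is shifted so every kept pixel retains
    its original world position.
    """
    row_off, col_off, height, width = content_window
    return sheet.window(row_off, col_off, height, width)


def estimate_white_reference(
    sheet: GeoRaster, patch: tuple[int, int, int, int]
) -> WhiteReference:
    """Mean color of a (row_off, col_off, height, width) patch.

    The patch is normally taken from the unprinted sheet edge; a zero band
    mean indicates the patch missed the paper entirely.
    """
    window = sheet.window(*patch)
    if window.data.ndim != 3 or window.data.shape[2] != 3:
        raise ValueError("white reference requires an RGB sheet")
    means = window.data.reshape(-1, 3).mean(axis=0)
    if np.any(means == 0):
        raise ValueError("degenerate white reference: a band mean is zero")
    return WhiteReference(*map(float, means))


def white_balance(sheet: GeoRaster, ref: WhiteReference) -> GeoRaster:
    """Scale each band by luminance / band reference; clip to [0, 255], uint8.

    With a gray reference (all bands equal) this is the identity. Conversion
    to unsigned integer truncates toward zero after clipping.
    """
    if sheet.data.ndim != 3 or sheet.data.shape[2] != 3:
        raise ValueError("white balance requires an RGB sheet")
    lum = ref.luminance
    gains = np.array([lum / ref.r_ref, lum / ref.g_ref, lum / ref.b_ref])
    balanced = sheet.data.astype(np.float64) * gains
    balanced = np.clip(balanced, 0.0, 255.0)
    return sheet.like(balanced.astype(np.uint8))


def georeference_rmse(points: ControlPointSet | Sequence | np.ndarray) -> float:
    """Root mean square of 2-D control-point residuals, in meters.

    ``sqrt(mean_i(x_i^2 + y_i^2))`` — invariant under point permutation and
    per-component sign flips.
    """
    if not isinstance(points, ControlPointSet):
        points = ControlPointSet(np.asarray(points))
    sq = np.sum(points.residuals ** 2, axis=1)
    return float(np.sqrt(sq.mean()))
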