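"""Minimal georeferenced raster container.

All rasters in this package are north-up with square pixels: world
coordinates are meters, pixel (0, 0) sits in the top-left corner, and the
world coordinate of a pixel refers to its center. That is the convention of
the scanned map sheets this package targets (~1.7 m/px after
georeferencing), and it keeps the affine transform down to three numbers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["GeoTransform", "GeoRaster"]


@dataclass(frozen=True)
class GeoTransform:
    """North-up affine georeference.

    ``origin_x``/``origin_y`` are the world coordinates of the *outer corner*
    of pixel (0, 0); ``pixel_size`` is the edge length of a pixel in meters.
    Rows increase southwards (world y decreases with row index).
    """

    origin_x: float
    origin_y: float
    pixel_size: float

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    def pixel_center(self, row, col):
        """World coordinates of the center(s) of pixel (row, col)."""
        x = self.origin_x + (np.asarray(col) + 0.5) * self.pixel_size
        y = self.origin_y - (np.asarray(row) + 0.5) * self.pixel_size
        return x, y

    def shifted(self, row_off: int, col_off: int) -> "GeoTransform":
        """Transform for a window whose top-left pixel is (row_off, col_off)."""
        return GeoTransform(
            self.origin_x + col_off * self.pixel_size,
            self.origin_y - row_off * self.pixel_size,
            self.pixel_size,
        )


@dataclass
class GeoRaster:
    """Pixel grid plus georeference.

    ``data`` is ``(H, W)`` for label/binary rasters or ``(H, W, 3)`` for RGB
    sheets. ``crs_id`` is an opaque label (e.g. ``"EPSG:3067"``); the package
    never reprojects, it only checks that layers agree.
    """

    data: np.ndarray
    transform: GeoTransform
    crs_id: str = "local"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (2, 3):
            raise ValueError("raster data must be 2-D or 3-D (H, W[, bands])")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    @property
    def pixel_size(self) -> float:
        return self.transform.pixel_size

    @property
    def pixel_area(self) -> float:
        return self.transform.pixel_size ** 2

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster footprint in world meters."""
        h, w = self.shape
        t = self.transform
        return (
            t.origin_x,
            t.origin_y - h * t.pixel_size,
            t.origin_x + w * t.pixel_size,
            t.origin_y,
        )

    def window(self, row_off: int, col_off: int, height: int, width: int) -> "GeoRaster":
        """Sub-raster with an updated georeference (shares memory)."""
        h, w = self.shape
        if height <= 0 or width <= 0:
            raise ValueError("window must be non-empty")
        if row_off < 0 or col_off < 0 or row_off + height > h or col_off + width > w:
            raise ValueError("window outside raster bounds")
        return GeoRaster(
            self.data[row_off : row_off + height, col_off : col_off + width],
            self.transform.shifted(row_off, col_off),
            self.crs_id,
        )

    def like(self, data: np.ndarray) -> "GeoRaster":
        """New raster sharing this one's georeference."""
        data = np.asarray(data)
        if data.shape[:2] != self.shape:
            raise ValueError("data shape does not match raster shape")
        return GeoRaster(data, self.transform, self.crs_id)

    # ---- I/O -------------------------------------------------------------

    def write(self, path: str | Path) -> None:
        """Write as TIFF with GeoTIFF pixel-scale/tiepoint tags.

        A ``.json`` sidecar stores the CRS label so round trips do not depend
        on a GeoTIFF keys parser being available.
        """
        path = Path(path)
        t = self.transform
        scale = (t.pixel_size, t.pixel_size, 0.0)
        tiepoint = (0.0, 0.0, 0.0, t.origin_x, t.origin_y, 0.0)
        extratags = [
            (33550, "d", 3, scale, True),       # ModelPixelScaleTag
            (33922, "d", 6, tiepoint, True),    # ModelTiepointTag
        ]
        photometric = "rgb" if self.data.ndim == 3 else "minisblack"
        tifffile.imwrite(path, self.data, photometric=photometric, extratags=extratags)
        sidecar = {"crs_id": self.crs_id}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def read(cls, path: str | Path) -> "GeoRaster":
        path = Path(path)
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            data = page.asarray()
            tags = page.tags
            try:
                scale = tags[33550].value
                tiepoint = tags[33922].value
            except KeyError as exc:
                raise ValueError(f"{path} has no GeoTIFF georeference tags") from exc
        transform = GeoTransform(float(tiepoint[3]), float(tiepoint[4]), float(scale[0]))
        crs_id = "local"
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            crs_id = json.loads(sidecar.read_text()).get("crs_id", "local")
        return cls(data, transform, crs_id)
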