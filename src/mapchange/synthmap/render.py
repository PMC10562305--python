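"""Rasterize a vector scene into an RGB map sheet and a label raster.

Styling follows 1:20 000 printed map conventions: fields as uniform light
fills, mires as horizontal hatch lines inside a dotted outline, roads as
wide red lines, watercourses as thin blue lines, water bodies as blue
fills, lettering and contour decoys in black. The label raster is burned
directly from the scene geometry with a pixel-center coverage rule and
never contains decoys.

Degradation of old scans is emulated with a per-band multiplicative color
cast (yellowed or reddish paper) and additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from PIL import Image, ImageDraw, ImageFont
from .scene import SynthScene
from ..georaster import GeoRaster, GeoTransform

__all__ = ["RenderStyle", "render_sheet", "rasterize_labels"]

# label codes, shared with the rest of the package
LABELS = {"fields": 1, "mires": 2, "roads": 3, "watercourses": 4,
          "water_bodies": 5}


@dataclass(frozen=True)
class RenderStyle:
    """Colors, symbology parameters and degradation model for rendering."""

    field_color: tuple[int, int, int] = (250, 240, 170)
    mire_line_color: tuple[int, int, int] = (70, 70, 70)
    mire_hatch_spacing_px: int = 6
    mire_dot_pitch_px: int = 5
    road_color: tuple[int, int, int] = (205, 50, 40)
    water_color: tuple[int, int, int] = (110, 160, 205)
    background_color: tuple[int, int, int] = (246, 243, 232)
    decoy_color: tuple[int, int, int] = (25, 25, 25)
    road_width_px: int = 5
    # 3 px ~= 5 m: the printed exaggeration of a ~0.3 mm blue line at
    # 1:20 000; anything thinner cannot survive the stated 5x5 majority
    # filter of the linear-class cleanup chain
    watercourse_width_px: int = 3
    color_cast: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sd: float = 2.5
    pixel_size_m: float = 1.7

    def __post_init__(self) -> None:
        if self.pixel_size_m <= 0:
            raise ValueError("pixel_size_m must be > 0")
        for name in ("field_color", "mire_line_color", "road_color",
                     "water_color", "background_color", "decoy_color"):
            if not all(0 <= v <= 255 for v in getattr(self, name)):
                raise ValueError(f"{name} components must lie in [0, 255]")
        if any(f <= 0 for f in self.color_cast):
            raise ValueError("color_cast factors must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _coverage_mask(geom, transform: GeoTransform, shape) -> np.ndarray:
    """Boolean mask of pixels whose centers the geometry covers."""
    h, w = shape
    out = np.zeros((h, w), dtype=bool)
    if geom.is_empty:
        return out
    px = transform.pixel_size
    minx, miny, maxx, maxy = geom.bounds
    c0 = max(0, int(np.floor((minx - transform.origin_x) / px - 0.5)))
    c1 = min(w - 1, int(np.ceil((maxx - transform.origin_x) / px)))
    r0 = max(0, int(np.floor((transform.origin_y - maxy) / px - 0.5)))
    r1 = min(h - 1, int(np.ceil((transform.origin_y - miny) / px)))
    if c1 < c0 or r1 < r0:
        return out
    rows = np.arange(r0, r1 + 1)
    cols = np.arange(c0, c1 + 1)
    cc, rr = np.meshgrid(cols, rows)
    xs, ys = transform.pixel_center(rr.ravel(), cc.ravel())
    shapely.prepare(geom)
    hit = shapely.intersects_xy(geom, xs, ys)
    out[r0 : r1 + 1, c0 : c1 + 1] = hit.reshape(rr.shape)
    return out


def _burn(geoms, value, labels, transform) -> None:
    for geom in geoms:
        labels[_coverage_mask(geom, transform, labels.shape)] = value


def _line_polys(lines, width_m: float):
    return [line.buffer(width_m / 2.0, cap_style="flat") for line in lines]


def rasterize_labels(scene: SynthScene, style: RenderStyle) -> GeoRaster:
    """Label raster (0 background, 1..5 classes), pixel-center coverage.

    Burn order: areal classes (mutually exclusive by scene invariant), then
    watercourses, then roads on top, so thin linear features survive.
    """
    px = style.pixel_size_m
    w = max(1, int(round(scene.extent[0] / px)))
    h = max(1, int(round(scene.extent[1] / px)))
    transform = GeoTransform(0.0, scene.extent[1], px)
    labels = np.zeros((h, w), dtype=np.uint8)
    _burn(scene.fields, LABELS["fields"], labels, transform)
    _burn(scene.mires, LABELS["mires"], labels, transform)
    _burn(scene.water_bodies, LABELS["water_bodies"], labels, transform)
    _burn(_line_polys(scene.watercourses, style.watercourse_width_px * px),
          LABELS["watercourses"], labels, transform)
    _burn(_line_polys(scene.roads, style.road_width_px * px),
          LABELS["roads"], labels, transform)
    return GeoRaster(labels, transform, scene.crs_id)


def _mire_symbology(mask: np.ndarray, geoms, transform, style) -> np.ndarray:
    """Hatch rows inside the polygon plus a dotted outline."""
    h, w = mask.shape
    sym = np.zeros_like(mask)
    rows = np.arange(h)
    hatch_rows = rows % style.mire_hatch_spacing_px == 0
    sym[hatch_rows] = mask[hatch_rows]
    px = transform.pixel_size
    pitch_m = style.mire_dot_pitch_px * px
    for geom in geoms:
        ring = geom.exterior
        n_dots = max(4, int(ring.length / pitch_m))
        for i in range(n_dots):
            pt = ring.interpolate(i * pitch_m)
            col = int((pt.x - transform.origin_x) / px)
            row = int((transform.origin_y - pt.y) / px)
            if 0 <= row < h and 0 <= col < w:
                sym[row, col] = True
    return sym


def _draw_text_decoys(rgb: np.ndarray, scene, style, transform) -> None:
    h, w = rgb.shape[:2]
    overlay = Image.new("L", (w, h), 0)
    draw = ImageDraw.Draw(overlay)
    font = ImageFont.load_default()
    px = transform.pixel_size
    for decoy in scene.text_decoys:
        col = int((decoy.x - transform.origin_x) / px)
        row = int((transform.origin_y - decoy.y) / px)
        draw.text((col, row), decoy.text, fill=255, font=font)
    mask = np.array(overlay) > 96
    rgb[mask] = style.decoy_color


def render_sheet(
    scene: SynthScene, style: RenderStyle | None = None, seed: int | None = None
) -> tuple[GeoRaster, GeoRaster]:
    """Render ``(rgb_sheet, label_raster)`` for one scene epoch.

    Noise and no other step consumes randomness; the noise stream derives
    from ``seed`` (default: the scene's own seed), so rendering is
    reproducible.
    """
    style = style or RenderStyle()
    label_raster = rasterize_labels(scene, style)
    labels = label_raster.data
    transform = label_raster.transform
    h, w = labels.shape

    rgb = np.empty((h, w, 3), dtype=np.float64)
    rgb[...] = style.background_color

    rgb[labels == LABELS["fields"]] = style.field_color

    mire_mask = labels == LABELS["mires"]
    sym = _mire_symbology(mire_mask, scene.mires, transform, style)
    rgb[sym] = style.mire_line_color

    rgb[labels == LABELS["water_bodies"]] = style.water_color
    rgb[labels == LABELS["watercourses"]] = style.water_color
    rgb[labels == LABELS["roads"]] = style.road_color

    # decoys: rendered, never labeled
    for contour in scene.contour_decoys:
        contour_mask = _coverage_mask(
            contour.buffer(transform.pixel_size / 2.0), transform, (h, w)
        )
        rgb[contour_mask & (labels == 0)] = style.decoy_color
    _draw_text_decoys(rgb, scene, style, transform)

    rgb *= np.asarray(style.color_cast)
    if style.noise_sd > 0:
        rng = np.random.default_rng(scene.seed if seed is None else seed)
        rgb += rng.normal(0.0, style.noise_sd, size=rgb.shape)
    rgb = np.clip(rgb, 0, 255).astype(np.uint8)
    return GeoRaster(rgb, transform, scene.crs_id), label_raster
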