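"""Vector scene generation and between-epoch evolution.

Default densities follow the magnitudes of a southern-boreal study area of
the kind the package targets: fields ~11% and mires ~9% of land area, water
bodies ~19%, roads ~0.4 km/km² and watercourses ~1.3 km/km² in the first
epoch. Epoch evolution removes whole field parcels (abandonment /
afforestation), digs straight drainage ditches concentrated in mires, and
extends the road network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely import affinity
from shapely.geometry import LineString, Polygon, box
from shapely.ops import substring

__all__ = ["SceneParams", "ChangeParams", "TextDecoy", "SynthScene",
           "generate_scene", "evolve_scene"]


@dataclass(frozen=True)
class TextDecoy:
    """A piece of map lettering: present in the rendered RGB, never in labels."""

    text: str
    x: float
    y: float
    size_px: int = 12


@dataclass(frozen=True)
class SceneParams:
    """Target densities and size ranges for scene generation."""

    field_area_fraction: float = 0.11
    mire_area_fraction: float = 0.09
    water_area_fraction: float = 0.19
    road_density_km_per_km2: float = 0.4
    watercourse_density_km_per_km2: float = 1.3
    text_decoys_per_km2: float = 1.5
    contour_decoys_per_km2: float = 0.8
    field_radius_m: tuple[float, float] = (120.0, 320.0)
    mire_radius_m: tuple[float, float] = (150.0, 450.0)
    water_radius_m: tuple[float, float] = (200.0, 600.0)

    def __post_init__(self) -> None:
        for name in ("field_area_fraction", "mire_area_fraction",
                     "water_area_fraction"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        for name in ("road_density_km_per_km2", "watercourse_density_km_per_km2",
                     "text_decoys_per_km2", "contour_decoys_per_km2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ChangeParams:
    """Controlled between-epoch change.

    ``field_loss_fraction`` — fraction of total field area removed (whole
    parcels); ``ditch_density_gain_per_km2`` — added watercourse length in
    km per km² of scene; ``road_added_km`` — added road length;
    ``mire_flip_fraction`` — fraction of mire area removed (drained mires
    reclassified away).
    """

    field_loss_fraction: float = 0.0
    ditch_density_gain_per_km2: float = 0.0
    road_added_km: float = 0.0
    mire_flip_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.field_loss_fraction <= 1:
            raise ValueError("field_loss_fraction must lie in [0, 1]")
        if not 0 <= self.mire_flip_fraction <= 1:
            raise ValueError("mire_flip_fraction must lie in [0, 1]")
        if self.ditch_density_gain_per_km2 < 0 or self.road_added_km < 0:
            raise ValueError("densities must be >= 0")


@dataclass
class SynthScene:
    """Vector ground truth for one epoch of one synthetic sheet."""

    extent: tuple[float, float]          # (width_m, height_m)
    fields: list[Polygon] = field(default_factory=list)
    mires: list[Polygon] = field(default_factory=list)
    water_bodies: list[Polygon] = field(default_factory=list)
    roads: list[LineString] = field(default_factory=list)
    watercourses: list[LineString] = field(default_factory=list)
    text_decoys: list[TextDecoy] = field(default_factory=list)
    contour_decoys: list[LineString] = field(default_factory=list)
    crs_id: str = "local"
    seed: int = 0

    @property
    def extent_box(self) -> Polygon:
        return box(0.0, 0.0, self.extent[0], self.extent[1])

    @property
    def area_km2(self) -> float:
        return self.extent[0] * self.extent[1] / 1e6

    def total_area(self, layer: str) -> float:
        return float(sum(g.area for g in getattr(self, layer)))

    def total_length(self, layer: str) -> float:
        return float(sum(g.length for g in getattr(self, layer)))

    def polygon_layers(self) -> dict[str, list[Polygon]]:
        return {"fields": self.fields, "mires": self.mires,
                "water_bodies": self.water_bodies}

    def line_layers(self) -> dict[str, list[LineString]]:
        return {"roads": self.roads, "watercourses": self.watercourses}

    def to_layerset(self, epoch: str = "truth"):
        """Ground-truth vector layers (one layer per class) for export."""
        from ..vectorize import VectorLayerSet

        return VectorLayerSet(
            epoch=epoch,
            polygons={k: list(v) for k, v in self.polygon_layers().items()},
            lines={k: list(v) for k, v in self.line_layers().items()},
            crs_id=self.crs_id,
        )


# --------------------------------------------------------------------------
# geometry generators

_GLYPHS = "ABCDEFHIJKLMNOPRSTUVYÄÖabcdefhijklmnoprstuvy"


def _blob(rng, cx, cy, r_min, r_max, n_vertices=12, roughness=0.45) -> Polygon:
    """Rounded star polygon: a natural-looking mire/lake outline."""
    r0 = rng.uniform(r_min, r_max)
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = r0 * (1.0 - roughness + roughness * 2 * rng.random(n_vertices))
    xs = cx + radii * np.cos(angles)
    ys = cy + radii * np.sin(angles)
    poly = Polygon(zip(xs, ys))
    if not poly.is_valid:
        poly = poly.buffer(0)
    # smooth corners; keep only the largest part if buffering split it
    poly = poly.buffer(r0 * 0.15).buffer(-r0 * 0.15)
    if poly.geom_type == "MultiPolygon":
        poly = max(poly.geoms, key=lambda g: g.area)
    return poly


def _parcel(rng, cx, cy, r_min, r_max) -> Polygon:
    """Rotated rectangle: a field parcel."""
    half_w = rng.uniform(r_min, r_max)
    half_h = half_w * rng.uniform(0.4, 1.0)
    angle = rng.uniform(-np.pi / 6, np.pi / 6)
    rect = box(cx - half_w, cy - half_h, cx + half_w, cy + half_h)
    return affinity.rotate(rect, np.degrees(angle), origin=(cx, cy))


def _wiggly_line(rng, extent, step_m=120.0, heading_jitter=0.35) -> LineString:
    """A brook-like polyline crossing part of the scene; simple by design
    because the heading drifts only slightly between steps."""
    w, h = extent
    x = rng.uniform(0, w)
    y = rng.uniform(0, h)
    heading = rng.uniform(0, 2 * np.pi)
    pts = [(x, y)]
    n_steps = int(rng.integers(8, 25))
    for _ in range(n_steps):
        heading += rng.uniform(-heading_jitter, heading_jitter)
        x += step_m * np.cos(heading)
        y += step_m * np.sin(heading)
        pts.append((x, y))
    return LineString(pts)


def _crossing_road(rng, extent) -> LineString:
    """A road running between two scene borders with slight bends."""
    w, h = extent
    sides = rng.choice(4, size=2, replace=False)

    def border_point(side):
        if side == 0:
            return (0.0, rng.uniform(0, h))
        if side == 1:
            return (w, rng.uniform(0, h))
        if side == 2:
            return (rng.uniform(0, w), 0.0)
        return (rng.uniform(0, w), h)

    p0 = np.array(border_point(sides[0]))
    p1 = np.array(border_point(sides[1]))
    n_mid = int(rng.integers(2, 5))
    ts = np.sort(rng.uniform(0.15, 0.85, n_mid))
    direction = p1 - p0
    normal = np.array([-direction[1], direction[0]])
    norm = np.linalg.norm(normal)
    normal = normal / norm if norm else normal
    pts = [tuple(p0)]
    for t in ts:
        offset = rng.uniform(-0.06, 0.06) * norm
        pts.append(tuple(p0 + t * direction + offset * normal))
    pts.append(tuple(p1))
    line = LineString(pts)
    return line if line.is_simple else LineString([tuple(p0), tuple(p1)])


def _clip_line(line: LineString, clip: Polygon) -> list[LineString]:
    g = line.intersection(clip)
    if g.is_empty:
        return []
    if g.geom_type == "LineString":
        return [g]
    return [p for p in getattr(g, "geoms", []) if p.geom_type == "LineString"]


def _place_polygons(rng, scene: SynthScene, layer: str, target_fraction: float,
                    radius_range, maker) -> None:
    """Rejection-sample non-overlapping polygons until the areal target."""
    w, h = scene.extent
    target = target_fraction * w * h
    margin = 30.0  # separation between areal classes, meters
    placed = [g for lay in scene.polygon_layers().values() for g in lay]
    tree_geoms = list(placed)
    out = getattr(scene, layer)
    total = 0.0
    attempts = 0
    max_attempts = 400 + int(40 * target / max(radius_range[0] ** 2, 1.0))
    while total < target and attempts < max_attempts:
        attempts += 1
        cx, cy = rng.uniform(0, w), rng.uniform(0, h)
        poly = maker(rng, cx, cy, *radius_range)
        poly = poly.intersection(scene.extent_box)
        if poly.is_empty or poly.geom_type != "Polygon" or poly.area < 1e4:
            continue
        remaining = target - total
        if poly.area > remaining:
            # shrink the final polygon toward the areal target
            factor = max(0.35, np.sqrt(remaining / poly.area))
            poly = affinity.scale(poly, factor, factor, origin="centroid")
            poly = poly.intersection(scene.extent_box)
            if poly.is_empty or poly.geom_type != "Polygon" or poly.area < 1e4:
                continue
        grown = poly.buffer(margin)
        if any(grown.intersects(other) for other in tree_geoms):
            continue
        out.append(poly)
        tree_geoms.append(poly)
        total += poly.area


def _add_lines(rng, scene, layer: str, target_km: float, maker) -> float:
    """Add polylines until the target total length; trim the last one."""
    target_m = target_km * 1000.0
    out = getattr(scene, layer)
    added = 0.0
    attempts = 0
    while added < target_m and attempts < 2000:
        attempts += 1
        for part in _clip_line(maker(rng, scene.extent), scene.extent_box):
            if part.length < 50.0:
                continue
            if added + part.length > target_m:
                part = substring(part, 0.0, target_m - added)
                if part.geom_type != "LineString" or part.length <= 0:
                    break
            out.append(part)
            added += part.length
            if added >= target_m:
                break
    return added


def generate_scene(
    extent_km: tuple[float, float],
    params: SceneParams | None = None,
    seed: int = 0,
) -> SynthScene:
    """Generate one epoch of synthetic vector ground truth.

    Deterministic under ``seed``. Areal classes (water bodies, mires,
    fields, placed in that order) are mutually non-overlapping; linear
    classes may cross anything, as on the real maps.
    """
    if extent_km[0] <= 0 or extent_km[1] <= 0:
        raise ValueError("extent must be positive")
    params = params or SceneParams()
    rng = np.random.default_rng(seed)
    extent = (extent_km[0] * 1000.0, extent_km[1] * 1000.0)
    scene = SynthScene(extent=extent, seed=seed)

    _place_polygons(rng, scene, "water_bodies", params.water_area_fraction,
                    params.water_radius_m, _blob)
    _place_polygons(rng, scene, "mires", params.mire_area_fraction,
                    params.mire_radius_m, _blob)
    _place_polygons(rng, scene, "fields", params.field_area_fraction,
                    params.field_radius_m, _parcel)

    area_km2 = scene.area_km2
    _add_lines(rng, scene, "roads",
               params.road_density_km_per_km2 * area_km2, _crossing_road)
    _add_lines(rng, scene, "watercourses",
               params.watercourse_density_km_per_km2 * area_km2, _wiggly_line)

    n_text = rng.poisson(params.text_decoys_per_km2 * area_km2)
    for _ in range(n_text):
        n_chars = int(rng.integers(3, 9))
        text = "".join(rng.choice(list(_GLYPHS), n_chars))
        scene.text_decoys.append(
            TextDecoy(text, float(rng.uniform(0, extent[0])),
                      float(rng.uniform(0, extent[1])),
                      size_px=int(rng.integers(10, 16)))
        )
    n_contours = rng.poisson(params.contour_decoys_per_km2 * area_km2)
    for _ in range(n_contours):
        for part in _clip_line(_wiggly_line(rng, extent, step_m=80.0,
                                            heading_jitter=0.5),
                               scene.extent_box):
            scene.contour_decoys.append(part)
    return scene


# --------------------------------------------------------------------------
# epoch evolution


def _remove_fraction(rng, polygons: list[Polygon], fraction: float) -> list[Polygon]:
    """Remove whole polygons until ~fraction of total area is gone."""
    if fraction >= 1.0:
        return []
    if fraction <= 0.0 or not polygons:
        return list(polygons)
    total = sum(g.area for g in polygons)
    target = fraction * total
    order = rng.permutation(len(polygons))
    removed = 0.0
    keep = set(range(len(polygons)))
    for idx in order:
        area = polygons[idx].area
        if removed + area <= target:
            keep.discard(int(idx))
            removed += area
    # one final parcel if it lands closer to the target than stopping short
    best = min(
        keep, default=None,
        key=lambda i: abs(removed + polygons[i].area - target),
    )
    if best is not None and abs(
        removed + polygons[best].area - target
    ) < abs(removed - target):
        keep.discard(best)
    return [polygons[i] for i in sorted(keep)]


def _ditches_in_mires(rng, scene: SynthScene, target_m: float) -> list[LineString]:
    """Straight parallel drainage ditches clipped to mire polygons."""
    ditches: list[LineString] = []
    added = 0.0
    mires = sorted(scene.mires, key=lambda g: -g.area)
    spacing = 60.0  # meters between parallel ditches
    for mire in mires or []:
        if added >= target_m:
            break
        angle = rng.uniform(0, np.pi)
        c = np.cos(angle), np.sin(angle)
        minx, miny, maxx, maxy = mire.bounds
        diag = float(np.hypot(maxx - minx, maxy - miny))
        cx, cy = (minx + maxx) / 2, (miny + maxy) / 2
        n_lines = int(diag // spacing) + 1
        for i in range(-n_lines, n_lines + 1):
            off = i * spacing
            # line through (cx, cy) + off * normal, direction c
            nx, ny = -c[1], c[0]
            p0 = (cx + nx * off - c[0] * diag, cy + ny * off - c[1] * diag)
            p1 = (cx + nx * off + c[0] * diag, cy + ny * off + c[1] * diag)
            for part in _clip_line(LineString([p0, p1]), mire.buffer(-15.0)):
                if part.length < 40.0:
                    continue
                if added + part.length > target_m:
                    part = substring(part, 0.0, target_m - added)
                ditches.append(part)
                added += part.length
                if added >= target_m:
                    return ditches
    # no (or not enough) mires: finish with straight field/forest ditches
    while added < target_m - 1.0:
        x0 = rng.uniform(0, scene.extent[0])
        y0 = rng.uniform(0, scene.extent[1])
        heading = rng.uniform(0, 2 * np.pi)
        length = min(rng.uniform(300, 900), target_m - added)
        cand = LineString([(x0, y0), (x0 + length * np.cos(heading),
                                      y0 + length * np.sin(heading))])
        for part in _clip_line(cand, scene.extent_box):
            if added + part.length > target_m:
                part = substring(part, 0.0, target_m - added)
            if part.length <= 0:
                continue
            ditches.append(part)
            added += part.length
    return ditches


def evolve_scene(scene: SynthScene, change: ChangeParams) -> SynthScene:
    """Produce the later epoch of a scene under the configured change.

    Unchanged layers are shared structurally (copied lists, same
    geometries). Watercourse length strictly increases whenever
    ``ditch_density_gain_per_km2 > 0``.
    """
    rng = np.random.default_rng(change.seed)
    out = SynthScene(
        extent=scene.extent,
        fields=_remove_fraction(rng, scene.fields, change.field_loss_fraction),
        mires=_remove_fraction(rng, scene.mires, change.mire_flip_fraction),
        water_bodies=list(scene.water_bodies),
        roads=list(scene.roads),
        watercourses=list(scene.watercourses),
        text_decoys=list(scene.text_decoys),
        contour_decoys=list(scene.contour_decoys),
        crs_id=scene.crs_id,
        seed=scene.seed,
    )
    ditch_target = change.ditch_density_gain_per_km2 * scene.area_km2 * 1000.0
    if ditch_target > 0:
        out.watercourses.extend(_ditches_in_mires(rng, out, ditch_target))
    if change.road_added_km > 0:
        _add_lines(rng, out, "roads", change.road_added_km, _crossing_road)
    return out
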