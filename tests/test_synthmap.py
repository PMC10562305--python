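import numpy as np
import pytest
from shapely.geometry import Polygon, box

from mapchange.synthmap import (ChangeParams, RenderStyle, SceneParams,
                                SynthScene, evolve_scene, generate_scene,
                                render_sheet)
from mapchange.synthmap.render import LABELS, rasterize_labels


class TestGenerateScene:
    def test_zero_densities_give_empty_scene(self):
        params = SceneParams(
            field_area_fraction=0, mire_area_fraction=0, water_area_fraction=0,
            road_density_km_per_km2=0, watercourse_density_km_per_km2=0,
            text_decoys_per_km2=0, contour_decoys_per_km2=0,
        )
        scene = generate_scene((2, 2), params, seed=1)
        assert not scene.fields and not scene.mires and not scene.water_bodies
        assert not scene.roads and not scene.watercourses
        assert not scene.text_decoys and not scene.contour_decoys

    def test_deterministic_under_seed(self):
        a = generate_scene((2, 2), seed=5)
        b = generate_scene((2, 2), seed=5)
        assert [g.wkt for g in a.fields] == [g.wkt for g in b.fields]
        assert [g.wkt for g in a.watercourses] == [g.wkt for g in b.watercourses]
        assert a.text_decoys == b.text_decoys

    def test_field_area_in_density_band(self):
        scene = generate_scene((5, 5), seed=7)
        target = SceneParams().field_area_fraction * 25e6
        total = scene.total_area("fields")
        assert 0.8 * target <= total <= 1.2 * target

    def test_geometries_within_extent(self, small_scene):
        extent = small_scene.extent_box.buffer(1e-6)
        for layer in ("fields", "mires", "water_bodies", "roads", "watercourses"):
            for geom in getattr(small_scene, layer):
                assert extent.contains(geom)

    def test_areal_classes_disjoint(self, small_scene):
        layers = list(small_scene.polygon_layers().values())
        flat = [g for lay in layers for g in lay]
        for i, a in enumerate(flat):
            for b in flat[i + 1 :]:
                assert a.intersection(b).area == pytest.approx(0.0, abs=1e-6)

    def test_lines_are_simple(self, small_scene):
        for line in small_scene.roads + small_scene.watercourses:
            assert line.is_simple

    def test_nonpositive_extent_rejected(self):
        with pytest.raises(ValueError):
            generate_scene((0, 2), seed=0)


class TestEvolveScene:
    def test_zero_change_is_identity(self, small_scene):
        out = evolve_scene(small_scene, ChangeParams())
        assert [g.wkt for g in out.fields] == [g.wkt for g in small_scene.fields]
        assert len(out.watercourses) == len(small_scene.watercourses)
        assert len(out.roads) == len(small_scene.roads)

    def test_total_field_loss(self, small_scene):
        out = evolve_scene(small_scene, ChangeParams(field_loss_fraction=1.0))
        assert out.fields == []

    def test_partial_field_loss_fraction(self, small_scene):
        out = evolve_scene(
            small_scene, ChangeParams(field_loss_fraction=0.3, seed=2)
        )
        removed = 1 - out.total_area("fields") / small_scene.total_area("fields")
        assert removed == pytest.approx(0.3, abs=0.08)

    def test_ditch_gain_length(self):
        scene = generate_scene((5, 5), seed=7)
        out = evolve_scene(
            scene, ChangeParams(ditch_density_gain_per_km2=2.0, seed=3)
        )
        gain = out.total_length("watercourses") - scene.total_length("watercourses")
        assert gain == pytest.approx(50_000.0, rel=0.10)

    def test_watercourse_length_strictly_increases(self, small_scene):
        out = evolve_scene(
            small_scene, ChangeParams(ditch_density_gain_per_km2=0.1, seed=1)
        )
        assert out.total_length("watercourses") > small_scene.total_length(
            "watercourses"
        )


class TestRenderSheet:
    def test_empty_scene_renders_background(self):
        scene = SynthScene(extent=(340.0, 340.0), seed=0)
        style = RenderStyle(noise_sd=0.0)
        rgb, labels = render_sheet(scene, style)
        assert (labels.data == 0).all()
        assert (rgb.data == np.array(style.background_color)).all()
        assert rgb.data.dtype == np.uint8

    def test_label_area_matches_polygon_area(self):
        # one 500 x 500 m field at 1.7 m/px
        scene = SynthScene(extent=(1000.0, 1000.0), seed=0)
        scene.fields.append(box(200.0, 200.0, 700.0, 700.0))
        style = RenderStyle(noise_sd=0.0)
        _, labels = render_sheet(scene, style)
        count = int((labels.data == LABELS["fields"]).sum())
        expected = 250_000 / 1.7**2
        perimeter_px = 4 * 500 / 1.7
        assert abs(count - expected) <= perimeter_px

    def test_color_cast_scales_bands(self):
        scene = SynthScene(extent=(340.0, 340.0), seed=0)
        plain = RenderStyle(noise_sd=0.0)
        cast = RenderStyle(noise_sd=0.0, color_cast=(1.2, 1.0, 1.0))
        rgb0, _ = render_sheet(scene, plain)
        rgb1, _ = render_sheet(scene, cast)
        expected = np.minimum(rgb0.data[..., 0].astype(float) * 1.2, 255)
        assert np.allclose(rgb1.data[..., 0], np.floor(expected), atol=1)

    def test_decoys_absent_from_labels(self, small_scene):
        assert small_scene.text_decoys or small_scene.contour_decoys
        style = RenderStyle(noise_sd=0.0)
        stripped = SynthScene(
            extent=small_scene.extent, fields=small_scene.fields,
            mires=small_scene.mires, water_bodies=small_scene.water_bodies,
            roads=small_scene.roads, watercourses=small_scene.watercourses,
            seed=small_scene.seed,
        )
        _, with_decoys = render_sheet(small_scene, style)
        _, without = render_sheet(stripped, style)
        assert np.array_equal(with_decoys.data, without.data)

    def test_labels_converge_to_vector_area_with_resolution(self):
        scene = SynthScene(extent=(1000.0, 1000.0), seed=0)
        scene.fields.append(
            Polygon([(100, 100), (800, 150), (700, 800), (150, 700)])
        )
        truth = scene.fields[0].area
        errors = []
        for px in (3.4, 0.85):
            labels = rasterize_labels(scene, RenderStyle(pixel_size_m=px))
            area = (labels.data == LABELS["fields"]).sum() * px**2
            errors.append(abs(area - truth) / truth)
        assert errors[1] < errors[0]
        assert errors[1] < 0.01

    def test_same_seed_same_sheet(self, small_scene):
        a, _ = render_sheet(small_scene, seed=4)
        b, _ = render_sheet(small_scene, seed=4)
        assert np.array_equal(a.data, b.data)
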