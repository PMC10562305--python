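import numpy as np
import pandas as pd
import pytest
from shapely import affinity
from shapely.geometry import LineString, box

from mapchange.change_analysis import (ChangeGrid, aggregate_to_grid,
                                       build_grid, change_summary,
                                       extreme_cells, length_within)
from mapchange.vectorize import VectorLayerSet


def _layers(epoch="a", polygons=None, lines=None):
    return VectorLayerSet(epoch=epoch, polygons=polygons or {},
                          lines=lines or {})


class TestBuildGrid:
    def test_square_kilometre(self):
        grid = build_grid((0, 0, 1000, 1000))
        assert grid.n_cells == 4

    def test_ten_km_sheet(self):
        grid = build_grid((0, 0, 10_000, 10_000))
        assert grid.n_cells == 400

    def test_snapping_extends_past_extent(self):
        grid = build_grid((100, 100, 1200, 800))
        assert grid.origin_x == 0.0 and grid.origin_y == 1000.0
        assert (grid.nx, grid.ny) == (3, 2)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_grid((0, 0, 1000, 1000), cell_size_m=0)
        with pytest.raises(ValueError):
            build_grid((0, 0, -5, 10))


class TestAggregate:
    def test_polygon_filling_one_cell(self):
        grid = build_grid((0, 0, 1000, 1000))
        layers = _layers(polygons={"fields": [box(0, 500, 500, 1000)]})
        out = aggregate_to_grid(layers, grid)
        values = out.measures["fields"].to_numpy()
        assert values[0] == pytest.approx(250_000.0)
        assert values[1:].sum() == pytest.approx(0.0)

    def test_line_split_across_cells(self):
        grid = build_grid((0, 0, 1000, 500))
        line = LineString([(200, 250), (900, 250)])  # 300 m / 400 m split
        out = aggregate_to_grid(grid=grid, layers=_layers(
            lines={"watercourses": [line]}))
        values = out.measures["watercourses"].to_numpy()
        assert values[0] == pytest.approx(300.0)
        assert values[1] == pytest.approx(400.0)

    def test_crs_mismatch_rejected(self):
        grid = build_grid((0, 0, 1000, 1000), crs_id="EPSG:3067")
        with pytest.raises(ValueError, match="CRS"):
            aggregate_to_grid(_layers(), grid)

    def test_empty_layers_all_zero(self):
        grid = build_grid((0, 0, 1000, 1000))
        out = aggregate_to_grid(_layers(), grid)
        assert (out.measures.to_numpy() == 0).all()

    def test_totals_conserved(self, small_scene):
        layers = _layers(
            polygons={"fields": small_scene.fields, "mires": small_scene.mires},
            lines={"watercourses": small_scene.watercourses},
        )
        grid = build_grid((0, 0, *small_scene.extent))
        out = aggregate_to_grid(layers, grid)
        assert out.measures["fields"].sum() == pytest.approx(
            small_scene.total_area("fields"), rel=1e-6)
        assert out.measures["watercourses"].sum() == pytest.approx(
            small_scene.total_length("watercourses"), rel=1e-6)

    def test_translation_invariance(self, small_scene):
        dx, dy = 12_500.0, -7_000.0  # multiples of the cell size
        layers = _layers(polygons={"fields": small_scene.fields})
        grid = build_grid((0, 0, *small_scene.extent))
        base = aggregate_to_grid(layers, grid)
        moved = _layers(polygons={"fields": [
            affinity.translate(g, dx, dy) for g in small_scene.fields]})
        grid2 = build_grid((dx, dy, small_scene.extent[0] + dx,
                            small_scene.extent[1] + dy))
        out = aggregate_to_grid(moved, grid2)
        assert np.allclose(base.measures["fields"], out.measures["fields"])


class TestLengthWithin:
    def test_fully_inside(self):
        assert length_within([LineString([(0, 0), (100, 0)])],
                             [box(-10, -10, 110, 10)]) == pytest.approx(100.0)

    def test_fully_outside(self):
        assert length_within([LineString([(0, 50), (100, 50)])],
                             [box(0, 0, 100, 10)]) == 0.0

    def test_partial_overlap(self):
        line = LineString([(0, 5), (1000, 5)])
        assert length_within([line], [box(100, 0, 350, 10)]) == pytest.approx(250.0)


def _grid_with(values_by_class):
    grid = build_grid((0, 0, 1000, 1000))
    for name, values in values_by_class.items():
        grid.measures[name] = values
    return grid


class TestChangeSummary:
    def test_identical_epochs_no_change(self):
        a = _grid_with({"fields": [1e5, 2e5, 0, 0]})
        b = _grid_with({"fields": [1e5, 2e5, 0, 0]})
        a.epoch, b.epoch = "1965", "1985"
        table = change_summary([a, b]).table
        assert (table["gain"] == 0).all()
        assert (table["loss"] == 0).all()
        assert (table["change"] == 0).all()

    def test_per_cell_accounting(self):
        a = _grid_with({"fields": [0.0, 1.0, 0, 0]})
        b = _grid_with({"fields": [3.0, 0.0, 0, 0]})
        row = change_summary([a, b]).table.set_index("class_name").loc["fields"]
        assert row["gain"] == 3.0 and row["loss"] == 1.0 and row["change"] == 2.0

    def test_change_equals_gain_minus_loss_and_total_diff(self):
        rng = np.random.default_rng(0)
        grids = []
        for epoch in ("1", "2", "3"):
            g = build_grid((0, 0, 2000, 2000))
            for name in g.measures.columns:
                g.measures[name] = rng.uniform(0, 1e5, g.n_cells)
            g.epoch = epoch
            grids.append(g)
        table = change_summary(grids).table
        assert np.allclose(table["change"], table["gain"] - table["loss"])
        assert np.allclose(table["change"],
                           table["total_second"] - table["total_first"])

    def test_grid_mismatch_rejected(self):
        a = build_grid((0, 0, 1000, 1000))
        b = build_grid((0, 0, 2000, 1000))
        with pytest.raises(ValueError):
            change_summary([a, b])

    def test_single_epoch_rejected(self):
        with pytest.raises(ValueError):
            change_summary([build_grid((0, 0, 1000, 1000))])


class TestExtremeCells:
    def test_all_zero_deltas(self):
        a = _grid_with({"fields": [0, 0, 0, 0]})
        out = extreme_cells(a, a, "fields", k=2)
        assert (out["delta"] == 0).all()

    def test_single_nonzero_ranks_first(self):
        a = _grid_with({"fields": [0, 0, 0, 0]})
        b = _grid_with({"fields": [0, 0, 5.0, 0]})
        out = extreme_cells(a, b, "fields", k=4)
        assert out["cell"].iloc[0] == 2

    def test_sort_by_magnitude(self):
        a = _grid_with({"fields": [0, 0, 0, 0]})
        b = _grid_with({"fields": [5.0, -7.0, 2.0, 0.0]})
        out = extreme_cells(a, b, "fields", k=3)
        assert list(out["delta"]) == [-7.0, 5.0, 2.0]

    def test_unknown_class_rejected(self):
        a = _grid_with({"fields": [0, 0, 0, 0]})
        with pytest.raises(ValueError):
            extreme_cells(a, a, "bogus")
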