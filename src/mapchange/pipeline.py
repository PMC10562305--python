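"""End-to-end orchestration: synth -> preprocess -> segment -> postprocess ->
vectorize -> change.

Two run modes:

* ``"oracle"`` — the rendered ground-truth label rasters feed the
  postprocess/vectorize/change stages directly, bypassing the network.
  This isolates the geometry stages: with it, the recovered field-area
  loss and ditch-length gain must match the configured scene change.
* ``"full"`` — a segmentation model is trained on tiles of the first-epoch
  sheet and predicts every epoch's sheet before post-processing.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .change_analysis import (aggregate_to_grid, build_grid, change_summary,
                              length_within, ChangeSummary)
from .georaster import GeoRaster
from .postprocess import postprocess_stack
from .preprocess import estimate_white_reference, white_balance
from .segmentation import TrainConfig, predict_sheet, train_model
from .segmentation.train import desk_scale_config
from .synthmap import (ChangeParams, RenderStyle, SceneParams, evolve_scene,
                       generate_scene, render_sheet)
from .tiling import build_tile_grid, extract_tiles, split_dataset
from .vectorio import write_layerset
from .vectorize import vectorize_stack

__all__ = ["PipelineConfig", "run_pipeline", "report", "find_white_patch"]


@dataclass
class PipelineConfig:
    extent_km: tuple[float, float] = (5.0, 5.0)
    epochs: tuple[str, ...] = ("1965", "1985")
    scene: SceneParams = dc_field(default_factory=SceneParams)
    style: RenderStyle = dc_field(default_factory=RenderStyle)
    change: ChangeParams = dc_field(
        default_factory=lambda: ChangeParams(
            field_loss_fraction=0.12, ditch_density_gain_per_km2=1.5,
            road_added_km=5.0
        )
    )
    mode: str = "oracle"                   # "oracle" | "full"
    train: TrainConfig | None = None       # defaults to desk_scale_config
    tile_px: int = 64
    grid_cell_m: float = 500.0
    min_area_m2: float = 1000.0
    out_dir: str | Path = "pipeline_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("oracle", "full"):
            raise ValueError("mode must be 'oracle' or 'full'")
        if len(self.epochs) < 2:
            raise ValueError("need at least two epochs of data")


def _write_config_yaml(config: PipelineConfig, path: Path) -> None:
    import dataclasses

    import yaml

    def plain(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [plain(v) for v in obj]
        if isinstance(obj, Path):
            return str(obj)
        return obj

    path.write_text(yaml.safe_dump(plain(config), sort_keys=False))


def find_white_patch(sheet: GeoRaster, patch_px: int = 32) -> tuple[int, int, int, int]:
    """Locate a bright, uniform patch along the sheet border.

    Stands in for the manual choice of the unprinted white reference area:
    candidate windows along all four edges are scored by mean brightness
    minus variability.
    """
    h, w = sheet.shape
    best, best_score = None, -np.inf
    candidates = []
    for c0 in range(0, w - patch_px + 1, patch_px):
        candidates += [(0, c0), (h - patch_px, c0)]
    for r0 in range(0, h - patch_px + 1, patch_px):
        candidates += [(r0, 0), (r0, w - patch_px)]
    for r0, c0 in candidates:
        patch = sheet.data[r0 : r0 + patch_px, c0 : c0 + patch_px].astype(float)
        score = patch.mean() - 4.0 * patch.std(axis=(0, 1)).mean()
        if score > best_score:
            best_score, best = score, (r0, c0, patch_px, patch_px)
    return best


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages for every epoch; returns the run manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_seed": config.seed, "mode": config.mode,
                      "stages": [], "artifacts": {}, "metrics": {}}

    def stage(name):
        manifest["stages"].append({"stage": name, "t": time.time()})

    try:
        stage("synth")
        _write_config_yaml(config, out_dir / "config.yaml")
        scenes = [generate_scene(config.extent_km, config.scene, config.seed)]
        for i in range(1, len(config.epochs)):
            change = ChangeParams(
                field_loss_fraction=config.change.field_loss_fraction,
                ditch_density_gain_per_km2=config.change.ditch_density_gain_per_km2,
                road_added_km=config.change.road_added_km,
                mire_flip_fraction=config.change.mire_flip_fraction,
                seed=config.seed + 1000 + i,
            )
            scenes.append(evolve_scene(scenes[-1], change))
        sheets, truths = [], []
        for i, scene in enumerate(scenes):
            rgb, labels = render_sheet(scene, config.style, seed=config.seed + i)
            sheets.append(rgb)
            truths.append(labels)
            rgb.write(out_dir / f"sheet_{config.epochs[i]}.tif")
            labels.write(out_dir / f"labels_{config.epochs[i]}.tif")
            write_layerset(
                scene.to_layerset(config.epochs[i]), out_dir / "truth_vectors"
            )

        stage("preprocess")
        balanced = []
        for rgb in sheets:
            ref = estimate_white_reference(rgb, find_white_patch(rgb))
            balanced.append(white_balance(rgb, ref))

        if config.mode == "full":
            stage("train")
            train_cfg = config.train or desk_scale_config(seed=config.seed)
            grid = build_tile_grid(balanced[0].shape, config.tile_px,
                                   config.tile_px)
            tiles = extract_tiles(balanced[0].data, grid)
            labels = extract_tiles(truths[0].data, grid)
            split = split_dataset(grid, seed=config.seed, block_tiles=2)
            model, log = train_model(train_cfg, split, tiles, labels)
            log.to_csv(out_dir / "training_log.csv", index=False)
            manifest["artifacts"]["training_log"] = str(out_dir / "training_log.csv")
            manifest["metrics"]["final_val_macro_f1"] = float(
                log["val_macro_f1"].iloc[-1]
            )
            stage("predict")
            label_rasters = []
            for sheet in balanced:
                pgrid = build_tile_grid(
                    sheet.shape, config.tile_px,
                    max(1, config.tile_px // 2), 3 * config.tile_px // 4,
                )
                label_rasters.append(predict_sheet(model, sheet, pgrid))
        else:
            label_rasters = truths

        stage("postprocess")
        stacks = [postprocess_stack(lr) for lr in label_rasters]

        stage("vectorize")
        layersets = []
        for epoch, stack, raster in zip(config.epochs, stacks, label_rasters):
            layers = vectorize_stack(stack, raster.transform, epoch=epoch,
                                     crs_id=raster.crs_id,
                                     min_area_m2=config.min_area_m2)
            write_layerset(layers, out_dir / "vectors")
            layersets.append(layers)

        stage("change")
        extent = (0.0, 0.0, config.extent_km[0] * 1000, config.extent_km[1] * 1000)
        scaffold = build_grid(extent, config.grid_cell_m)
        grids = [aggregate_to_grid(layers, scaffold) for layers in layersets]
        summary = change_summary(grids)
        context = pd.DataFrame.from_records([
            dict(
                epoch=layers.epoch,
                length_in_fields=length_within(
                    layers.lines.get("watercourses", []),
                    layers.polygons.get("fields", []),
                ),
                length_in_mires=length_within(
                    layers.lines.get("watercourses", []),
                    layers.polygons.get("mires", []),
                ),
            )
            for layers in layersets
        ])
        summary = ChangeSummary(summary.table, context)
        summary.table.to_csv(out_dir / "change_summary.csv", index=False)
        context.to_csv(out_dir / "watercourse_context.csv", index=False)
        manifest["artifacts"]["change_summary"] = str(out_dir / "change_summary.csv")
        manifest["artifacts"]["watercourse_context"] = str(
            out_dir / "watercourse_context.csv"
        )
        manifest["summary"] = summary
        manifest["scenes"] = scenes
        manifest["layersets"] = layersets
        return manifest
    except Exception as exc:
        failed = manifest["stages"][-1]["stage"] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {exc}") from exc


def report(manifest: dict) -> str:
    """Human-readable change report from a completed run manifest."""
    missing = [k for k in ("summary",) if k not in manifest]
    if missing:
        raise ValueError(f"incomplete manifest, missing: {missing}")
    summary: ChangeSummary = manifest["summary"]
    lines = ["Land use and land cover change summary", ""]
    table = summary.table.copy()
    areal = table["class_name"].isin(("fields", "mires", "water_bodies"))
    for col in ("total_first", "total_second", "gain", "loss", "change"):
        table.loc[areal, col] = table.loc[areal, col] / 1e6     # m² -> km²
        table.loc[~areal, col] = table.loc[~areal, col] / 1e3   # m  -> km
    table["unit"] = np.where(areal, "km²", "km")
    lines.append(table.round(2).to_string(index=False))
    if summary.watercourse_context is not None:
        lines += ["", "Watercourse length within fields/mires (km):"]
        ctx = summary.watercourse_context.copy()
        ctx[["length_in_fields", "length_in_mires"]] = (
            ctx[["length_in_fields", "length_in_mires"]] / 1e3
        )
        lines.append(ctx.round(2).to_string(index=False))
    if "final_val_macro_f1" in manifest.get("metrics", {}):
        lines += ["", f"Validation macro F1: "
                      f"{manifest['metrics']['final_val_macro_f1']:.3f}"]
    return "\n".join(lines)
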