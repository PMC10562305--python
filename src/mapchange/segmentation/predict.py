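"""Full-sheet inference with overlapping tiles and edge discarding."""

from __future__ import annotations

import numpy as np

from .model import UNet
from .train import prepare_images
from ..georaster import GeoRaster
from ..tiling import TileGrid, build_tile_grid, demosaic_predictions, extract_tiles

__all__ = ["predict_tiles", "predict_sheet"]


def predict_tiles(model: UNet, images: np.ndarray, batch_size: int = 8) -> np.ndarray:
    """Argmax label tiles for a (N, H, W, 3) uint8 image stack."""
    return model.predict_labels(prepare_images(images), batch_size)


def predict_sheet(
    model: UNet,
    sheet: GeoRaster,
    grid: TileGrid | None = None,
    batch_size: int = 8,
) -> GeoRaster:
    """Predict a full sheet by mosaicked inference.

    Default grid: the sheet tiled with 256-px tiles, 128-px stride, keeping
    the central 192 px of every prediction. Output georeference equals the
    input's.
    """
    if grid is None:
        grid = build_tile_grid(sheet.shape, tile_px=256, stride_px=128, keep_px=192)
    tiles = extract_tiles(sheet.data, grid)
    pred = predict_tiles(model, tiles, batch_size)
    labels = demosaic_predictions(pred, grid)
    return sheet.like(labels)
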