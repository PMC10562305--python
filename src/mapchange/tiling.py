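"""Tiling, leakage-free dataset splitting, and overlap de-mosaicking.

Sheets are far larger than what a segmentation network consumes, so they
are cut into square tiles. Training uses non-overlapping tiles; inference
uses overlapping tiles (stride < tile) and keeps only the central window of
each prediction, because the model is least reliable near tile edges. The
de-mosaicking step reassembles those central windows into a full sheet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TileGrid", "DatasetSplit", "build_tile_grid", "split_dataset",
           "extract_tiles", "demosaic_predictions"]


def _axis_origins(extent: int, tile: int, stride: int) -> list[int]:
    """Tile origins along one axis; the last tile is shifted inward to fit."""
    origins = list(range(0, extent - tile + 1, stride))
    if origins[-1] != extent - tile:
        origins.append(extent - tile)
    return origins


@dataclass(frozen=True)
class TileGrid:
    """Tiling geometry shared by training and mosaicked inference.

    ``keep_px`` is the central window each tile contributes when
    de-mosaicking (192 px for 256-px tiles with 128-px stride keeps full
    coverage while discarding the unreliable 32-px rim).
    """

    sheet_shape: tuple[int, int]
    tile_px: int = 256
    stride_px: int = 256
    keep_px: int = 256
    origins: tuple[tuple[int, int], ...] = field(init=False)

    def __post_init__(self) -> None:
        h, w = self.sheet_shape
        if self.tile_px <= 0 or self.stride_px <= 0:
            raise ValueError("tile_px and stride_px must be positive")
        if self.tile_px > h or self.tile_px > w:
            raise ValueError("tile larger than sheet")
        if not (0 < self.keep_px <= self.tile_px):
            raise ValueError("keep_px must satisfy 0 < keep_px <= tile_px")
        if self.stride_px > self.tile_px:
            raise ValueError("stride_px must not exceed tile_px")
        rows = _axis_origins(h, self.tile_px, self.stride_px)
        cols = _axis_origins(w, self.tile_px, self.stride_px)
        object.__setattr__(
            self, "origins", tuple((r, c) for r in rows for c in cols)
        )

    def __len__(self) -> int:
        return len(self.origins)

    @property
    def margin_px(self) -> int:
        return (self.tile_px - self.keep_px) // 2


def build_tile_grid(
    sheet_shape: tuple[int, int],
    tile_px: int = 256,
    stride_px: int = 256,
    keep_px: int | None = None,
) -> TileGrid:
    """Enumerate tile origins covering a sheet.

    With ``stride_px == tile_px`` this is the non-overlapping training
    tiling; with stride 128 and keep 192 it is the inference tiling.
    """
    if keep_px is None:
        keep_px = tile_px
    return TileGrid(tuple(sheet_shape), tile_px, stride_px, keep_px)


def extract_tiles(data: np.ndarray, grid: TileGrid) -> np.ndarray:
    """Stack of tiles in the grid's row-major origin order."""
    t = grid.tile_px
    return np.stack([data[r : r + t, c : c + t] for r, c in grid.origins])


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train/val/test tile index sets over one TileGrid.

    Assignment is block-wise on tile origins, so the three sets occupy
    contiguous geographic blocks and no validation/test tile overlaps a
    training tile. Because the assignment depends only on tile origins and
    the seed, every epoch of the same sheet receives the same geographic
    split.
    """

    train: tuple[int, ...]
    val: tuple[int, ...]
    test: tuple[int, ...]

    def __post_init__(self) -> None:
        sets = [set(self.train), set(self.val), set(self.test)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("split sets must be pairwise disjoint")


def split_dataset(
    grid: TileGrid,
    train_frac: float = 0.75,
    val_frac_of_train: float = 0.25,
    block_tiles: int = 4,
    seed: int = 0,
) -> DatasetSplit:
    """Block-wise train/val/test split without spatial leakage.

    Tiles are grouped into ``block_tiles`` x ``block_tiles`` blocks of the
    training tiling; whole blocks are assigned, in seed-shuffled order, to
    test until ``floor((1 - train_frac) * n)`` tiles are reached, then to
    validation until ``floor(val_frac_of_train * n_remaining)`` tiles, and
    the remainder trains. Counts therefore round down to whole tiles and up
    to whole blocks.
    """
    if not (0 < train_frac < 1) or not (0 < val_frac_of_train < 1):
        raise ValueError("fractions must lie strictly between 0 and 1")
    n = len(grid)
    block_px = block_tiles * grid.tile_px
    keys = [(r // block_px, c // block_px) for r, c in grid.origins]
    blocks: dict[tuple[int, int], list[int]] = {}
    for idx, key in enumerate(keys):
        blocks.setdefault(key, []).append(idx)
    if len(blocks) < 3:
        raise ValueError(
            f"only {len(blocks)} spatial block(s); need at least 3 for a "
            "train/val/test split (reduce block_tiles)"
        )
    order = sorted(blocks)
    rng = np.random.default_rng(seed)
    rng.shuffle(order)

    n_test_target = int(np.floor((1 - train_frac) * n))
    test: list[int] = []
    i = 0
    while len(test) < n_test_target and i < len(order) - 2:
        test.extend(blocks[order[i]])
        i += 1
    n_val_target = int(np.floor(val_frac_of_train * (n - len(test))))
    val: list[int] = []
    while len(val) < n_val_target and i < len(order) - 1:
        val.extend(blocks[order[i]])
        i += 1
    train: list[int] = []
    for key in order[i:]:
        train.extend(blocks[key])
    if not train or not val or not test:
        raise ValueError("split produced an empty set; use smaller blocks")
    return DatasetSplit(tuple(sorted(train)), tuple(sorted(val)), tuple(sorted(test)))


def tile_manifest(grid: TileGrid, split: DatasetSplit | None = None):
    """Tile index table (tile_id, y0, x0[, split]) for export as CSV."""
    import pandas as pd

    rows = [
        {"tile_id": i, "y0": r, "x0": c}
        for i, (r, c) in enumerate(grid.origins)
    ]
    df = pd.DataFrame(rows)
    if split is not None:
        assignment = {}
        for name in ("train", "val", "test"):
            for idx in getattr(split, name):
                assignment[idx] = name
        df["split"] = df["tile_id"].map(assignment)
    return df


def demosaic_predictions(tiles: np.ndarray, grid: TileGrid) -> np.ndarray:
    """Reassemble per-tile label predictions into a full sheet.

    Each tile contributes its central ``keep_px`` window; tiles touching the
    sheet border additionally keep their outer margin so the output covers
    the whole sheet. Overlaps resolve to the last tile written in row-major
    origin order.
    """
    if len(tiles) != len(grid):
        raise ValueError(
            f"incomplete coverage: {len(tiles)} predictions for {len(grid)} tiles"
        )
    h, w = grid.sheet_shape
    t, m = grid.tile_px, grid.margin_px
    out = np.zeros((h, w), dtype=np.asarray(tiles[0]).dtype)
    written = np.zeros((h, w), dtype=bool)
    for tile, (r0, c0) in zip(tiles, grid.origins):
        tile = np.asarray(tile)
        if tile.shape[:2] != (t, t):
            raise ValueError("prediction tile shape does not match grid tile_px")
        top = 0 if r0 == 0 else m
        left = 0 if c0 == 0 else m
        bottom = t if r0 + t == h else t - m
        right = t if c0 + t == w else t - m
        out[r0 + top : r0 + bottom, c0 + left : c0 + right] = tile[
            top:bottom, left:right
        ]
        written[r0 + top : r0 + bottom, c0 + left : c0 + right] = True
    if not written.all():
        raise ValueError("incomplete coverage: unwritten pixels remain")
    return out
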