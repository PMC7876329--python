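"""Field-scale tiled inference, density stitching, overlays, block reports.

Mosaics of arbitrary size are reflect-padded to a tile multiple, predicted
tile by tile (bounded memory), and stitched back without overlap so the
stitched density sums exactly to the sum of the cropped tile densities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from skimage.draw import polygon as draw_polygon

from .counting_peaks import integrate_count
from .density_targets import DensityMap, as_density_array
from .unet_model import UNet, normalize_input

__all__ = ["MosaicLayout", "plan_tiling", "infer_mosaic", "render_overlay",
           "block_report", "save_density", "load_density"]


@dataclass
class MosaicLayout:
    mosaic_shape: tuple      # (H, W)
    tile_size: int
    pad: tuple               # (bottom, right)
    tiles: list              # [(row_offset, col_offset), ...] row-major
    georeference: dict | None = None  # {"transform": 6-tuple, "crs": str}

    @property
    def padded_shape(self):
        return (self.mosaic_shape[0] + self.pad[0],
                self.mosaic_shape[1] + self.pad[1])


def plan_tiling(mosaic_shape, tile_size: int, model_depth: int, *,
                georeference: dict | None = None) -> MosaicLayout:
    """Plan non-overlapping row-major tiles over a reflect-padded mosaic.

    The mosaic is padded on the bottom and right up to the next multiple
    of ``tile_size``; ``tile_size`` itself must be divisible by
    ``2**model_depth`` so each tile passes through the network.
    """
    div = 2 ** model_depth
    if tile_size % div:
        raise ValueError(
            f"tile_size {tile_size} not divisible by 2**depth = {div}")
    h, w = int(mosaic_shape[0]), int(mosaic_shape[1])
    if h <= 0 or w <= 0:
        raise ValueError(f"mosaic shape {mosaic_shape} must be positive")
    pad_b = (-h) % tile_size
    pad_r = (-w) % tile_size
    tiles = [(r, c)
             for r in range(0, h + pad_b, tile_size)
             for c in range(0, w + pad_r, tile_size)]
    return MosaicLayout((h, w), tile_size, (pad_b, pad_r), tiles,
                        georeference)


def infer_mosaic(model: UNet, mosaic: np.ndarray, layout: MosaicLayout, *,
                 context_margin: int = 0) -> DensityMap:
    """Predict per tile and stitch into one field-scale density map.

    Padding regions are cropped away before placement, so the integral of
    the stitched map equals the sum of the cropped tile integrals exactly.
    Only one tile is resident at a time. ``context_margin`` (a multiple of
    ``2**depth``, default off) predicts each tile on a reflect-padded
    window extended by that margin and center-crops the result, which
    softens tile-border artifacts without introducing any overlap in the
    stitched output.
    """
    if mosaic.shape[:2] != layout.mosaic_shape:
        raise ValueError(
            f"mosaic shape {mosaic.shape[:2]} does not match layout "
            f"{layout.mosaic_shape}")
    div = 2 ** model.spec.depth
    if layout.tile_size % div:
        raise ValueError(
            f"layout tile_size {layout.tile_size} incompatible with model "
            f"depth {model.spec.depth} (needs divisibility by {div})")
    if context_margin % div:
        raise ValueError(
            f"context_margin {context_margin} must be a multiple of {div}")
    h, w = layout.mosaic_shape
    pad_b, pad_r = layout.pad
    m = context_margin
    padded = np.pad(mosaic, ((m, pad_b + m), (m, pad_r + m), (0, 0)),
                    mode="reflect") if (pad_b or pad_r or m) else mosaic
    out = np.zeros((h, w), dtype=np.float32)
    ts = layout.tile_size
    for r0, c0 in layout.tiles:
        window = padded[r0:r0 + ts + 2 * m, c0:c0 + ts + 2 * m]
        pred = model.forward(normalize_input(window)[None],
                             train=False)[0, :, :, 0]
        if m:
            pred = pred[m:-m, m:-m]
        vh = min(ts, h - r0)
        vw = min(ts, w - c0)
        if vh <= 0 or vw <= 0:
            continue
        out[r0:r0 + vh, c0:c0 + vw] = pred[:vh, :vw]
    return DensityMap(out)


# yellow (low) -> red (high)
_LOW = np.array([255.0, 255.0, 0.0])
_HIGH = np.array([255.0, 0.0, 0.0])


def render_overlay(density, transparency_floor: float = 1e-4,
                   base_image: np.ndarray | None = None, *,
                   vmax: float | None = None) -> np.ndarray:
    """Map density to an RGBA overlay: transparent below the floor, then
    yellow to red monotonically in density.

    The color scale saturates at ``vmax`` (default: 99th percentile of the
    positive density, robust to hot pixels). With ``base_image`` the
    overlay is alpha-composited onto the RGB mosaic and an opaque RGBA
    image is returned.
    """
    if transparency_floor < 0:
        raise ValueError("transparency_floor must be >= 0")
    arr = as_density_array(density).astype(np.float64)
    visible = arr >= transparency_floor
    if vmax is None:
        pos = arr[arr > 0]
        vmax = float(np.percentile(pos, 99)) if pos.size else 1.0
    if vmax <= 0:
        vmax = 1.0
    t = np.clip(arr / vmax, 0.0, 1.0)[..., None]
    rgb = (1 - t) * _LOW + t * _HIGH
    alpha = np.where(visible, 255, 0).astype(np.uint8)
    rgba = np.dstack([np.round(rgb).astype(np.uint8), alpha])
    if base_image is not None:
        base = np.asarray(base_image, dtype=np.float64)[..., :3]
        a = (alpha / 255.0)[..., None] * 0.6  # overlay opacity
        comp = a * rgb + (1 - a) * base
        rgba = np.dstack([np.round(comp).astype(np.uint8),
                          np.full(arr.shape, 255, dtype=np.uint8)])
    return rgba


def block_report(density, block_polygons) -> "pd.DataFrame":
    """Integrated count and mean density per block polygon.

    ``block_polygons`` maps block_id -> list of (row, col) vertices. The
    report is sorted ascending by mean density (rank 1 = sparsest block)
    to surface failed-forcing candidates first.
    """
    import pandas as pd

    arr = as_density_array(density)
    h, w = arr.shape
    rows = []
    for block_id, verts in block_polygons.items():
        verts = np.asarray(verts, dtype=float)
        if verts.ndim != 2 or len(verts) < 3:
            raise ValueError(f"block {block_id!r}: degenerate polygon")
        if verts[:, 0].min() < 0 or verts[:, 0].max() > h \
                or verts[:, 1].min() < 0 or verts[:, 1].max() > w:
            raise ValueError(f"block {block_id!r}: polygon outside mosaic")
        rr, cc = draw_polygon(verts[:, 0], verts[:, 1], shape=arr.shape)
        if rr.size == 0:
            raise ValueError(f"block {block_id!r}: degenerate polygon")
        mask = np.zeros(arr.shape, dtype=bool)
        mask[rr, cc] = True
        rows.append({"block_id": block_id,
                     "count": integrate_count(arr, mask),
                     "mean_density": float(arr[mask].mean())})
    report = pd.DataFrame(rows).sort_values(
        "mean_density", kind="stable").reset_index(drop=True)
    report["rank"] = np.arange(1, len(report) + 1)
    return report


def save_density(density, path, *, georeference: dict | None = None) -> Path:
    """Persist a density map as single-band float32 TIFF.

    Georeference (affine transform + CRS), when present, goes to a JSON
    sidecar so the overlay and block reports can be placed on the mosaic.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, as_density_array(density).astype(np.float32))
    if georeference is not None:
        path.with_suffix(".json").write_text(json.dumps(georeference))
    return path


def load_density(path) -> DensityMap:
    path = Path(path)
    values = tifffile.imread(path)
    side = path.with_suffix(".json")
    geo = json.loads(side.read_text()) if side.exists() else None
    dm = DensityMap(values)
    if geo is not None:
        dm.pixel_size = geo.get("pixel_size")
    return dm
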