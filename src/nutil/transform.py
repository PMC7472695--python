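"""2D transformation of tiled TIFF section images.

Section scans come off the scanner in arbitrary orientation and at full
resolution; before registration they must be rotated/mirrored into a standard
orientation, cropped to the tissue, downscaled, and renamed into serial-section
order.  All raster operations here use **nearest-neighbor inverse mapping**
(pointwise sampling, no antialiasing): every output pixel is mapped through
the inverse of the composed flip -> rotate -> scale transform and filled with
the nearest source pixel, or the configured background color when the
preimage falls outside the source.

Conventions (fixed and relied upon by the tests):

* composition order is flip, then rotate (counter-clockwise positive, about
  the pixel-index center ``((w-1)/2, (h-1)/2)``), then scale;
* scaling samples source index ``floor((i + 0.5) / scale)`` (clamped);
* nearest-neighbor ties at exact half-pixel preimages round down
  (``ceil(v - 0.5)``);
* output geometry of a rotation is the ceiling of the axis-aligned extent of
  the four rotated corners, so multiples of 90 degrees are exact.

Processing is tile-wise over the output raster, reading only the source tiles
each output tile needs, so memory stays bounded for arbitrarily large images.
"""

from __future__ import annotations

import csv
import math
import os
import shutil
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import InputError, ParameterError
from .tiled_image import (
    DEFAULT_TILE_SIZE,
    TiledImage,
    open_tiled,
    write_tiled,
)

__all__ = [
    "TransformSpec",
    "BoundingBox",
    "compute_output_geometry",
    "transform_tiled",
    "transform_array",
    "autocrop_bbox",
    "scale_pointwise",
    "batch_rename",
    "area_percent_to_scale",
]


@dataclass(frozen=True)
class TransformSpec:
    """Parameters of one 2D transformation.

    ``scale`` and ``thumbnail_factor`` are *linear* fractions in (0, 1]; use
    :func:`area_percent_to_scale` to convert an area percentage.  ``background``
    fills output pixels whose preimage lies outside the source (typically
    black or white).
    """

    rotation_deg: float = 0.0
    flip_horizontal: bool = False
    flip_vertical: bool = False
    scale: float = 1.0
    background: tuple[int, int, int] = (0, 0, 0)
    autocrop: bool = False
    thumbnail_factor: float | None = None
    output_name: str | None = None

    def __post_init__(self):
        if not (0.0 < self.scale <= 1.0):
            raise ParameterError(f"scale must be in (0, 1], got {self.scale}")
        if self.thumbnail_factor is not None and not (0.0 < self.thumbnail_factor <= 1.0):
            raise ParameterError(
                f"thumbnail_factor must be in (0, 1], got {self.thumbnail_factor}"
            )
        bg = tuple(int(c) for c in self.background)
        if len(bg) != 3 or any(not 0 <= c <= 255 for c in bg):
            raise ParameterError(f"background must be an RGB triple, got {self.background}")
        object.__setattr__(self, "background", bg)


@dataclass(frozen=True)
class BoundingBox:
    """Inclusive pixel-index bounding box."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self):
        if self.x_min > self.x_max or self.y_min > self.y_max:
            raise ParameterError(f"degenerate bounding box: {self}")

    @property
    def width(self) -> int:
        return self.x_max - self.x_min + 1

    @property
    def height(self) -> int:
        return self.y_max - self.y_min + 1


def area_percent_to_scale(area_percent: float) -> float:
    """Convert an area percentage (e.g. 25) to the linear scale factor (0.5)."""
    if not (0.0 < area_percent <= 100.0):
        raise ParameterError(f"area percent must be in (0, 100], got {area_percent}")
    return math.sqrt(area_percent / 100.0)


def compute_output_geometry(w: int, h: int, rotation_deg: float) -> tuple[int, int]:
    """Raster size needed to hold ``(w, h)`` rotated by ``rotation_deg``.

    Ceiling of the axis-aligned extent of the four rotated corners; exact at
    multiples of 90 degrees (180k preserves (w, h), odd 90k swaps to (h, w)).
    """
    if w < 1 or h < 1:
        raise ParameterError("image dimensions must be >= 1")
    quarter, rem = divmod(rotation_deg % 360.0, 90.0)
    if rem == 0.0:
        return (w, h) if int(quarter) % 2 == 0 else (h, w)
    theta = math.radians(rotation_deg)
    c, s = abs(math.cos(theta)), abs(math.sin(theta))
    return (math.ceil(w * c + h * s), math.ceil(w * s + h * c))


def _nearest(v: np.ndarray) -> np.ndarray:
    # round-half-down: exact half-pixel preimages take the lower index
    return np.ceil(v - 0.5).astype(np.int64)


def _inverse_map(
    spec: TransformSpec, src_w: int, src_h: int, xs: np.ndarray, ys: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map output pixel indices back to source indices.

    Returns (x_src, y_src, inside) where ``inside`` marks preimages falling
    within the source raster.  ``xs``/``ys`` broadcast together.
    """
    rw, rh = compute_output_geometry(src_w, src_h, spec.rotation_deg)
    # undo scale: pointwise sampling convention floor((i+0.5)/scale)
    if spec.scale != 1.0:
        xr = np.floor((xs + 0.5) / spec.scale)
        yr = np.floor((ys + 0.5) / spec.scale)
        np.clip(xr, 0, rw - 1, out=xr)
        np.clip(yr, 0, rh - 1, out=yr)
    else:
        xr, yr = np.asarray(xs, dtype=float), np.asarray(ys, dtype=float)
    # undo rotation about pixel-index centers
    theta = math.radians(spec.rotation_deg)
    c, s = math.cos(theta), math.sin(theta)
    dx = xr - (rw - 1) / 2.0
    dy = yr - (rh - 1) / 2.0
    # image-axis (y down) CCW rotation forward is [[c, s], [-s, c]];
    # this is its inverse applied to output coordinates
    xsrc = _nearest(c * dx - s * dy + (src_w - 1) / 2.0)
    ysrc = _nearest(s * dx + c * dy + (src_h - 1) / 2.0)
    inside = (xsrc >= 0) & (xsrc < src_w) & (ysrc >= 0) & (ysrc < src_h)
    # undo flips (applied first in the forward order)
    if spec.flip_horizontal:
        xsrc = (src_w - 1) - xsrc
    if spec.flip_vertical:
        ysrc = (src_h - 1) - ysrc
    return xsrc, ysrc, inside


def output_dimensions(spec: TransformSpec, src_w: int, src_h: int) -> tuple[int, int]:
    """Full (pre-autocrop) output raster size for a spec."""
    rw, rh = compute_output_geometry(src_w, src_h, spec.rotation_deg)
    if spec.scale != 1.0:
        return max(1, round(rw * spec.scale)), max(1, round(rh * spec.scale))
    return rw, rh


def transform_array(img: np.ndarray, spec: TransformSpec) -> np.ndarray:
    """Whole-raster reference transform (flip -> rotate -> scale -> autocrop).

    Semantically identical to :func:`transform_tiled`; used for small images
    and as the flat reference the tile-wise path is tested against.
    """
    img = np.asarray(img, dtype=np.uint8)
    src_h, src_w = img.shape[:2]
    out_w, out_h = output_dimensions(spec, src_w, src_h)
    ys, xs = np.mgrid[0:out_h, 0:out_w]
    xsrc, ysrc, inside = _inverse_map(spec, src_w, src_h, xs, ys)
    out = np.empty((out_h, out_w, 3), dtype=np.uint8)
    out[:] = spec.background
    out[inside] = img[ysrc[inside], xsrc[inside]]
    if spec.autocrop:
        box = autocrop_bbox(out, spec.background)
        out = out[box.y_min : box.y_max + 1, box.x_min : box.x_max + 1]
    return out


def autocrop_bbox(img: np.ndarray, background: tuple[int, int, int]) -> BoundingBox:
    """Tightest box containing all pixels different from ``background``.

    An all-background image returns the full-image box (empty rasters break
    every downstream consumer).
    """
    img = np.asarray(img)
    if img.size == 0:
        raise ParameterError("image is empty")
    fg = np.any(img != np.asarray(background, dtype=img.dtype), axis=2)
    rows = np.flatnonzero(fg.any(axis=1))
    cols = np.flatnonzero(fg.any(axis=0))
    if rows.size == 0:
        return BoundingBox(0, 0, img.shape[1] - 1, img.shape[0] - 1)
    return BoundingBox(int(cols[0]), int(rows[0]), int(cols[-1]), int(rows[-1]))


def scale_pointwise(img: np.ndarray, scale: float) -> np.ndarray:
    """Downscale by pointwise sampling (no antialiasing).

    Output pixel ``(x, y)`` takes source pixel
    ``(floor((x+0.5)/scale), floor((y+0.5)/scale))`` clamped to bounds; output
    size is ``round(w*scale) x round(h*scale)``, at least 1x1.
    """
    if not (0.0 < scale <= 1.0):
        raise ParameterError(f"scale must be in (0, 1] (no enlargement), got {scale}")
    img = np.asarray(img)
    h, w = img.shape[:2]
    if scale == 1.0:
        return img.copy()
    ow, oh = max(1, round(w * scale)), max(1, round(h * scale))
    xs = np.minimum(np.floor((np.arange(ow) + 0.5) / scale).astype(np.int64), w - 1)
    ys = np.minimum(np.floor((np.arange(oh) + 0.5) / scale).astype(np.int64), h - 1)
    return img[np.ix_(ys, xs)]


def _tile_pass(
    src: TiledImage,
    spec: TransformSpec,
    out_w: int,
    out_h: int,
    tile_size: int,
):
    """Yield output tiles (row-major) by inverse-mapping each through src.

    Also accumulates the non-background bounding box into a mutable holder
    so autocropping needs no second full pass over pixels.
    """
    bg = np.asarray(spec.background, dtype=np.uint8)
    bbox = [out_w, out_h, -1, -1]  # x_min, y_min, x_max, y_max

    def tiles():
        for ty0 in range(0, out_h, tile_size):
            th = min(tile_size, out_h - ty0)
            for tx0 in range(0, out_w, tile_size):
                tw = min(tile_size, out_w - tx0)
                ys, xs = np.mgrid[ty0 : ty0 + th, tx0 : tx0 + tw]
                xsrc, ysrc, inside = _inverse_map(spec, src.width, src.height, xs, ys)
                block = np.empty((th, tw, 3), dtype=np.uint8)
                block[:] = bg
                if inside.any():
                    # fetch only the source window this output tile touches
                    x0, x1 = int(xsrc[inside].min()), int(xsrc[inside].max())
                    y0, y1 = int(ysrc[inside].min()), int(ysrc[inside].max())
                    win = src.read_region(x0, y0, x1 - x0 + 1, y1 - y0 + 1)
                    block[inside] = win[ysrc[inside] - y0, xsrc[inside] - x0]
                fg = np.any(block != bg, axis=2)
                if fg.any():
                    rows = np.flatnonzero(fg.any(axis=1))
                    cols = np.flatnonzero(fg.any(axis=0))
                    bbox[0] = min(bbox[0], tx0 + int(cols[0]))
                    bbox[1] = min(bbox[1], ty0 + int(rows[0]))
                    bbox[2] = max(bbox[2], tx0 + int(cols[-1]))
                    bbox[3] = max(bbox[3], ty0 + int(rows[-1]))
                yield block

    return tiles, bbox


def transform_tiled(
    input_path: str | os.PathLike,
    spec: TransformSpec,
    output_path: str | os.PathLike,
    tile_size: int = DEFAULT_TILE_SIZE,
    compression: str = "lzw",
    cache_capacity: int | None = 16,
) -> Path:
    """Transform a tiled TIFF file tile-wise and write a tiled TIFF result.

    With ``autocrop`` the transform is written to a temporary sibling first
    and the tight crop copied out of it, mirroring the bounded-memory design.
    With ``thumbnail_factor`` a pointwise-sampled PNG thumbnail of the final
    image is written into a ``thumbnails/`` sibling directory.
    Returns the output path.
    """
    output_path = Path(output_path)
    output_path.parent.mkdir(parents=True, exist_ok=True)
    with open_tiled(input_path, cache_capacity=cache_capacity) as src:
        out_w, out_h = output_dimensions(spec, src.width, src.height)
        target = output_path
        if spec.autocrop:
            target = output_path.with_name(output_path.name + ".tmp.tif")
        tiles, bbox = _tile_pass(src, spec, out_w, out_h, tile_size)
        write_tiled(
            target,
            tiles(),
            shape=(out_h, out_w, 3),
            tile_size=tile_size,
            compression=compression,
        )
    if spec.autocrop:
        if bbox[2] < 0:  # all background: keep the full image
            bbox = [0, 0, out_w - 1, out_h - 1]
        box = BoundingBox(*bbox)
        with open_tiled(target, cache_capacity=cache_capacity) as tmp:

            def cropped():
                for ty0 in range(box.y_min, box.y_max + 1, tile_size):
                    th = min(tile_size, box.y_max + 1 - ty0)
                    for tx0 in range(box.x_min, box.x_max + 1, tile_size):
                        tw = min(tile_size, box.x_max + 1 - tx0)
                        yield tmp.read_region(tx0, ty0, tw, th)

            write_tiled(
                output_path,
                cropped(),
                shape=(box.height, box.width, 3),
                tile_size=tile_size,
                compression=compression,
            )
        target.unlink()
    if spec.thumbnail_factor is not None:
        thumb_dir = output_path.parent / "thumbnails"
        thumb_dir.mkdir(exist_ok=True)
        with open_tiled(output_path, cache_capacity=cache_capacity) as final:
            thumb = scale_pointwise(final.read_full(), spec.thumbnail_factor)
        Image.fromarray(thumb).save(thumb_dir / (output_path.stem + ".png"))
    return output_path


def batch_rename(
    files: list[str | os.PathLike],
    output_dir: str | os.PathLike,
    base_name: str,
    start_index: int = 1,
    zero_pad: int = 3,
) -> list[Path]:
    """Copy files into serial-section names ``<base>_sNNN.<ext>``.

    List order defines section order.  Collisions among the target names are
    rejected before any file is written; a ``rename_log.csv`` mapping old to
    new names is written alongside the copies.
    """
    files = [Path(f) for f in files]
    for f in files:
        if not f.exists():
            raise InputError(f"no such file: {f}")
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    new_names = [
        f"{base_name}_s{start_index + i:0{zero_pad}d}{f.suffix}"
        for i, f in enumerate(files)
    ]
    if len(set(new_names)) != len(new_names):
        dupes = sorted({n for n in new_names if new_names.count(n) > 1})
        raise ParameterError(f"output name collision: {dupes}")
    existing = [n for n in new_names if (output_dir / n).exists()]
    if existing:
        raise ParameterError(f"output name collision with existing files: {existing}")
    written = []
    for f, name in zip(files, new_names):
        shutil.copyfile(f, output_dir / name)
        written.append(output_dir / name)
    with open(output_dir / "rename_log.csv", "w", newline="") as fh:
        log = csv.writer(fh)
        log.writerow(["original", "renamed"])
        for f, name in zip(files, new_names):
            log.writerow([str(f), name])
    return written
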