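"""Tiled-TIFF data model and conversion.

Very large section scans (up to ~80,000 x 70,000 pixels) cannot be held in
memory as flat rasters.  The tiled-TIFF container stores the raster as a grid
of independently decodable fixed-size tiles, so any operation can run over a
bounded working set of tiles.  This module provides:

* :class:`TiledImage` -- a lazy, cache-backed reader for tiled (Big)TIFF,
* :class:`TileCache` -- an instrumented LRU cache bounding the working set,
* :func:`create_tiled_tiff` / :func:`convert_directory` -- PNG/JPEG to tiled
  TIFF conversion (batch image-format converter),
* :func:`write_tiled` -- write an in-memory or tile-iterator raster as tiled
  TIFF.

Color model is fixed to 8-bit RGB; grayscale and RGBA inputs are promoted /
reduced to RGB on read.  ``none`` and ``lzw`` compression are lossless and
round-trip exactly; ``jpeg`` is lossy and carries no round-trip guarantee.
"""

from __future__ import annotations

import math
import os
from collections import OrderedDict
from pathlib import Path
from typing import Iterator

import numpy as np
import tifffile
from PIL import Image

from .errors import FormatError, InputError, ParameterError

__all__ = [
    "TileCache",
    "TiledImage",
    "create_tiled_tiff",
    "convert_directory",
    "write_tiled",
    "open_tiled",
    "DEFAULT_TILE_SIZE",
]

DEFAULT_TILE_SIZE = 256
_COMPRESSIONS = {"none": None, "lzw": "lzw", "jpeg": "jpeg"}
# BigTIFF switch-over: classic TIFF offsets are 32-bit.
_BIGTIFF_THRESHOLD = 4 * 1024**3


class TileCache:
    """Least-recently-used cache of decoded tiles.

    Holds at most ``capacity`` decoded tiles; the instrumentation counters
    (``decodes``, ``hits``, ``max_resident``) let tests assert the bounded
    working-set contract.  ``capacity=None`` means unbounded.
    """

    def __init__(self, capacity: int | None = 16):
        if capacity is not None and capacity < 1:
            raise ParameterError("cache capacity must be >= 1 or None")
        self.capacity = capacity
        self._store: OrderedDict[tuple[int, int], np.ndarray] = OrderedDict()
        self.decodes = 0
        self.hits = 0
        self.max_resident = 0

    def __len__(self) -> int:
        return len(self._store)

    def get(self, key, loader) -> np.ndarray:
        if key in self._store:
            self._store.move_to_end(key)
            self.hits += 1
            return self._store[key]
        tile = loader(key)
        self.decodes += 1
        self._store[key] = tile
        if self.capacity is not None:
            while len(self._store) > self.capacity:
                self._store.popitem(last=False)
        self.max_resident = max(self.max_resident, len(self._store))
        return tile

    def clear(self) -> None:
        self._store.clear()


class TiledImage:
    """Lazy reader for a tiled (Big)TIFF file.

    Pixel access never exposes the internal padding of edge tiles: reads are
    clipped to ``(width, height)``.  Tiles are decoded on demand through an
    LRU :class:`TileCache`, so the resident decoded-pixel footprint is bounded
    regardless of image size.
    """

    def __init__(self, path: str | os.PathLike, cache_capacity: int | None = 16):
        path = Path(path)
        if not path.exists():
            raise InputError(f"no such file: {path}")
        try:
            self._tif = tifffile.TiffFile(path)
        except Exception as exc:  # noqa: BLE001 - normalise to toolbox errors
            raise FormatError(f"not a readable TIFF file: {path}: {exc}") from exc
        page = self._tif.pages[0]
        if not page.is_tiled:
            self._tif.close()
            raise FormatError(
                f"{path} is a striped TIFF; this tool requires tiled TIFF "
                "(convert it with create_tiled_tiff)"
            )
        self.path = path
        self._page = page
        self.width = int(page.imagewidth)
        self.height = int(page.imagelength)
        self.tile_width = int(page.tilewidth)
        self.tile_height = int(page.tilelength)
        self.compression = {1: "none", 5: "lzw", 7: "jpeg"}.get(
            int(page.compression), str(page.compression)
        )
        self.cache = TileCache(cache_capacity)
        self._samples = page.samplesperpixel

    # -- geometry -----------------------------------------------------------
    @property
    def n_tile_cols(self) -> int:
        return math.ceil(self.width / self.tile_width)

    @property
    def n_tile_rows(self) -> int:
        return math.ceil(self.height / self.tile_height)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.height, self.width, 3)

    # -- tile access --------------------------------------------------------
    def _decode_tile(self, key: tuple[int, int]) -> np.ndarray:
        row, col = key
        index = row * self.n_tile_cols + col
        fh = self._tif.filehandle
        fh.seek(self._page.dataoffsets[index])
        data = fh.read(self._page.databytecounts[index])
        segment, _, _ = self._page.decode(
            data, index, jpegtables=self._page.jpegtables
        )
        tile = np.asarray(segment)[0]
        if tile.ndim == 2:
            tile = np.repeat(tile[:, :, None], 3, axis=2)
        return np.ascontiguousarray(tile[:, :, :3], dtype=np.uint8)

    def get_tile(self, row: int, col: int) -> np.ndarray:
        """Decoded tile ``(tile_height, tile_width, 3)``; edge tiles padded."""
        if not (0 <= row < self.n_tile_rows and 0 <= col < self.n_tile_cols):
            raise ParameterError(f"tile index out of range: ({row}, {col})")
        return self.cache.get((row, col), self._decode_tile)

    def read_region(self, x0: int, y0: int, w: int, h: int) -> np.ndarray:
        """Read the window clipped to image bounds.

        Only tiles overlapping the window are decoded.  The returned block
        has the clipped window's shape; a zero-area intersection is a
        parameter error.
        """
        if w <= 0 or h <= 0:
            raise ParameterError("window must have positive width and height")
        cx0, cy0 = max(x0, 0), max(y0, 0)
        cx1, cy1 = min(x0 + w, self.width), min(y0 + h, self.height)
        if cx0 >= cx1 or cy0 >= cy1:
            raise ParameterError("window does not intersect the image")
        out = np.empty((cy1 - cy0, cx1 - cx0, 3), dtype=np.uint8)
        tw, th = self.tile_width, self.tile_height
        for trow in range(cy0 // th, (cy1 - 1) // th + 1):
            for tcol in range(cx0 // tw, (cx1 - 1) // tw + 1):
                tile = self.get_tile(trow, tcol)
                tx0, ty0 = tcol * tw, trow * th
                sx0, sy0 = max(cx0, tx0), max(cy0, ty0)
                sx1 = min(cx1, tx0 + tw)
                sy1 = min(cy1, ty0 + th)
                out[sy0 - cy0 : sy1 - cy0, sx0 - cx0 : sx1 - cx0] = tile[
                    sy0 - ty0 : sy1 - ty0, sx0 - tx0 : sx1 - tx0
                ]
        return out

    def read_full(self) -> np.ndarray:
        return self.read_region(0, 0, self.width, self.height)

    def iter_tiles(self) -> Iterator[tuple[int, int, np.ndarray]]:
        """Yield ``(row, col, tile)`` in row-major order (clipped at edges)."""
        for row in range(self.n_tile_rows):
            for col in range(self.n_tile_cols):
                tile = self.get_tile(row, col)
                h = min(self.tile_height, self.height - row * self.tile_height)
                w = min(self.tile_width, self.width - col * self.tile_width)
                yield row, col, tile[:h, :w]

    def close(self) -> None:
        self.cache.clear()
        self._tif.close()

    def __enter__(self) -> "TiledImage":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def open_tiled(path: str | os.PathLike, cache_capacity: int | None = 16) -> TiledImage:
    """Open an existing tiled TIFF, verifying that it is indeed tiled."""
    return TiledImage(path, cache_capacity=cache_capacity)


def _validate_tile_size(tile_size: int) -> None:
    if not (16 <= tile_size <= 4096):
        raise ParameterError(f"tile_size must be in [16, 4096], got {tile_size}")
    if tile_size % 16 != 0:
        raise ParameterError(
            f"tile_size must be a multiple of 16 (TIFF requirement), got {tile_size}"
        )


def _validate_compression(compression: str) -> str | None:
    if compression not in _COMPRESSIONS:
        raise ParameterError(
            f"compression must be one of {sorted(_COMPRESSIONS)}, got {compression!r}"
        )
    return _COMPRESSIONS[compression]


def load_rgb(path: str | os.PathLike) -> np.ndarray:
    """Decode a PNG/JPEG into an 8-bit RGB array (grayscale promoted)."""
    try:
        with Image.open(path) as im:
            return np.asarray(im.convert("RGB"), dtype=np.uint8)
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot decode image {path}: {exc}") from exc


def write_tiled(
    output_path: str | os.PathLike,
    data,
    shape: tuple[int, int, int] | None = None,
    tile_size: int = DEFAULT_TILE_SIZE,
    compression: str = "lzw",
) -> None:
    """Write an RGB raster (array or row-major tile iterator) as tiled TIFF.

    BigTIFF is selected automatically when the uncompressed raster would not
    fit classic 32-bit TIFF offsets.
    """
    _validate_tile_size(tile_size)
    comp = _validate_compression(compression)
    if shape is None:
        data = np.asarray(data, dtype=np.uint8)
        shape = data.shape
    nbytes = int(np.prod(shape))
    tifffile.imwrite(
        output_path,
        data,
        shape=shape,
        dtype=np.uint8,
        tile=(tile_size, tile_size),
        compression=comp,
        bigtiff=nbytes > _BIGTIFF_THRESHOLD,
        photometric="rgb",
    )


def create_tiled_tiff(
    source_image_path: str | os.PathLike,
    output_path: str | os.PathLike,
    tile_size: int = DEFAULT_TILE_SIZE,
    compression: str = "lzw",
) -> TiledImage:
    """Convert a PNG/JPEG image to tiled TIFF and return a handle on it.

    Lossless for ``none``/``lzw``: decoded pixels equal the source
    pixel-for-pixel.
    """
    _validate_tile_size(tile_size)
    _validate_compression(compression)
    rgb = load_rgb(source_image_path)
    write_tiled(output_path, rgb, tile_size=tile_size, compression=compression)
    return open_tiled(output_path)


def convert_directory(
    input_dir: str | os.PathLike,
    output_dir: str | os.PathLike,
    tile_size: int = DEFAULT_TILE_SIZE,
    compression: str = "lzw",
) -> list[Path]:
    """Batch-convert every PNG/JPEG in ``input_dir`` to tiled TIFF.

    Files are independent units of work; per-file failures raise immediately
    (conversion is a preprocessing prerequisite, not best-effort).
    Returns the list of written files.
    """
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    if not input_dir.is_dir():
        raise InputError(f"input directory does not exist: {input_dir}")
    output_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for src in sorted(input_dir.iterdir()):
        if src.suffix.lower() not in {".png", ".jpg", ".jpeg"}:
            continue
        dst = output_dir / (src.stem + ".tif")
        create_tiled_tiff(src, dst, tile_size=tile_size, compression=compression).close()
        written.append(dst)
    return written
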