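"""Bulk downscaling of PNG/JPEG images to PNG.

Thumbnails and registration-sized copies of section images are produced by
shrinking the originals, either to a fixed pixel width or to a percentage of
the original size, with bilinear filtering or plain pointwise sampling
("no filtering").  Enlargement is not supported: it serves no purpose for
histological image analysis.

Bilinear weights use pixel-center alignment (source coordinate
``(x + 0.5)/scale - 0.5``); the unfiltered path is the same pointwise
sampling as :func:`nutil.transform.scale_pointwise`, so the two tools agree
pixel-for-pixel on identical inputs.  Output is always 8-bit RGB PNG.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import InputError, ParameterError
from .tiled_image import load_rgb
from .transform import scale_pointwise

__all__ = ["ResizeSpec", "resize_image", "resize_batch"]

logger = logging.getLogger(__name__)

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


@dataclass(frozen=True)
class ResizeSpec:
    """How to shrink: ``percent`` of original size or ``fixed_width`` pixels.

    ``filter`` is ``"bilinear"`` or ``"none"`` (pointwise sampling).
    """

    mode: str  # {"fixed_width", "percent"}
    value: float
    filter: str = "bilinear"

    def __post_init__(self):
        if self.mode not in {"fixed_width", "percent"}:
            raise ParameterError(f"mode must be fixed_width or percent, got {self.mode!r}")
        if self.filter not in {"bilinear", "none"}:
            raise ParameterError(f"filter must be bilinear or none, got {self.filter!r}")
        if self.mode == "percent" and not (0.0 < self.value <= 100.0):
            raise ParameterError(f"percent must be in (0, 100], got {self.value}")
        if self.mode == "fixed_width" and self.value < 1:
            raise ParameterError(f"fixed_width must be >= 1, got {self.value}")

    def target_size(self, w: int, h: int) -> tuple[int, int]:
        """Output size for a ``w x h`` source, aspect ratio preserved."""
        if self.mode == "percent":
            scale = self.value / 100.0
        else:
            if self.value > w:
                raise ParameterError(
                    f"fixed_width {self.value} exceeds source width {w}; "
                    "enlargement of images is not supported"
                )
            scale = self.value / w
        ow = int(self.value) if self.mode == "fixed_width" else max(1, round(w * scale))
        return ow, max(1, round(h * scale))


def resize_image(
    source_path: str | os.PathLike, spec: ResizeSpec, output_path: str | os.PathLike
) -> Path:
    """Shrink one PNG/JPEG to a PNG at the spec's size; returns the output path."""
    rgb = load_rgb(source_path)
    h, w = rgb.shape[:2]
    ow, oh = spec.target_size(w, h)
    if spec.filter == "bilinear":
        out = np.asarray(
            Image.fromarray(rgb).resize((ow, oh), Image.Resampling.BILINEAR)
        )
    else:
        out = scale_pointwise(rgb, min(1.0, ow / w) if w else 1.0)
        # per-axis rounding can differ by one pixel from the uniform scale
        if out.shape[:2] != (oh, ow):
            out = out[:oh, :ow]
    output_path = Path(output_path)
    output_path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(out.astype(np.uint8)).save(output_path)
    return output_path


def resize_batch(
    input_dir: str | os.PathLike, output_dir: str | os.PathLike, spec: ResizeSpec
) -> dict[str, list[str]]:
    """Resize every PNG/JPEG in ``input_dir`` into ``output_dir``.

    Files are independent: a per-file failure is logged and the batch
    continues.  Non-image files are skipped and logged.  Returns a summary
    ``{"ok": [...], "skipped": [...], "failed": [...]}``; the same summary is
    written to ``resize_log.txt`` in the output directory.
    """
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    if not input_dir.is_dir():
        raise InputError(f"input directory does not exist: {input_dir}")
    output_dir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, list[str]] = {"ok": [], "skipped": [], "failed": []}
    entries = sorted(p for p in input_dir.iterdir() if p.is_file())
    if not entries:
        logger.warning("resize: input directory %s is empty", input_dir)
    for src in entries:
        if src.suffix.lower() not in _IMAGE_SUFFIXES:
            summary["skipped"].append(src.name)
            logger.info("resize: skipping non-image file %s", src.name)
            continue
        try:
            resize_image(src, spec, output_dir / (src.stem + ".png"))
            summary["ok"].append(src.name)
        except (InputError, ParameterError, OSError) as exc:
            summary["failed"].append(src.name)
            logger.error("resize: %s failed: %s", src.name, exc)
    with open(output_dir / "resize_log.txt", "w") as fh:
        for key in ("ok", "skipped", "failed"):
            for name in summary[key]:
                fh.write(f"{key}\t{name}\n")
    return summary
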