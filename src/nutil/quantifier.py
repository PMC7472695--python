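"""Quantification of segmented objects within brain-atlas regions.

The post-processing stage of the workflow: segmentation images (one unique
RGB color per analysis class, e.g. black for labelled cells) are paired with
per-section atlas maps (2D grids of integer region IDs produced by
registering the sections to a 3D reference atlas).  Objects — connected
components of object-colored pixels — are extracted by breadth-first search,
filtered by size, anchored to atlas regions pixel-by-pixel, quantified per
region (counts, pixel areas, and *load* = object pixels / region pixels),
optionally partitioned by hemisphere masks and aggregated into user-defined
custom regions, and finally projected into 3D atlas space as point clouds.

Object splitting: an object straddling N atlas regions is either assigned
whole to one of the overlapped regions (splitting OFF — at random with a
recorded seed, or to the majority region), or split into N per-region
sub-objects (splitting ON).  Splitting conserves pixel counts but
invalidates object counts, so reports flag the count column when it is on.
"""

from __future__ import annotations

import csv
import io
import logging
import os
import re
import shlex
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .atlas_anchoring import build_point_cloud, load_anchorings
from .errors import InputError, ParameterError, ValidationError
from .tiled_image import load_rgb
from .transform import BoundingBox

__all__ = [
    "AtlasMap",
    "LabelTable",
    "SegmentationObject",
    "QuantifierConfig",
    "MaskSpec",
    "CustomRegionSet",
    "extract_objects",
    "filter_by_size",
    "assign_objects",
    "apply_mask",
    "summarize",
    "render_overlay",
    "run_quantifier",
    "OUTSIDE_REGION_ID",
    "OUTSIDE_REGION_NAME",
]

logger = logging.getLogger(__name__)

OUTSIDE_REGION_ID = 0
OUTSIDE_REGION_NAME = "outside atlas"

_SECTION_TOKEN = re.compile(r"_s(\d+)")


def section_id_of(name: str) -> int | None:
    """Serial-section number from the ``_sNNN`` file-name token."""
    m = _SECTION_TOKEN.search(Path(name).stem)
    return int(m.group(1)) if m else None


# ---------------------------------------------------------------------------
# label tables and atlas maps
# ---------------------------------------------------------------------------


class LabelTable:
    """Mapping of atlas region IDs to names and display colors.

    Region ID 0 is reserved for "outside atlas" (background of the atlas
    map) and may not appear as a row.
    """

    def __init__(self, rows: list[tuple[int, str, tuple[int, int, int]]]):
        self._name: dict[int, str] = {}
        self._color: dict[int, tuple[int, int, int]] = {}
        for rid, name, color in rows:
            rid = int(rid)
            if rid == OUTSIDE_REGION_ID:
                raise ValidationError("region ID 0 is reserved for outside-atlas")
            if rid in self._name:
                raise ValidationError(f"duplicate region ID {rid} in label table")
            self._name[rid] = str(name)
            self._color[rid] = tuple(int(c) for c in color)

    @property
    def region_ids(self) -> list[int]:
        return sorted(self._name)

    def __contains__(self, rid: int) -> bool:
        return rid in self._name

    def __len__(self) -> int:
        return len(self._name)

    def name(self, rid: int) -> str:
        if rid == OUTSIDE_REGION_ID:
            return OUTSIDE_REGION_NAME
        return self._name[rid]

    def color(self, rid: int) -> tuple[int, int, int]:
        if rid == OUTSIDE_REGION_ID:
            return (0, 0, 0)
        return self._color[rid]

    @classmethod
    def from_itksnap(cls, path: str | os.PathLike) -> "LabelTable":
        """Parse an ITK-SNAP style label description file.

        Lines: ``ID R G B [A VIS MSH] "name"``; ``#`` comments ignored; a
        row with ID 0 ("Clear Label") is skipped.
        """
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = shlex.split(line)
                if len(parts) < 5:
                    raise ValidationError(f"{path}: malformed label line: {line!r}")
                rid = int(parts[0])
                if rid == 0:
                    continue
                r, g, b = (int(v) for v in parts[1:4])
                rows.append((rid, parts[-1], (r, g, b)))
        return cls(rows)

    def to_itksnap(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("# ITK-SNAP label description file\n")
            fh.write('0 0 0 0 0 0 0 "Clear Label"\n')
            for rid in self.region_ids:
                r, g, b = self._color[rid]
                fh.write(f'{rid} {r} {g} {b} 1 1 1 "{self._name[rid]}"\n')


def _nearest_indices(n_out: int, n_src: int) -> np.ndarray:
    # pointwise sampling, same convention as transform.scale_pointwise
    return np.minimum(
        np.floor((np.arange(n_out) + 0.5) * n_src / n_out).astype(np.int64),
        n_src - 1,
    )


@dataclass
class AtlasMap:
    """Per-section 2D grid of non-negative integer region IDs (0 = outside).

    The sentinel -1 marks pixels excluded from quantification entirely
    (outside the active mask territory); it is produced by :func:`apply_mask`
    and never read from files.
    """

    section_id: int
    grid: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2 or self.grid.size == 0:
            raise ValidationError(
                f"section {self.section_id}: atlas map must be a non-empty 2D grid"
            )
        if self.grid.min() < -1:
            raise ValidationError(
                f"section {self.section_id}: atlas map contains negative IDs"
            )

    @property
    def width(self) -> int:
        return self.grid.shape[1]

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    def validate_against(self, labels: LabelTable) -> None:
        ids = np.unique(self.grid)
        unknown = [int(i) for i in ids if i != 0 and i not in labels]
        if unknown:
            raise ValidationError(
                f"section {self.section_id}: atlas IDs not in label table: {unknown}"
            )

    def rescaled(self, width: int, height: int) -> "AtlasMap":
        """Nearest-neighbor rescale to the segmentation grid (IDs preserved)."""
        if (width, height) == (self.width, self.height):
            return self
        xs = _nearest_indices(width, self.width)
        ys = _nearest_indices(height, self.height)
        return AtlasMap(self.section_id, self.grid[np.ix_(ys, xs)])

    # -- file dialects ------------------------------------------------------
    @classmethod
    def from_png(cls, path: str | os.PathLike, section_id: int) -> "AtlasMap":
        """24-bit RGB PNG interpreted as ID = R + 256*G + 65536*B."""
        rgb = load_rgb(path).astype(np.int64)
        grid = rgb[:, :, 0] + 256 * rgb[:, :, 1] + 65536 * rgb[:, :, 2]
        return cls(section_id, grid)

    @classmethod
    def from_text(cls, path: str | os.PathLike, section_id: int) -> "AtlasMap":
        """Whitespace-separated integer grid, one row per line."""
        grid = np.loadtxt(path, dtype=np.int64, ndmin=2)
        return cls(section_id, grid)

    @classmethod
    def load(cls, path: str | os.PathLike, section_id: int) -> "AtlasMap":
        path = Path(path)
        if path.suffix.lower() == ".png":
            return cls.from_png(path, section_id)
        return cls.from_text(path, section_id)

    def to_png(self, path: str | os.PathLike) -> None:
        grid = self.grid.astype(np.int64)
        if grid.max() > 0xFFFFFF:
            raise ValidationError("region IDs exceed 24-bit PNG encoding")
        rgb = np.stack(
            [grid % 256, (grid // 256) % 256, grid // 65536], axis=2
        ).astype(np.uint8)
        Image.fromarray(rgb).save(path)

    def region_pixel_counts(self) -> dict[int, int]:
        """Pixels per region ID; mask-excluded pixels (ID < 0) not counted."""
        ids, counts = np.unique(self.grid, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts) if i >= 0}


# ---------------------------------------------------------------------------
# segmentation objects
# ---------------------------------------------------------------------------


@dataclass
class SegmentationObject:
    """One connected component of object-colored pixels.

    ``pixels`` is an (N, 2) array of (x, y) indices in raster order.  After
    anchoring, ``assignments`` lists (region_id, pixel_count) pairs and
    ``region_id`` holds the single assigned region (for a split parent the
    sub-objects carry the per-region IDs).
    """

    object_id: str
    section_id: int
    pixels: np.ndarray
    image_width: int
    image_height: int
    territory: str | None = None
    assignments: list[tuple[int, int]] = field(default_factory=list)
    region_id: int | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.int64).reshape(-1, 2)
        if len(self.pixels) == 0:
            raise ParameterError("an object must contain at least one pixel")

    @property
    def area(self) -> int:
        return len(self.pixels)

    @property
    def centroid(self) -> tuple[float, float]:
        return (float(self.pixels[:, 0].mean()), float(self.pixels[:, 1].mean()))

    @property
    def bbox(self) -> BoundingBox:
        xs, ys = self.pixels[:, 0], self.pixels[:, 1]
        return BoundingBox(int(xs.min()), int(ys.min()), int(xs.max()), int(ys.max()))

    @property
    def shape_elongation(self) -> float:
        """Bounding-box aspect ratio >= 1 (the "shape" statistic)."""
        b = self.bbox
        lo, hi = sorted((b.width, b.height))
        return hi / lo


_OFFSETS = {
    4: ((0, -1), (0, 1), (-1, 0), (1, 0)),
    8: ((0, -1), (0, 1), (-1, 0), (1, 0), (-1, -1), (-1, 1), (1, -1), (1, 1)),
}


def _bfs_components(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Label connected components of a boolean mask by breadth-first search.

    Components are numbered 1.. in raster order of their first pixel;
    background is 0.  The BFS frontier is expanded a full layer at a time
    with vectorised neighbor arithmetic, which preserves BFS semantics while
    staying fast on large sections.
    """
    if connectivity not in _OFFSETS:
        raise ParameterError(f"connectivity must be 4 or 8, got {connectivity}")
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=np.int32)
    queued = ~np.asarray(mask, dtype=bool)  # background can never be queued
    # raster-order seeds: np.nonzero scans rows first
    seed_ys, seed_xs = np.nonzero(mask)
    offsets = np.asarray(_OFFSETS[connectivity], dtype=np.int64)
    current = 0
    for sy, sx in zip(seed_ys, seed_xs):
        if queued[sy, sx]:
            continue
        current += 1
        fy = np.asarray([sy], dtype=np.int64)
        fx = np.asarray([sx], dtype=np.int64)
        queued[fy, fx] = True
        while fy.size:
            labels[fy, fx] = current
            ny = (fy[:, None] + offsets[:, 0]).ravel()
            nx = (fx[:, None] + offsets[:, 1]).ravel()
            ok = (ny >= 0) & (ny < h) & (nx >= 0) & (nx < w)
            ny, nx = ny[ok], nx[ok]
            ok = ~queued[ny, nx]
            ny, nx = ny[ok], nx[ok]
            if ny.size:
                flat = np.unique(ny * w + nx)
                ny, nx = flat // w, flat % w
                queued[ny, nx] = True
            fy, fx = ny, nx
    return labels


def extract_objects(
    segmentation: np.ndarray,
    object_color: tuple[int, int, int],
    connectivity: int = 8,
    section_id: int = 0,
    territory: str | None = None,
) -> list[SegmentationObject]:
    """Connected components of pixels exactly matching ``object_color``.

    Object IDs are assigned in raster order of each component's first pixel,
    so extraction is deterministic.  No matching pixels yields an empty list.
    """
    seg = np.asarray(segmentation)
    if seg.ndim != 3 or seg.shape[2] < 3:
        raise InputError("segmentation must be an RGB image array")
    color = np.asarray(object_color, dtype=seg.dtype)
    mask = np.all(seg[:, :, :3] == color, axis=2)
    labels = _bfs_components(mask, connectivity)
    n = labels.max()
    objects = []
    h, w = mask.shape
    if n:
        order = np.argsort(labels.ravel(), kind="stable")
        flat = labels.ravel()[order]
        start = np.searchsorted(flat, np.arange(1, n + 1))
        stop = np.append(start[1:], flat.size)
        for i in range(n):
            idx = np.sort(order[start[i] : stop[i]])  # raster order
            pixels = np.column_stack((idx % w, idx // w))
            prefix = f"{territory}:" if territory else ""
            objects.append(
                SegmentationObject(
                    object_id=f"{prefix}{i + 1}",
                    section_id=section_id,
                    pixels=pixels,
                    image_width=w,
                    image_height=h,
                    territory=territory,
                )
            )
    return objects


def filter_by_size(
    objects: list[SegmentationObject], min_size: int = 1, max_size: int | None = None
) -> list[SegmentationObject]:
    """Keep objects with ``min_size <= area <= max_size`` (inclusive bounds)."""
    if min_size < 1:
        raise ParameterError(f"min_size must be >= 1, got {min_size}")
    if max_size is not None and max_size < min_size:
        raise ParameterError("max_size must be >= min_size")
    hi = float("inf") if max_size is None else max_size
    return [o for o in objects if min_size <= o.area <= hi]


def _object_rng(seed: int, section_id: int, object_id: str) -> np.random.Generator:
    # stable per-object stream: independent of processing order / concurrency
    digest = sum((i + 1) * b for i, b in enumerate(object_id.encode())) % (2**31)
    return np.random.default_rng([seed % (2**31), section_id, digest])


def assign_objects(
    objects: list[SegmentationObject],
    atlas: AtlasMap,
    splitting: bool = False,
    mode: str = "random_seeded",
    seed: int = 0,
) -> list[SegmentationObject]:
    """Anchor each object to atlas region(s) by per-pixel lookup.

    Splitting ON: each object overlapping N regions is replaced by N
    sub-objects, one per region, carrying that region's pixels (pixel counts
    conserved; object counts invalidated).  Splitting OFF: the whole object
    is assigned to a single overlapped region — chosen uniformly at random
    (``random_seeded``, reproducible from the seed) or to the region covering
    most of its pixels (``majority``, ties to the smaller region ID).

    Pixels over atlas ID 0 are tallied to the reserved outside-atlas row.
    """
    if mode not in {"random_seeded", "majority"}:
        raise ParameterError(f"assignment mode must be random_seeded or majority: {mode}")
    if not objects:
        return []
    w = objects[0].image_width
    h = objects[0].image_height
    grid = atlas.rescaled(w, h).grid
    out: list[SegmentationObject] = []
    for obj in objects:
        ids = grid[obj.pixels[:, 1], obj.pixels[:, 0]]
        uniq, counts = np.unique(ids, return_counts=True)
        overlapped = [(int(r), int(c)) for r, c in zip(uniq, counts)]
        if splitting and len(overlapped) > 1:
            for j, (rid, cnt) in enumerate(overlapped, start=1):
                sub = SegmentationObject(
                    object_id=f"{obj.object_id}.{j}",
                    section_id=obj.section_id,
                    pixels=obj.pixels[ids == rid],
                    image_width=w,
                    image_height=h,
                    territory=obj.territory,
                    assignments=[(rid, cnt)],
                    region_id=rid,
                )
                out.append(sub)
        else:
            if len(overlapped) == 1:
                rid = overlapped[0][0]
            elif mode == "majority":
                # max count, ties to the smaller region id
                rid = min(overlapped, key=lambda rc: (-rc[1], rc[0]))[0]
            else:
                rng = _object_rng(seed, obj.section_id, obj.object_id)
                rid = overlapped[rng.integers(len(overlapped))][0]
            obj = replace(obj)
            obj.assignments = [(rid, obj.area)]
            obj.region_id = rid
            out.append(obj)
    return out


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MaskSpec:
    """Per-section mask images partitioning sections into territories.

    ``territories`` maps a territory name (e.g. "left"/"right") to the RGB
    color painting it in the mask image.  Territory colors must be distinct;
    unmatched pixels belong to no territory.
    """

    mask_dir: str | os.PathLike
    territories: tuple[tuple[str, tuple[int, int, int]], ...]

    def __post_init__(self):
        colors = [tuple(c) for _, c in self.territories]
        if len(set(colors)) != len(colors):
            raise ValidationError("mask territory colors must be distinct")
        if not self.territories:
            raise ValidationError("mask requires at least one territory")


def apply_mask(
    segmentation: np.ndarray,
    atlas: AtlasMap,
    mask_image: np.ndarray,
    territories,
    object_color: tuple[int, int, int],
) -> dict[str, tuple[np.ndarray, AtlasMap]]:
    """Split a section into independent per-territory (segmentation, atlas) pairs.

    Each territory keeps exactly the pixels whose mask color matches its
    color; territories are disjoint by construction.  Outside the territory,
    segmentation pixels are overwritten with a fill color distinct from the
    object color, and atlas IDs are set to -1 so they are excluded from the
    territory's region-pixel denominators.  The mask is nearest-neighbor
    rescaled to the segmentation grid if needed.
    """
    seg = np.asarray(segmentation)
    h, w = seg.shape[:2]
    mask = np.asarray(mask_image)
    if mask.shape[:2] != (h, w):
        xs = _nearest_indices(w, mask.shape[1])
        ys = _nearest_indices(h, mask.shape[0])
        mask = mask[np.ix_(ys, xs)]
    if mask.shape[:2] != (h, w):
        raise ValidationError("mask dimensions do not match segmentation after rescale")
    grid = atlas.rescaled(w, h).grid
    fill = ((object_color[0] + 1) % 256, object_color[1], object_color[2])
    out = {}
    for name, color in territories:
        tmask = np.all(mask[:, :, :3] == np.asarray(color, dtype=mask.dtype), axis=2)
        if not tmask.any():
            logger.warning("mask territory %r matches no pixels", name)
        tseg = seg.copy()
        tseg[~tmask] = fill
        tgrid = np.where(tmask, grid, -1)
        out[name] = (tseg, AtlasMap(atlas.section_id, tgrid))
    return out


# ---------------------------------------------------------------------------
# custom regions
# ---------------------------------------------------------------------------


class CustomRegionSet:
    """User-defined ensembles of atlas region IDs reported as single units.

    CSV dialect: ``custom_name,color,member_ids`` with the color as
    ``R;G;B`` and member IDs ``;``-separated.  No atlas region may belong to
    two custom regions.
    """

    def __init__(self, rows: list[tuple[str, tuple[int, int, int], list[int]]]):
        seen: dict[int, str] = {}
        self.rows = []
        for name, color, member_ids in rows:
            member_ids = [int(i) for i in member_ids]
            for rid in member_ids:
                if rid in seen:
                    raise ValidationError(
                        f"region ID {rid} belongs to both {seen[rid]!r} and {name!r}"
                    )
                seen[rid] = name
            self.rows.append((str(name), tuple(int(c) for c in color), member_ids))

    def __len__(self) -> int:
        return len(self.rows)

    def validate_against(self, labels: LabelTable) -> None:
        for name, _, member_ids in self.rows:
            unknown = [i for i in member_ids if i not in labels]
            if unknown:
                raise ValidationError(
                    f"custom region {name!r} references unknown atlas IDs {unknown}"
                )

    def region_of(self, rid: int):
        for name, color, member_ids in self.rows:
            if rid in member_ids:
                return name, color
        return None

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "CustomRegionSet":
        rows = []
        with open(path, newline="") as fh:
            for rec in csv.DictReader(fh):
                color = tuple(int(c) for c in rec["color"].split(";"))
                if len(color) != 3:
                    raise ValidationError(f"bad color {rec['color']!r} in {path}")
                members = [int(i) for i in rec["member_ids"].split(";") if i.strip()]
                rows.append((rec["custom_name"], color, members))
        return cls(rows)

    def to_csv(self, path: str | os.PathLike) -> None:
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["custom_name", "color", "member_ids"])
            for name, color, member_ids in self.rows:
                wr.writerow(
                    [name, ";".join(map(str, color)), ";".join(map(str, member_ids))]
                )


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "section_id",
    "territory",
    "row_type",
    "region_id",
    "region_name",
    "region_pixels",
    "object_count",
    "object_pixels",
    "load",
]


def summarize(
    objects: list[SegmentationObject],
    atlas: AtlasMap,
    labels: LabelTable,
    custom_regions: CustomRegionSet | None = None,
    territory: str = "",
) -> pd.DataFrame:
    """Per-region quantification rows for one section (or one territory).

    One row per label-table region (zero-filled when unobserved), one
    reserved outside-atlas row, then one row per custom region summing its
    member rows.  ``load`` = object_pixels / region_pixels (0 when the
    region has no pixels in this section).
    """
    region_px = atlas.region_pixel_counts()
    obj_count: dict[int, int] = {}
    obj_px: dict[int, int] = {}
    for obj in objects:
        for rid, cnt in obj.assignments:
            obj_px[rid] = obj_px.get(rid, 0) + cnt
        if obj.region_id is not None:
            obj_count[obj.region_id] = obj_count.get(obj.region_id, 0) + 1
    rows = []
    for rid in [OUTSIDE_REGION_ID] + labels.region_ids:
        rp = region_px.get(rid, 0)
        op = obj_px.get(rid, 0)
        rows.append(
            {
                "section_id": atlas.section_id,
                "territory": territory,
                "row_type": "outside" if rid == OUTSIDE_REGION_ID else "atlas",
                "region_id": rid,
                "region_name": labels.name(rid),
                "region_pixels": rp,
                "object_count": obj_count.get(rid, 0),
                "object_pixels": op,
                "load": op / rp if rp else 0.0,
            }
        )
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if custom_regions is not None:
        df = pd.concat(
            [df, _custom_rows(df, custom_regions)], ignore_index=True
        )
    return df


def _custom_rows(df: pd.DataFrame, custom_regions: CustomRegionSet) -> pd.DataFrame:
    """Custom-region rows: column-wise sums of their member-region rows."""
    atlas_rows = df[df.row_type == "atlas"]
    rows = []
    for name, _, member_ids in custom_regions.rows:
        sub = atlas_rows[atlas_rows.region_id.isin(member_ids)]
        rp = int(sub.region_pixels.sum())
        op = int(sub.object_pixels.sum())
        rows.append(
            {
                "section_id": df.section_id.iloc[0] if len(df) else "",
                "territory": df.territory.iloc[0] if len(df) else "",
                "row_type": "custom",
                "region_id": -1,
                "region_name": name,
                "region_pixels": rp,
                "object_count": int(sub.object_count.sum()),
                "object_pixels": op,
                "load": op / rp if rp else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def aggregate_global(
    section_reports: list[pd.DataFrame], custom_regions: CustomRegionSet | None = None
) -> pd.DataFrame:
    """Global rows: column-wise sums of section rows, loads recomputed."""
    if not section_reports:
        raise ValidationError("no section reports to aggregate")
    allrows = pd.concat(section_reports, ignore_index=True)
    base = allrows[allrows.row_type != "custom"]
    grouped = (
        base.groupby(["territory", "row_type", "region_id", "region_name"], sort=False)[
            ["region_pixels", "object_count", "object_pixels"]
        ]
        .sum()
        .reset_index()
    )
    grouped.insert(0, "section_id", "all")
    grouped["load"] = np.where(
        grouped.region_pixels > 0, grouped.object_pixels / grouped.region_pixels, 0.0
    )
    out = grouped[REPORT_COLUMNS]
    if custom_regions is not None:
        parts = []
        for terr, sub in out.groupby("territory", sort=False):
            cr = _custom_rows(sub, custom_regions)
            cr["section_id"] = "all"
            cr["territory"] = terr
            parts.append(cr)
        out = pd.concat([out] + parts, ignore_index=True)
    return out


def write_report_csv(
    df: pd.DataFrame, path: str | os.PathLike, splitting: bool
) -> None:
    """Write a report CSV; a header comment flags split-invalidated counts."""
    buf = io.StringIO()
    if splitting:
        buf.write(
            "# object splitting ON: object_count is invalidated "
            "(objects are split at region boundaries)\n"
        )
    df.to_csv(buf, index=False, float_format="%.9g")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# overlays
# ---------------------------------------------------------------------------


def render_overlay(
    atlas: AtlasMap,
    labels: LabelTable,
    objects: list[SegmentationObject],
    output_path: str | os.PathLike,
    custom_regions: CustomRegionSet | None = None,
) -> Path:
    """Atlas map with color-coded objects superimposed.

    Regions are filled with a lightened version of their label color and
    annotated with their region ID; object pixels are painted in the
    full-saturation color of their assigned region (custom-region color when
    one covers it).
    """
    grid = atlas.grid
    h, w = grid.shape
    img = np.full((h, w, 3), 255, dtype=np.uint8)
    for rid in [i for i in np.unique(grid) if i > 0]:
        color = np.asarray(labels.color(int(rid)), dtype=np.float64)
        light = (0.5 * color + 0.5 * 255).astype(np.uint8)
        img[grid == rid] = light
    # region-ID annotations go under the objects so labeling stays visible
    pil = Image.fromarray(img)
    draw = ImageDraw.Draw(pil)
    for rid in [int(i) for i in np.unique(grid) if i > 0]:
        ys, xs = np.nonzero(grid == rid)
        draw.text(
            (float(xs.mean()), float(ys.mean())), str(rid), fill=(0, 0, 0), anchor="mm"
        )
    img = np.asarray(pil).copy()
    for obj in objects:
        rid = obj.region_id
        if rid is None:
            continue
        color = labels.color(rid)
        if custom_regions is not None and rid != OUTSIDE_REGION_ID:
            hit = custom_regions.region_of(rid)
            if hit is not None:
                color = hit[1]
        px = obj.pixels
        ok = (px[:, 0] < w) & (px[:, 1] < h)
        img[px[ok, 1], px[ok, 0]] = color
    pil = Image.fromarray(img)
    output_path = Path(output_path)
    output_path.parent.mkdir(parents=True, exist_ok=True)
    pil.save(output_path)
    return output_path


# ---------------------------------------------------------------------------
# batch runner
# ---------------------------------------------------------------------------


@dataclass
class QuantifierConfig:
    """Parameters of one quantification run (mirrors the run template)."""

    segmentation_dir: str | os.PathLike
    atlas_dir: str | os.PathLike
    anchoring_file: str | os.PathLike | None
    label_file: str | os.PathLike
    output_dir: str | os.PathLike
    object_color: tuple[int, int, int] = (0, 0, 0)
    connectivity: int = 8
    min_size: int = 1
    max_size: int | None = None
    splitting: bool = False
    assignment_mode: str = "random_seeded"
    rng_seed: int = 0
    mask: MaskSpec | None = None
    point_cloud_density: int = 1
    custom_region_file: str | os.PathLike | None = None
    coloring: str = "region"  # {"region", "custom"}
    workers: int = 1

    def __post_init__(self):
        if self.min_size < 1:
            raise ParameterError("min_size must be >= 1")
        if self.max_size is not None and self.max_size < self.min_size:
            raise ParameterError("min_size must not exceed max_size")
        if self.point_cloud_density < 1:
            raise ParameterError("point_cloud_density must be >= 1")
        if self.coloring not in {"region", "custom"}:
            raise ParameterError("coloring must be 'region' or 'custom'")


def _discover_sections(config: QuantifierConfig):
    """Pair segmentations with atlas maps (and masks) by their _sNNN token.

    Fail-fast: any unpaired section aborts the run before processing.
    """
    seg_dir = Path(config.segmentation_dir)
    atlas_dir = Path(config.atlas_dir)
    if not seg_dir.is_dir():
        raise InputError(f"segmentation directory does not exist: {seg_dir}")
    segs = {}
    for p in sorted(seg_dir.glob("*.png")):
        sid = section_id_of(p.name)
        if sid is not None:
            segs[sid] = p
    atlases = {}
    for p in sorted(atlas_dir.iterdir()) if atlas_dir.is_dir() else []:
        if p.suffix.lower() not in {".png", ".txt"}:
            continue
        sid = section_id_of(p.name)
        if sid is not None:
            atlases[sid] = p
    if not segs:
        raise ValidationError(f"no *_sNNN segmentation PNGs found in {seg_dir}")
    problems = []
    for sid in sorted(segs):
        if sid not in atlases:
            problems.append(f"section {sid}: segmentation without atlas map")
    for sid in sorted(atlases):
        if sid not in segs:
            problems.append(f"section {sid}: atlas map without segmentation")
    masks = {}
    if config.mask is not None:
        mask_dir = Path(config.mask.mask_dir)
        for p in sorted(mask_dir.glob("*.png")) if mask_dir.is_dir() else []:
            sid = section_id_of(p.name)
            if sid is not None:
                masks[sid] = p
        for sid in sorted(segs):
            if sid not in masks:
                problems.append(f"section {sid}: no mask image")
    if problems:
        raise ValidationError("unpaired sections:\n  " + "\n  ".join(problems))
    return segs, atlases, masks


def _process_section(
    sid: int,
    seg_path: Path,
    atlas_path: Path,
    mask_path: Path | None,
    config: QuantifierConfig,
    labels: LabelTable,
    custom_regions: CustomRegionSet | None,
):
    t0 = time.perf_counter()
    seg = load_rgb(seg_path)
    atlas = AtlasMap.load(atlas_path, sid)
    atlas.validate_against(labels)
    atlas = atlas.rescaled(seg.shape[1], seg.shape[0])
    units: list[tuple[str, np.ndarray, AtlasMap]] = []
    if config.mask is not None:
        mask_img = load_rgb(mask_path)
        parts = apply_mask(
            seg, atlas, mask_img, config.mask.territories, config.object_color
        )
        units = [(name, tseg, tatlas) for name, (tseg, tatlas) in parts.items()]
    else:
        units = [("", seg, atlas)]
    all_objects: list[SegmentationObject] = []
    reports = []
    for terr, tseg, tatlas in units:
        objs = extract_objects(
            tseg,
            config.object_color,
            connectivity=config.connectivity,
            section_id=sid,
            territory=terr or None,
        )
        objs = filter_by_size(objs, config.min_size, config.max_size)
        objs = assign_objects(
            objs,
            tatlas,
            splitting=config.splitting,
            mode=config.assignment_mode,
            seed=config.rng_seed,
        )
        reports.append(
            summarize(objs, tatlas, labels, custom_regions, territory=terr)
        )
        all_objects.extend(objs)
    report = pd.concat(reports, ignore_index=True)
    elapsed = time.perf_counter() - t0
    return sid, report, all_objects, atlas, elapsed


def run_quantifier(config: QuantifierConfig):
    """Run the full quantification pipeline over a paired section set.

    Writes per-section CSV reports, a combined global CSV, a point-cloud
    JSON, per-section overlay PNGs, and a run log.  Sections are independent
    units of work: results are invariant to processing order and to the
    number of workers.  Returns ``(global_report, point_cloud)``.
    """
    segs, atlases, masks = _discover_sections(config)
    labels = LabelTable.from_itksnap(config.label_file)
    custom_regions = (
        CustomRegionSet.from_csv(config.custom_region_file)
        if config.custom_region_file
        else None
    )
    if custom_regions is not None:
        custom_regions.validate_against(labels)
    if config.coloring == "custom" and custom_regions is None:
        raise ParameterError("coloring='custom' requires a custom region file")
    anchorings = (
        load_anchorings(config.anchoring_file) if config.anchoring_file else None
    )
    out_dir = Path(config.output_dir)
    (out_dir / "reports").mkdir(parents=True, exist_ok=True)
    (out_dir / "overlays").mkdir(parents=True, exist_ok=True)

    sids = sorted(segs)

    def work(sid):
        return _process_section(
            sid,
            segs[sid],
            atlases[sid],
            masks.get(sid),
            config,
            labels,
            custom_regions,
        )

    if config.workers > 1:
        with ThreadPoolExecutor(max_workers=config.workers) as pool:
            results = list(pool.map(work, sids))
    else:
        results = [work(sid) for sid in sids]
    results.sort(key=lambda r: r[0])

    section_reports = []
    all_objects: list[SegmentationObject] = []
    timings = {}
    for sid, report, objs, atlas, elapsed in results:
        section_reports.append(report)
        all_objects.extend(objs)
        timings[sid] = elapsed
        write_report_csv(
            report, out_dir / "reports" / f"report_s{sid:03d}.csv", config.splitting
        )
        render_overlay(
            atlas,
            labels,
            objs,
            out_dir / "overlays" / f"overlay_s{sid:03d}.png",
            custom_regions,
        )
    global_report = aggregate_global(section_reports, custom_regions)
    write_report_csv(global_report, out_dir / "reports" / "report_global.csv", config.splitting)

    cloud = None
    if anchorings is not None:
        missing = sorted(set(segs) - set(anchorings))
        if missing:
            raise ValidationError(f"sections without anchoring: {missing}")

        def group_of(obj):
            rid = obj.region_id
            if rid is None:
                return None
            if config.coloring == "custom":
                hit = custom_regions.region_of(rid)
                return hit  # objects outside any custom region are dropped
            return labels.name(rid), labels.color(rid)

        cloud = build_point_cloud(
            all_objects, anchorings, group_of, density=config.point_cloud_density
        )
        cloud.to_json(out_dir / "point_cloud.json")

    with open(out_dir / "run_log.txt", "w") as fh:
        fh.write("quantifier run\n")
        fh.write(f"object_color={config.object_color}\n")
        fh.write(f"connectivity={config.connectivity}\n")
        fh.write(f"min_size={config.min_size} max_size={config.max_size}\n")
        fh.write(f"splitting={config.splitting} mode={config.assignment_mode}\n")
        fh.write(f"rng_seed={config.rng_seed}\n")
        fh.write(f"point_cloud_density={config.point_cloud_density}\n")
        fh.write(f"workers={config.workers}\n")
        for sid in sids:
            fh.write(f"section {sid}: {timings[sid]:.3f}s\n")
    return global_report, cloud
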