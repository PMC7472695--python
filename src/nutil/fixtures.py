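"""Synthetic section datasets with planted, fully known ground truth.

Every pipeline stage can be tested without downloading an atlas or a scanned
dataset: this module generates the whole input dialect the quantifier
consumes — atlas-map PNGs, an ITK-SNAP label table, ``anchorings.json``,
segmentation PNGs, optional hemisphere masks — together with a ground-truth
CSV listing every planted object (section, region, area, centroid).

Design choices that keep the ground truth closed-form:

* atlas layouts are simple partitions (vertical stripes, concentric frames,
  or a seeded Voronoi tessellation);
* planted shapes are squares, discs and elongated bars, placed entirely
  inside their target region with at least one pixel of clearance from other
  objects and from region borders (so 8-connected extraction can never merge
  or split them);
* anchorings are axis-aligned with integer components
  (o = (0, 0, z_s), u = (w, 0, 0), v = (0, h, 0)), so the atlas coordinate of
  pixel (x, y) in section s is exactly (x + 0.5, y + 0.5, z_s);
* the generator is a pure function of its spec and seed.

Segmentations use the common convention of black (0, 0, 0) objects on a
white background.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .atlas_anchoring import SectionAnchoring, save_anchorings
from .errors import ParameterError, ValidationError
from .quantifier import AtlasMap, LabelTable, extract_objects

__all__ = [
    "PlantedObject",
    "FixtureSpec",
    "generate_fixture",
    "generate_boundary_object",
    "verify_fixture",
    "OBJECT_COLOR",
    "BACKGROUND_COLOR",
]

OBJECT_COLOR = (0, 0, 0)
BACKGROUND_COLOR = (255, 255, 255)

# distinct, stable display colors for generated label tables
_PALETTE = [
    (230, 25, 75), (60, 180, 75), (255, 225, 25), (0, 130, 200),
    (245, 130, 48), (145, 30, 180), (70, 240, 240), (240, 50, 230),
    (210, 245, 60), (250, 190, 190), (0, 128, 128), (170, 110, 40),
]


@dataclass(frozen=True)
class PlantedObject:
    """One object to plant: which section/region, its pixel area and shape."""

    section: int
    region: int
    area: int
    shape: str = "square"  # {"square", "disc", "bar"}

    def __post_init__(self):
        if self.shape not in {"square", "disc", "bar"}:
            raise ParameterError(f"unknown shape {self.shape!r}")
        if self.area < 1:
            raise ParameterError("planted area must be >= 1")


@dataclass(frozen=True)
class FixtureSpec:
    """Full description of a synthetic dataset; seed determines everything."""

    sections: int = 2
    image_size: tuple[int, int] = (160, 120)  # (w, h)
    n_regions: int = 4
    layout: str = "vertical_stripes"  # {"vertical_stripes", "concentric", "voronoi"}
    planted_objects: tuple[PlantedObject, ...] = ()
    salt_noise: int = 0  # single-pixel noise objects per section
    seed: int = 0

    def __post_init__(self):
        if self.sections < 1:
            raise ParameterError("need at least one section")
        if self.layout not in {"vertical_stripes", "concentric", "voronoi"}:
            raise ParameterError(f"unknown layout {self.layout!r}")
        if self.n_regions < 1:
            raise ParameterError("need at least one region")
        for po in self.planted_objects:
            if not (1 <= po.section <= self.sections):
                raise ParameterError(f"planted object section {po.section} out of range")
            if not (1 <= po.region <= self.n_regions):
                raise ParameterError(f"planted object region {po.region} out of range")


# ---------------------------------------------------------------------------
# atlas layouts
# ---------------------------------------------------------------------------


def _layout_grid(spec: FixtureSpec, rng: np.random.Generator) -> np.ndarray:
    w, h = spec.image_size
    k = spec.n_regions
    if spec.layout == "vertical_stripes":
        xs = np.arange(w)
        grid = np.tile((xs * k // w) + 1, (h, 1))
    elif spec.layout == "concentric":
        # nested frames, region 1 outermost
        ys, xs = np.mgrid[0:h, 0:w]
        d = np.minimum.reduce([xs, ys, w - 1 - xs, h - 1 - ys])
        step = max(1, min(w, h) // (2 * k))
        grid = np.minimum(d // step, k - 1) + 1
    else:  # voronoi
        pts = np.column_stack(
            [rng.integers(0, w, size=k), rng.integers(0, h, size=k)]
        ).astype(float)
        ys, xs = np.mgrid[0:h, 0:w]
        d2 = (xs[..., None] - pts[:, 0]) ** 2 + (ys[..., None] - pts[:, 1]) ** 2
        grid = np.argmin(d2, axis=2) + 1  # ties resolve to the smaller id
    return grid.astype(np.int64)


# ---------------------------------------------------------------------------
# planted shapes
# ---------------------------------------------------------------------------


def _shape_offsets(po: PlantedObject) -> np.ndarray:
    """(N, 2) (dx, dy) pixel offsets of the shape, anchored at its top-left."""
    if po.shape == "square":
        side = math.isqrt(po.area)
        if side * side != po.area:
            raise ParameterError(
                f"square object area must be a perfect square, got {po.area}"
            )
        dy, dx = np.mgrid[0:side, 0:side]
    elif po.shape == "bar":
        # elongated rectangle; folds into more rows when a single row would
        # be too long to fit typical fixture regions
        rows = 1
        while po.area // rows > 40 or po.area % rows:
            rows += 1
            if rows > po.area:
                raise ParameterError(f"cannot shape a bar of area {po.area}")
        dy, dx = np.mgrid[0:rows, 0 : po.area // rows]
    else:  # disc: radius from requested area; actual pixel count is recorded
        r = max(1.0, math.sqrt(po.area / math.pi))
        n = math.ceil(2 * r) + 1
        dy, dx = np.mgrid[0:n, 0:n]
        c = (n - 1) / 2.0
        keep = (dx - c) ** 2 + (dy - c) ** 2 <= r * r
        dx, dy = dx[keep], dy[keep]
        return np.column_stack([dx.ravel() - dx.min(), dy.ravel() - dy.min()])
    return np.column_stack([dx.ravel(), dy.ravel()])


def _place(
    offsets: np.ndarray,
    region_mask: np.ndarray,
    blocked: np.ndarray,
    rng: np.random.Generator,
    attempts: int = 500,
) -> tuple[int, int] | None:
    """Random top-left such that the shape fits the region and clears others."""
    h, w = region_mask.shape
    bw = int(offsets[:, 0].max()) + 1
    bh = int(offsets[:, 1].max()) + 1
    for _ in range(attempts):
        x0 = int(rng.integers(1, max(2, w - bw - 1)))
        y0 = int(rng.integers(1, max(2, h - bh - 1)))
        xs, ys = offsets[:, 0] + x0, offsets[:, 1] + y0
        if xs.max() >= w - 1 or ys.max() >= h - 1:
            continue
        if not region_mask[ys, xs].all():
            continue
        # one-pixel clearance so 8-connected components never merge
        x_lo, x_hi = xs.min() - 1, xs.max() + 2
        y_lo, y_hi = ys.min() - 1, ys.max() + 2
        if blocked[y_lo:y_hi, x_lo:x_hi].any():
            continue
        return x0, y0
    return None


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _label_table(spec: FixtureSpec) -> LabelTable:
    rows = [
        (rid, f"Region_{rid}", _PALETTE[(rid - 1) % len(_PALETTE)])
        for rid in range(1, spec.n_regions + 1)
    ]
    return LabelTable(rows)


def _anchorings(spec: FixtureSpec) -> dict[int, SectionAnchoring]:
    w, h = spec.image_size
    return {
        s: SectionAnchoring(
            section_id=s,
            o=(0.0, 0.0, float(20 * s)),
            u=(float(w), 0.0, 0.0),
            v=(0.0, float(h), 0.0),
            width=w,
            height=h,
            filename=f"seg_s{s:03d}.png",
        )
        for s in range(1, spec.sections + 1)
    }


def generate_fixture(spec: FixtureSpec, output_dir: str | os.PathLike) -> pd.DataFrame:
    """Write a complete synthetic dataset and return its ground truth.

    Output tree: ``atlas/atlas_sNNN.png``, ``segmentations/seg_sNNN.png``,
    ``labels.txt``, ``anchorings.json``, ``ground_truth.csv``.  The returned
    DataFrame equals the written CSV: one row per planted object with
    section_id, region_id, shape, area (actual pixel count), centroid_x/y
    and the section z-plane of every pixel's atlas coordinate.
    """
    output_dir = Path(output_dir)
    (output_dir / "atlas").mkdir(parents=True, exist_ok=True)
    (output_dir / "segmentations").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    w, h = spec.image_size
    layout_rng = np.random.default_rng([spec.seed, 1])
    grid = _layout_grid(spec, layout_rng)

    labels = _label_table(spec)
    labels.to_itksnap(output_dir / "labels.txt")
    anchorings = _anchorings(spec)
    save_anchorings(anchorings, output_dir / "anchorings.json")

    truth_rows = []
    for s in range(1, spec.sections + 1):
        seg = np.full((h, w, 3), BACKGROUND_COLOR, dtype=np.uint8)
        blocked = np.zeros((h, w), dtype=bool)
        section_rng = np.random.default_rng([spec.seed, 2, s])
        planted_here = [po for po in spec.planted_objects if po.section == s]
        for i, po in enumerate(planted_here):
            offsets = _shape_offsets(po)
            pos = _place(offsets, grid == po.region, blocked, section_rng)
            if pos is None:
                raise ValidationError(
                    f"planted object {i} (section {s}, region {po.region}, "
                    f"area {po.area}, {po.shape}) does not fit in its region"
                )
            xs, ys = offsets[:, 0] + pos[0], offsets[:, 1] + pos[1]
            seg[ys, xs] = OBJECT_COLOR
            blocked[ys, xs] = True
            truth_rows.append(
                {
                    "section_id": s,
                    "region_id": po.region,
                    "shape": po.shape,
                    "area": len(xs),
                    "centroid_x": float(xs.mean()),
                    "centroid_y": float(ys.mean()),
                    "z_plane": float(20 * s),
                }
            )
        for _ in range(spec.salt_noise):
            pos = _place(np.zeros((1, 2), dtype=np.int64), grid > 0, blocked, section_rng)
            if pos is None:
                raise ValidationError("no free pixel left for salt noise")
            seg[pos[1], pos[0]] = OBJECT_COLOR
            blocked[pos[1], pos[0]] = True
            truth_rows.append(
                {
                    "section_id": s,
                    "region_id": int(grid[pos[1], pos[0]]),
                    "shape": "salt",
                    "area": 1,
                    "centroid_x": float(pos[0]),
                    "centroid_y": float(pos[1]),
                    "z_plane": float(20 * s),
                }
            )
        Image.fromarray(seg).save(output_dir / "segmentations" / f"seg_s{s:03d}.png")
        AtlasMap(s, grid).to_png(output_dir / "atlas" / f"atlas_s{s:03d}.png")

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "section_id", "region_id", "shape", "area",
            "centroid_x", "centroid_y", "z_plane",
        ],
    )
    truth = truth.sort_values(
        ["section_id", "centroid_y", "centroid_x"], kind="stable"
    ).reset_index(drop=True)
    truth.to_csv(output_dir / "ground_truth.csv", index=False, float_format="%.9g")
    return truth


def generate_boundary_object(
    spec: FixtureSpec,
    region_a: int,
    region_b: int,
    pixels_a: int,
    pixels_b: int,
    output_dir: str | os.PathLike,
    section: int = 1,
    row: int | None = None,
) -> dict:
    """Plant one connected object straddling two adjacent stripe regions.

    The object is a 1-pixel-high bar crossing the stripe boundary with
    exactly ``pixels_a`` pixels in ``region_a`` and ``pixels_b`` in
    ``region_b`` (both must be positive: a non-straddling request is
    rejected).  Requires the vertical-stripes layout with ``region_b ==
    region_a + 1``.  Returns the planted pixel sets per region.
    """
    if spec.layout != "vertical_stripes":
        raise ParameterError("boundary objects require the vertical_stripes layout")
    if region_b != region_a + 1:
        raise ParameterError(
            f"regions {region_a} and {region_b} are not adjacent stripes"
        )
    if pixels_a < 1 or pixels_b < 1:
        raise ParameterError("a straddling object needs pixels in both regions")
    w, h = spec.image_size
    grid = _layout_grid(spec, np.random.default_rng([spec.seed, 1]))
    boundary_cols = np.flatnonzero(grid[0, :-1] != grid[0, 1:])
    col = None
    for c in boundary_cols:
        if grid[0, c] == region_a and grid[0, c + 1] == region_b:
            col = int(c)
            break
    if col is None:
        raise ParameterError(f"no stripe boundary between {region_a} and {region_b}")
    x_lo = col - pixels_a + 1
    x_hi = col + pixels_b
    if x_lo < 0 or x_hi >= w:
        raise ParameterError("straddling bar does not fit inside the image")
    if row is None:
        row = h // 2
    base = FixtureSpec(
        sections=spec.sections,
        image_size=spec.image_size,
        n_regions=spec.n_regions,
        layout=spec.layout,
        planted_objects=(),
        seed=spec.seed,
    )
    generate_fixture(base, output_dir)
    seg_path = Path(output_dir) / "segmentations" / f"seg_s{section:03d}.png"
    seg = np.asarray(Image.open(seg_path).convert("RGB")).copy()
    seg[row, x_lo : x_hi + 1] = OBJECT_COLOR
    Image.fromarray(seg).save(seg_path)
    return {
        "section": section,
        "row": row,
        "pixels": {region_a: pixels_a, region_b: pixels_b},
        "x_range": (x_lo, x_hi),
    }


def verify_fixture(output_dir: str | os.PathLike) -> bool:
    """Re-derive the ground truth from the written pixels and compare.

    Re-reads the segmentations and atlas maps, re-extracts 8-connected
    objects, assigns each to the (unique, by construction) region under its
    pixels, and checks the rebuilt table equals ``ground_truth.csv``.
    Raises :class:`ValidationError` on any discrepancy.
    """
    output_dir = Path(output_dir)
    written = pd.read_csv(output_dir / "ground_truth.csv")
    rows = []
    for seg_path in sorted((output_dir / "segmentations").glob("seg_s*.png")):
        sid = int(seg_path.stem.split("_s")[1])
        seg = np.asarray(Image.open(seg_path).convert("RGB"))
        atlas = AtlasMap.from_png(output_dir / "atlas" / f"atlas_s{sid:03d}.png", sid)
        for obj in extract_objects(seg, OBJECT_COLOR, connectivity=8, section_id=sid):
            ids = np.unique(atlas.grid[obj.pixels[:, 1], obj.pixels[:, 0]])
            if len(ids) != 1:
                raise ValidationError(
                    f"section {sid}: planted object straddles regions {ids}"
                )
            cx, cy = obj.centroid
            rows.append(
                {
                    "section_id": sid,
                    "region_id": int(ids[0]),
                    "area": obj.area,
                    "centroid_x": cx,
                    "centroid_y": cy,
                    "z_plane": float(20 * sid),
                }
            )
    rebuilt = (
        pd.DataFrame(
            rows,
            columns=["section_id", "region_id", "area", "centroid_x", "centroid_y", "z_plane"],
        )
        .sort_values(["section_id", "centroid_y", "centroid_x"], kind="stable")
        .reset_index(drop=True)
    )
    ref = written[rebuilt.columns].reset_index(drop=True)
    if len(ref) != len(rebuilt):
        raise ValidationError(
            f"object count mismatch: wrote {len(ref)}, re-derived {len(rebuilt)}"
        )
    if not np.allclose(ref.to_numpy(float), rebuilt.to_numpy(float), atol=1e-9):
        raise ValidationError("re-derived ground truth differs from written CSV")
    return True
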