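"""Linear section anchoring: mapping 2D section pixels into 3D atlas space.

A registered section is placed in the reference atlas by a linear anchoring:
an origin vector ``o`` (atlas position of the section's top-left corner) and
two in-plane axis vectors ``u`` and ``v`` spanning the section's full pixel
width and height.  A pixel ``(x, y)`` of a ``width x height`` section then
maps to

    o + ((x + 0.5) / width) * u + ((y + 0.5) / height) * v

using the pixel-center convention (the +0.5 half-pixel inset); a corner
convention (no inset) is available for cross-tool comparison.  All
coordinates are in atlas voxel units with the axis order of the anchoring
file; no RAS conversion is applied.

Anchorings are read from a JSON file (``anchorings.json``), one entry per
section: ``{"filename", "section_id", "width", "height", "ox","oy","oz",
"ux","uy","uz", "vx","vy","vz"}``.

Point clouds sampled from anchored objects (every k-th object pixel in
row-major order) are exported as JSON groups of flat coordinate triplets,
the layout consumed by atlas point-cloud viewers such as MeshView.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError, ValidationError

__all__ = [
    "SectionAnchoring",
    "PointCloud",
    "PointGroup",
    "load_anchorings",
    "pixel_to_atlas",
    "build_point_cloud",
]


@dataclass(frozen=True)
class SectionAnchoring:
    """Linear placement of one section's pixel grid in 3D atlas space."""

    section_id: int
    o: tuple[float, float, float]
    u: tuple[float, float, float]
    v: tuple[float, float, float]
    width: int
    height: int
    filename: str | None = None

    def __post_init__(self):
        if self.width < 1 or self.height < 1:
            raise ValidationError(
                f"section {self.section_id}: anchoring width/height must be >= 1"
            )
        u, v = np.asarray(self.u, float), np.asarray(self.v, float)
        if u.shape != (3,) or v.shape != (3,):
            raise ValidationError(f"section {self.section_id}: u and v must be 3-vectors")
        cross = np.cross(u, v)
        norm = np.linalg.norm(u) * np.linalg.norm(v)
        if norm == 0.0 or np.linalg.norm(cross) <= 1e-12 * norm:
            raise ValidationError(
                f"section {self.section_id}: axis vectors u and v are degenerate "
                "(zero-length or parallel)"
            )


def load_anchorings(path: str | os.PathLike) -> dict[int, SectionAnchoring]:
    """Parse an ``anchorings.json`` file into ``{section_id: SectionAnchoring}``.

    Malformed entries (missing fields, duplicate section ids, degenerate
    u/v) raise :class:`ValidationError` naming the offending section.
    """
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh)
    if isinstance(raw, dict) and "sections" in raw:
        raw = raw["sections"]
    if not isinstance(raw, list):
        raise ValidationError(f"{path}: expected a JSON list of section anchorings")
    out: dict[int, SectionAnchoring] = {}
    for entry in raw:
        sid = entry.get("section_id")
        if sid is None:
            raise ValidationError(f"{path}: entry without section_id: {entry}")
        required = [
            "width", "height",
            "ox", "oy", "oz", "ux", "uy", "uz", "vx", "vy", "vz",
        ]
        missing = [k for k in required if k not in entry]
        if missing:
            raise ValidationError(
                f"{path}: section {sid} is missing fields {missing}"
            )
        if sid in out:
            raise ValidationError(f"{path}: duplicate section_id {sid}")
        out[int(sid)] = SectionAnchoring(
            section_id=int(sid),
            o=(entry["ox"], entry["oy"], entry["oz"]),
            u=(entry["ux"], entry["uy"], entry["uz"]),
            v=(entry["vx"], entry["vy"], entry["vz"]),
            width=int(entry["width"]),
            height=int(entry["height"]),
            filename=entry.get("filename"),
        )
    return out


def save_anchorings(
    anchorings: dict[int, SectionAnchoring], path: str | os.PathLike
) -> None:
    """Inverse of :func:`load_anchorings` (used by the fixture generator)."""
    entries = []
    for sid in sorted(anchorings):
        a = anchorings[sid]
        entries.append(
            {
                "filename": a.filename,
                "section_id": a.section_id,
                "width": a.width,
                "height": a.height,
                "ox": a.o[0], "oy": a.o[1], "oz": a.o[2],
                "ux": a.u[0], "uy": a.u[1], "uz": a.u[2],
                "vx": a.v[0], "vy": a.v[1], "vz": a.v[2],
            }
        )
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=1)


def pixel_to_atlas(
    a: SectionAnchoring,
    x,
    y,
    image_width: int | None = None,
    image_height: int | None = None,
    pixel_center: bool = True,
) -> np.ndarray:
    """Map pixel indices ``(x, y)`` to a 3D atlas coordinate.

    ``x``/``y`` may be scalars or arrays; the result has shape ``(..., 3)``.
    If the segmentation was produced at a different resolution than the
    registered image, pass its ``image_width``/``image_height``: pixel
    coordinates are rescaled proportionally (the fractional position along
    u and v is what matters, not absolute pixel counts).
    """
    w = int(image_width) if image_width is not None else a.width
    h = int(image_height) if image_height is not None else a.height
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x < 0) or np.any(x >= w) or np.any(y < 0) or np.any(y >= h):
        raise ParameterError(
            f"pixel index out of range for a {w}x{h} section (section {a.section_id})"
        )
    inset = 0.5 if pixel_center else 0.0
    fx = (x + inset) / w
    fy = (y + inset) / h
    o = np.asarray(a.o, float)
    u = np.asarray(a.u, float)
    v = np.asarray(a.v, float)
    return o + fx[..., None] * u + fy[..., None] * v


@dataclass
class PointGroup:
    """One colorized group of 3D points (flat ``[x1,y1,z1,x2,...]`` triplets)."""

    name: str
    color: tuple[int, int, int]
    triplets: list[float] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.triplets) // 3


@dataclass
class PointCloud:
    """Groups of colorized atlas-space points for a whole run."""

    groups: list[PointGroup] = field(default_factory=list)

    @property
    def total_points(self) -> int:
        return sum(g.count for g in self.groups)

    def to_json(self, path: str | os.PathLike) -> None:
        payload = [
            {
                "name": g.name,
                "r": g.color[0],
                "g": g.color[1],
                "b": g.color[2],
                "count": g.count,
                "triplets": g.triplets,
            }
            for g in self.groups
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "PointCloud":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            groups=[
                PointGroup(
                    name=g["name"],
                    color=(g["r"], g["g"], g["b"]),
                    triplets=list(g["triplets"]),
                )
                for g in payload
            ]
        )


def sample_pixels(pixels: np.ndarray, k: int) -> np.ndarray:
    """Every k-th pixel of an object, row-major (sorted by y, then x).

    Yields ``ceil(len(pixels)/k)`` pixels: indices 0, k, 2k, ...
    """
    if k < 1:
        raise ParameterError(f"point-cloud density k must be >= 1, got {k}")
    pixels = np.asarray(pixels)
    order = np.lexsort((pixels[:, 0], pixels[:, 1]))
    return pixels[order][::k]


def build_point_cloud(
    objects,
    anchorings: dict[int, SectionAnchoring],
    group_of,
    density: int = 1,
    pixel_center: bool = True,
) -> PointCloud:
    """Project every k-th pixel of each object into atlas space.

    ``objects`` are anchored segmentation objects (each with ``section_id``
    and ``pixels``, plus whatever ``group_of`` needs); ``group_of(obj)``
    returns ``(name, (r, g, b))`` — typically the object's atlas region or
    its custom region — or ``None`` to leave the object out of the cloud.
    ``density`` takes one coordinate per k-th object pixel (k=5 keeps every
    fifth pixel of large connectivity-style objects).
    """
    missing = sorted(
        {obj.section_id for obj in objects if obj.section_id not in anchorings}
    )
    if missing:
        raise ValidationError(
            f"no anchoring for sections with objects: {missing}"
        )
    groups: dict[str, PointGroup] = {}
    for obj in objects:
        key = group_of(obj)
        if key is None:
            continue
        name, color = key
        anchor = anchorings[obj.section_id]
        taken = sample_pixels(np.asarray(obj.pixels), density)
        coords = pixel_to_atlas(
            anchor,
            taken[:, 0],
            taken[:, 1],
            image_width=getattr(obj, "image_width", None),
            image_height=getattr(obj, "image_height", None),
            pixel_center=pixel_center,
        )
        grp = groups.setdefault(name, PointGroup(name=name, color=tuple(color)))
        grp.triplets.extend(float(c) for c in coords.ravel())
    return PointCloud(groups=[groups[k] for k in sorted(groups)])
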