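"""Plain-text run templates (.NUT files).

A run template is a UTF-8 ``key=value`` file.  Lines starting with ``#`` are
comments.  Keys before the first ``file=`` line are global; each ``file=``
line opens a per-file block that inherits the globals and may override them.
Values are plain strings; RGB colors are ``R;G;B`` triples.

Example (transform run)::

    tool=transform
    background=255;255;255
    autocrop=true
    file=brain_s001.tif
    rotation=90
    file=brain_s002.tif
    rotation=-90
    flip_h=true
"""

from __future__ import annotations

import os
from pathlib import Path

from .errors import InputError, ParameterError

__all__ = ["parse_nut", "parse_color", "parse_bool"]


def parse_color(value: str) -> tuple[int, int, int]:
    parts = value.replace(",", ";").split(";")
    if len(parts) != 3:
        raise ParameterError(f"expected R;G;B color, got {value!r}")
    return tuple(int(p) for p in parts)  # type: ignore[return-value]


def parse_bool(value: str) -> bool:
    v = value.strip().lower()
    if v in {"1", "true", "yes", "on"}:
        return True
    if v in {"0", "false", "no", "off"}:
        return False
    raise ParameterError(f"expected a boolean, got {value!r}")


def parse_nut(path: str | os.PathLike) -> tuple[dict, list[dict]]:
    """Parse a .NUT template into ``(globals, per-file blocks)``.

    Each per-file block is a dict containing at least ``file`` and every
    global key (overridden by block-local assignments).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such template: {path}")
    globals_: dict[str, str] = {}
    blocks: list[dict] = []
    current: dict | None = None
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ParameterError(f"{path}:{ln}: expected key=value, got {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key == "file":
            current = dict(globals_)
            current["file"] = value
            blocks.append(current)
        elif current is None:
            globals_[key] = value
        else:
            current[key] = value
    return globals_, blocks
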