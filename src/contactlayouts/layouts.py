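"""Deterministic 2D geometry for the three contact-layout encodings.

Each layout encodes a single spatial contact on a segmented chain:

* ``matrix`` — full n x n adjacency matrix; the contact fills the two
  symmetric cells (a, b) and (b, a), and the diagonal carries the
  alternating light/dark segment shading (intrasegment contacts are not
  encoded, so the diagonal is free to act as a segment ruler).
* ``half_matrix`` — the upper triangle only, drawn as a 45-degree-rotated
  triangle resting on a horizontal base row of shaded segment cells; the
  contact fills exactly one cell.
* ``circular`` — the chain bent into a circle of equal arcs (segment 1 at
  the top, proceeding clockwise), with the contact drawn as a straight
  chord between the midpoints of the two contact arcs; the contact arcs
  are highlighted as well.

All coordinates live in the unit square; :func:`write_svg` renders them as
byte-deterministic standalone SVG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

from .stimuli import Contact

__all__ = [
    "LayoutGeometry",
    "Primitive",
    "matrix_geometry",
    "half_matrix_geometry",
    "circular_geometry",
    "contact_geometry",
    "write_svg",
]

LIGHT, DARK, GREEN = "light_gray", "dark_gray", "green"

FILL_COLORS = {
    LIGHT: "#d9d9d9",
    DARK: "#737373",
    GREEN: "#2ca25f",
}


@dataclass(frozen=True)
class Primitive:
    """One drawable element.

    ``shape`` is one of cell, triangle_cell, node_arc_segment, chord;
    ``key`` identifies the element logically (grid indices, segment number,
    or contact endpoints) so that geometric invariants can be tested
    without parsing coordinates; ``coords`` are unit-square reals whose
    meaning depends on the shape.
    """

    shape: str
    key: tuple
    coords: tuple[float, ...]
    fill: str


@dataclass(frozen=True)
class LayoutGeometry:
    layout: str
    n_segments: int
    primitives: tuple[Primitive, ...]

    def green(self) -> tuple[Primitive, ...]:
        return tuple(p for p in self.primitives if p.fill == GREEN)


def _segment_fill(i: int) -> str:
    # segment 1 is light; shades alternate along the chain
    return LIGHT if i % 2 == 1 else DARK


def _check(contact: Contact, n_segments: int) -> None:
    if contact.b > n_segments:
        raise ValueError(f"contact {contact} exceeds n_segments={n_segments}")


def matrix_geometry(contact: Contact, n_segments: int) -> LayoutGeometry:
    """Full symmetric adjacency-matrix encoding of one contact.

    Cells are squares of side 1/n; cell (row i, column j) has its top-left
    corner at ((j-1)/n, (i-1)/n).  Only diagonal (shaded) and contact
    (green) cells are emitted; empty cells are left to the background.
    """
    _check(contact, n_segments)
    n = n_segments
    s = 1.0 / n

    def cell(i: int, j: int, fill: str) -> Primitive:
        return Primitive("cell", ("cell", i, j), ((j - 1) * s, (i - 1) * s, s, s), fill)

    prims = [cell(i, i, _segment_fill(i)) for i in range(1, n + 1)]
    prims.append(cell(contact.a, contact.b, GREEN))
    prims.append(cell(contact.b, contact.a, GREEN))
    return LayoutGeometry("matrix", n, tuple(prims))


def half_matrix_geometry(contact: Contact, n_segments: int) -> LayoutGeometry:
    """Upper-triangle encoding: one green cell per contact, shaded base row.

    The triangle is the full matrix rotated 45 degrees so its diagonal
    becomes a horizontal base.  Cell (i, j) with i <= j is a diamond of
    half-diagonal 1/(2n) centered at x = (i + j - 1)/(2n), y measured
    upward from the base as (j - i)/(2n); base cells are the (i, i)
    diamonds carrying the segment shading.
    """
    _check(contact, n_segments)
    n = n_segments
    r = 1.0 / (2 * n)

    def diamond(i: int, j: int, fill: str) -> Primitive:
        cx = (i + j - 1) / (2 * n)
        cy = (j - i) / (2 * n)
        return Primitive("triangle_cell", ("cell", i, j), (cx, cy, r), fill)

    prims = [diamond(i, i, _segment_fill(i)) for i in range(1, n + 1)]
    prims.append(diamond(contact.a, contact.b, GREEN))
    return LayoutGeometry("half_matrix", n, tuple(prims))


def circular_geometry(contact: Contact, n_segments: int) -> LayoutGeometry:
    """Circular encoding: shaded arcs plus one chord for the contact.

    Segment k occupies the clockwise arc from angle 90 - (k-1)*360/n to
    90 - k*360/n degrees (segment 1 starts at the top).  Arc coordinates
    are (start_angle, end_angle) in radians on the unit circle; the chord
    joins the arc midpoints of the two contact segments.  The contact arcs
    are green, the rest carry the alternating segment shading.
    """
    _check(contact, n_segments)
    n = n_segments
    step = 2 * math.pi / n

    def arc_angles(k: int) -> tuple[float, float]:
        start = math.pi / 2 - (k - 1) * step
        return (start, start - step)

    prims = []
    for k in range(1, n + 1):
        fill = GREEN if k in (contact.a, contact.b) else _segment_fill(k)
        prims.append(Primitive("node_arc_segment", ("arc", k), arc_angles(k), fill))

    def midpoint(k: int) -> tuple[float, float]:
        theta = math.pi / 2 - (k - 0.5) * step
        return (math.cos(theta), math.sin(theta))

    x1, y1 = midpoint(contact.a)
    x2, y2 = midpoint(contact.b)
    prims.append(
        Primitive("chord", ("chord", contact.a, contact.b), (x1, y1, x2, y2), GREEN)
    )
    return LayoutGeometry("circular", n, tuple(prims))


_BUILDERS = {
    "matrix": matrix_geometry,
    "half_matrix": half_matrix_geometry,
    "circular": circular_geometry,
}


def contact_geometry(layout: str, contact: Contact, n_segments: int) -> LayoutGeometry:
    """Dispatch to the named layout's geometry builder."""
    try:
        return _BUILDERS[layout](contact, n_segments)
    except KeyError:
        raise ValueError(f"unknown layout {layout!r}") from None


def _fmt(x: float) -> str:
    return f"{x:.4f}"


def _svg_elements(geom: LayoutGeometry, size: float, margin: float) -> list[str]:
    span = size - 2 * margin
    out = []
    for p in geom.primitives:
        color = FILL_COLORS[p.fill]
        if p.shape == "cell":
            x, y, w, h = p.coords
            out.append(
                f'<rect x="{_fmt(margin + x * span)}" y="{_fmt(margin + y * span)}" '
                f'width="{_fmt(w * span)}" height="{_fmt(h * span)}" fill="{color}"/>'
            )
        elif p.shape == "triangle_cell":
            cx, cy, r = p.coords
            # y grows upward from the base in geometry space; flip for SVG
            px, py = margin + cx * span, size - margin - cy * span
            d = r * span
            pts = f"{_fmt(px)},{_fmt(py - d)} {_fmt(px + d)},{_fmt(py)} " \
                  f"{_fmt(px)},{_fmt(py + d)} {_fmt(px - d)},{_fmt(py)}"
            out.append(f'<polygon points="{pts}" fill="{color}"/>')
        elif p.shape == "node_arc_segment":
            start, end = p.coords
            cx = cy = size / 2
            rad = span / 2
            x1 = cx + rad * math.cos(start)
            y1 = cy - rad * math.sin(start)
            x2 = cx + rad * math.cos(end)
            y2 = cy - rad * math.sin(end)
            out.append(
                f'<path d="M {_fmt(x1)} {_fmt(y1)} A {_fmt(rad)} {_fmt(rad)} 0 0 1 '
                f'{_fmt(x2)} {_fmt(y2)}" fill="none" stroke="{color}" '
                f'stroke-width="{_fmt(size * 0.05)}"/>'
            )
        elif p.shape == "chord":
            x1, y1, x2, y2 = p.coords
            cx = cy = size / 2
            rad = span / 2
            out.append(
                f'<line x1="{_fmt(cx + rad * x1)}" y1="{_fmt(cy - rad * y1)}" '
                f'x2="{_fmt(cx + rad * x2)}" y2="{_fmt(cy - rad * y2)}" '
                f'stroke="{color}" stroke-width="{_fmt(size * 0.02)}"/>'
            )
        else:  # pragma: no cover - guarded by Primitive construction
            raise ValueError(f"unknown primitive shape {p.shape!r}")
    return out


def write_svg(
    geometry: LayoutGeometry, path: Union[str, Path], size: float = 320.0
) -> Path:
    """Write a geometry as a standalone SVG file.

    Output contains no timestamps or environment state, so identical
    geometry always produces byte-identical files.
    """
    margin = size * 0.08
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_fmt(size)}" '
        f'height="{_fmt(size)}" viewBox="0 0 {_fmt(size)} {_fmt(size)}">',
        f'<rect x="0" y="0" width="{_fmt(size)}" height="{_fmt(size)}" fill="#ffffff"/>',
        *_svg_elements(geometry, size, margin),
        "</svg>",
    ]
    path = Path(path)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
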