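"""Rasterize polygon annotations into label masks and trace regions back out.

Rasterization uses a pixel-center inclusion test: pixel (row r, col c) is set
when the point (x=c, y=r) lies inside the polygon under the chosen fill rule
(nonzero winding by default, even-odd optional) or exactly on its boundary.
Overlaps between a participant's polygons are resolved by draw order — the
later-drawn polygon wins — and pixels covered by no polygon receive the
taxonomy's default class (stroma, "defined by absence of annotations").
Reviewer correction overlays are patched on top of the rendered mask and
always outrank the original annotations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from skimage import measure

from .annotation_model import (
    AnnotationSet,
    AnnotationValidationError,
    ClassTaxonomy,
    LabelMask,
    PolygonAnnotation,
)

__all__ = [
    "RenderPolicy",
    "Region",
    "DegeneratePolygonWarning",
    "rasterize_polygon",
    "render_annotation_set",
    "apply_corrections",
    "extract_regions",
    "trace_component_polygon",
]

_EPS_BOUNDARY = 1e-9
_EPS_AREA = 1e-12


class DegeneratePolygonWarning(UserWarning):
    """A zero-area polygon rasterized to an empty mask."""


@dataclass(frozen=True)
class RenderPolicy:
    """Rendering semantics, fixed per render call.

    ``overlap_rule`` is fixed to later-drawn-wins (draw order is the only
    precedence signal annotation platforms record). ``fill_rule`` selects the
    interior test for self-overlapping outlines; ``clip_to_roi`` records that
    geometry outside the ROI grid is discarded (rasters never extend past it).
    """

    overlap_rule: str = "later_drawn_wins"
    clip_to_roi: bool = True
    fill_rule: str = "nonzero"  # or "evenodd"

    def __post_init__(self) -> None:
        if self.overlap_rule != "later_drawn_wins":
            raise ValueError("overlap_rule is fixed to 'later_drawn_wins'")
        if self.fill_rule not in ("nonzero", "evenodd"):
            raise ValueError(f"fill_rule must be 'nonzero' or 'evenodd', got {self.fill_rule!r}")


def _shoelace_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _inside_mask(verts: np.ndarray, xs: np.ndarray, ys: np.ndarray, fill_rule: str) -> np.ndarray:
    """Vectorized interior + boundary test for a grid of points.

    ``xs``/``ys`` are flat coordinate arrays of equal length. Interior is
    winding-number (nonzero) or crossing-parity (even-odd); points within
    ``_EPS_BOUNDARY`` of an edge are always included.
    """
    n = len(verts)
    wn = np.zeros(xs.shape, dtype=np.int64)
    parity = np.zeros(xs.shape, dtype=bool)
    on_edge = np.zeros(xs.shape, dtype=bool)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        dy = y2 - y1
        is_left = (x2 - x1) * (ys - y1) - (xs - x1) * dy
        if fill_rule == "nonzero":
            up = (y1 <= ys) & (ys < y2) & (is_left > 0)
            down = (y2 <= ys) & (ys < y1) & (is_left < 0)
            wn += up.astype(np.int64)
            wn -= down.astype(np.int64)
        else:
            crosses = (y1 > ys) != (y2 > ys)
            if np.any(crosses):
                with np.errstate(divide="ignore", invalid="ignore"):
                    x_int = x1 + (ys - y1) * (x2 - x1) / dy
                parity ^= crosses & (xs < x_int)
        # distance of points to the closed segment
        ex, ey = x2 - x1, y2 - y1
        seg2 = ex * ex + ey * ey
        if seg2 < _EPS_AREA:
            d2 = (xs - x1) ** 2 + (ys - y1) ** 2
        else:
            t = np.clip(((xs - x1) * ex + (ys - y1) * ey) / seg2, 0.0, 1.0)
            d2 = (xs - (x1 + t * ex)) ** 2 + (ys - (y1 + t * ey)) ** 2
        on_edge |= d2 <= _EPS_BOUNDARY
    interior = (wn != 0) if fill_rule == "nonzero" else parity
    return interior | on_edge


def rasterize_polygon(
    p: PolygonAnnotation,
    height: int,
    width: int,
    policy: RenderPolicy = RenderPolicy(),
) -> np.ndarray:
    """Binary (height x width) mask of the pixels whose centers fall inside
    the closed polygon (boundary-inclusive). Degenerate zero-area polygons
    yield an empty mask with a :class:`DegeneratePolygonWarning`."""
    verts = p.vertex_array()
    out = np.zeros((height, width), dtype=bool)
    if abs(_shoelace_area(verts)) < _EPS_AREA:
        warnings.warn(
            f"polygon (class {p.class_name!r}, draw_order {p.draw_order}) has zero area",
            DegeneratePolygonWarning,
            stacklevel=2,
        )
        return out
    # restrict work to the polygon's bounding box on the grid
    c0 = max(int(np.floor(verts[:, 0].min())), 0)
    c1 = min(int(np.ceil(verts[:, 0].max())), width - 1)
    r0 = max(int(np.floor(verts[:, 1].min())), 0)
    r1 = min(int(np.ceil(verts[:, 1].max())), height - 1)
    if c0 > c1 or r0 > r1:
        return out
    cols = np.arange(c0, c1 + 1)
    rows = np.arange(r0, r1 + 1)
    xs, ys = np.meshgrid(cols.astype(float), rows.astype(float))
    inside = _inside_mask(verts, xs.ravel(), ys.ravel(), policy.fill_rule)
    out[r0 : r1 + 1, c0 : c1 + 1] = inside.reshape(rows.size, cols.size)
    return out


def render_annotation_set(
    s: AnnotationSet,
    taxonomy: ClassTaxonomy,
    policy: RenderPolicy = RenderPolicy(),
) -> LabelMask:
    """Rasterize one participant's polygons to a label mask over the ROI grid.

    Pixels covered by no polygon get the default class; overlapping polygons
    are resolved by draw order (higher wins).
    """
    h, w = s.roi.height, s.roi.width
    labels = np.full((h, w), taxonomy.default_class.label_code, dtype=np.int64)
    for p in sorted(s.polygons, key=lambda p: p.draw_order):
        code = taxonomy.code(p.class_name)
        sel = rasterize_polygon(p, h, w, policy)
        labels[sel] = code
    return LabelMask(labels, taxonomy)


def apply_corrections(
    base: LabelMask,
    corrections: Sequence[PolygonAnnotation],
    taxonomy: ClassTaxonomy | None = None,
    policy: RenderPolicy = RenderPolicy(),
) -> LabelMask:
    """Patch reviewer correction overlays on top of a rendered mask.

    Pixels under a correction polygon take the correction's class (later draw
    order wins among overlapping corrections); every other pixel is returned
    unchanged (conservation).
    """
    taxonomy = taxonomy or base.taxonomy
    for p in corrections:
        if not p.is_correction:
            raise AnnotationValidationError(
                f"polygon (class {p.class_name!r}, draw_order {p.draw_order}) "
                "is not flagged as a correction"
            )
    out = base.labels.copy()
    h, w = base.shape
    for p in sorted(corrections, key=lambda p: p.draw_order):
        sel = rasterize_polygon(p, h, w, policy)
        out[sel] = taxonomy.code(p.class_name)
    return LabelMask(out, base.taxonomy)


@dataclass(frozen=True)
class Region:
    """One connected region of one class traced back out of a mask."""

    class_name: str
    polygon: tuple[tuple[float, float], ...]  # closed boundary, (x, y)
    area_px: int


def trace_component_polygon(binary: np.ndarray) -> tuple[tuple[float, float], ...]:
    """Outer boundary of the largest connected piece of a binary image as a
    closed (x, y) polygon passing midway between set and unset pixels, so that
    re-rasterizing it with the pixel-center rule recovers the pixel set."""
    padded = np.pad(binary.astype(float), 1)
    contours = measure.find_contours(padded, 0.5, fully_connected="high")
    if not contours:
        return ()
    # the outer boundary encloses any hole contours, so it has the largest area
    contour = max(contours, key=lambda c: abs(_shoelace_area(c[:, ::-1])))
    pts = contour[:-1] if np.allclose(contour[0], contour[-1]) else contour
    # (row, col) in padded frame -> (x, y) in image frame
    return tuple((float(c - 1.0), float(r - 1.0)) for r, c in pts)


def extract_regions(
    m: LabelMask,
    include_default: bool = False,
    connectivity: int = 2,
) -> list[Region]:
    """Trace every connected component of every non-default class (8-connected
    by default) as a closed boundary polygon. The default class is excluded
    unless requested, mirroring its definition by absence of annotations; the
    per-class sum of ``area_px`` equals the class's pixel count."""
    regions: list[Region] = []
    default_code = m.taxonomy.default_class.label_code
    for entry in m.taxonomy.entries:
        if entry.label_code == default_code and not include_default:
            continue
        channel = m.labels == entry.label_code
        if not channel.any():
            continue
        lab, n = measure.label(channel, connectivity=connectivity, return_num=True)
        for comp in range(1, n + 1):
            comp_mask = lab == comp
            rr, cc = np.nonzero(comp_mask)
            r0, r1 = rr.min(), rr.max() + 1
            c0, c1 = cc.min(), cc.max() + 1
            poly = trace_component_polygon(comp_mask[r0:r1, c0:c1])
            poly = tuple((x + c0, y + r0) for x, y in poly)
            if len(poly) < 3:
                continue  # cannot happen for a nonempty component, kept defensive
            regions.append(Region(entry.class_name, poly, int(comp_mask.sum())))
    return regions
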