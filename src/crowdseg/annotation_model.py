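"""Domain types and file formats for crowdsourced region annotations.

The unit of work is one participant's set of labeled closed polygons on one
rectangular region of interest (ROI) cropped from a whole-slide image. Polygons
are exchanged as JSON documents (one per participant/ROI pair, mirroring the
element model of web-based slide-annotation platforms); rendered label masks
are exchanged as 8-bit indexed PNG images with a JSON sidecar mapping pixel
values to class names.

Coordinate convention: 0-based, pixel-center, ROI-local; ``x`` is the column
index and ``y`` the row index. Conversion to the slide frame is addition of the
ROI origin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

__all__ = [
    "TaxonomyError",
    "AnnotationValidationError",
    "TaxonomyEntry",
    "ClassTaxonomy",
    "Participant",
    "ROI",
    "PolygonAnnotation",
    "AnnotationSet",
    "LabelMask",
    "default_taxonomy",
    "read_taxonomy",
    "write_taxonomy",
    "read_annotation_document",
    "write_annotation_document",
    "read_label_mask",
    "write_label_mask",
]

TIERS = ("predominant", "non_predominant", "challenging", "meta")
PARTICIPANT_TIERS = ("SP", "JP", "NP", "AL")


class TaxonomyError(ValueError):
    """A class name or label code violates the taxonomy contract."""


class AnnotationValidationError(ValueError):
    """An annotation document or polygon violates a structural invariant."""


@dataclass(frozen=True)
class TaxonomyEntry:
    class_name: str
    tier: str  # one of TIERS
    color: tuple[int, int, int]
    label_code: int
    is_default: bool = False

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise TaxonomyError(f"unknown tier {self.tier!r} for class {self.class_name!r}")
        if not (isinstance(self.label_code, (int, np.integer)) and self.label_code > 0):
            raise TaxonomyError(
                f"label_code for {self.class_name!r} must be a positive integer "
                f"(0 is reserved for outside-ROI/undefined), got {self.label_code!r}"
            )
        if len(self.color) != 3 or any(not (0 <= v <= 255) for v in self.color):
            raise TaxonomyError(f"color for {self.class_name!r} must be an RGB triple in 0..255")


@dataclass(frozen=True)
class ClassTaxonomy:
    """The fixed class scheme of a study: names, experience tiers, render colors
    and stable integer label codes.

    Exactly one class is the *default* class — the tissue assumed wherever a
    participant drew nothing (stroma, in breast-cancer studies where it is the
    most prevalent component). Label code 0 is reserved for pixels outside the
    ROI and is never a class.
    """

    entries: tuple[TaxonomyEntry, ...]

    def __post_init__(self) -> None:
        names = [e.class_name.lower() for e in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise TaxonomyError(f"duplicate class names (case-insensitive): {dupes}")
        codes = [e.label_code for e in self.entries]
        if len(set(codes)) != len(codes):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise TaxonomyError(f"duplicate label codes: {dupes}")
        defaults = [e for e in self.entries if e.is_default]
        if len(defaults) != 1:
            raise TaxonomyError(f"exactly one default class required, found {len(defaults)}")
        if defaults[0].tier != "predominant":
            raise TaxonomyError("the default class must have tier 'predominant'")

    # -- lookups -------------------------------------------------------------
    @property
    def default_class(self) -> TaxonomyEntry:
        return next(e for e in self.entries if e.is_default)

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(e.class_name for e in self.entries)

    def __contains__(self, class_name: str) -> bool:
        return class_name.lower() in {e.class_name.lower() for e in self.entries}

    def entry(self, class_name: str) -> TaxonomyEntry:
        for e in self.entries:
            if e.class_name.lower() == class_name.lower():
                return e
        raise TaxonomyError(f"class {class_name!r} is not in the taxonomy")

    def code(self, class_name: str) -> int:
        return self.entry(class_name).label_code

    def name_of(self, label_code: int) -> str:
        for e in self.entries:
            if e.label_code == label_code:
                return e.class_name
        raise TaxonomyError(f"label code {label_code} is not in the taxonomy")

    def names_by_tier(self, tier: str) -> tuple[str, ...]:
        return tuple(e.class_name for e in self.entries if e.tier == tier)

    def analysis_classes(self) -> tuple[str, ...]:
        """All non-meta classes — the default 'all classes' subset for discordance."""
        return tuple(e.class_name for e in self.entries if e.tier != "meta")


@dataclass(frozen=True)
class Participant:
    participant_id: str
    tier: str  # SP / JP / NP / AL

    def __post_init__(self) -> None:
        if self.tier not in PARTICIPANT_TIERS:
            raise AnnotationValidationError(
                f"participant tier must be one of {PARTICIPANT_TIERS}, got {self.tier!r}"
            )


@dataclass(frozen=True)
class ROI:
    roi_id: str
    slide_id: str
    institute_id: str
    origin: tuple[int, int]  # (x, y) in the slide frame
    width: int
    height: int
    set_membership: str  # "core" or "evaluation"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise AnnotationValidationError("ROI width and height must be positive")
        if self.set_membership not in ("core", "evaluation"):
            raise AnnotationValidationError(
                f"set_membership must be 'core' or 'evaluation', got {self.set_membership!r}"
            )


@dataclass(frozen=True)
class PolygonAnnotation:
    """One labeled closed polygon drawn by one participant.

    Vertices are ROI-local (x, y) pixel-center coordinates; the polygon is
    implicitly closed (last vertex joined to the first). ``draw_order``
    strictly orders all polygons of one participant on one ROI and resolves
    overlaps (later-drawn wins). Corrections are reviewer overlays patched on
    top of original annotations.
    """

    class_name: str
    vertices: tuple[tuple[float, float], ...]
    participant_id: str
    is_correction: bool = False
    draw_order: int = 0

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise AnnotationValidationError(
                f"polygon needs >= 3 vertices, got {len(self.vertices)}"
            )

    def vertex_array(self) -> np.ndarray:
        return np.asarray(self.vertices, dtype=float)


@dataclass(frozen=True)
class AnnotationSet:
    """One participant's polygons on one ROI."""

    roi: ROI
    participant: Participant
    polygons: tuple[PolygonAnnotation, ...]

    def __post_init__(self) -> None:
        for p in self.polygons:
            if p.participant_id != self.participant.participant_id:
                raise AnnotationValidationError(
                    f"polygon participant {p.participant_id!r} does not match "
                    f"set participant {self.participant.participant_id!r}"
                )


@dataclass
class LabelMask:
    """A 2-D integer image of label codes over an ROI grid plus its taxonomy.

    Value 0 marks pixels outside the ROI / undefined; every nonzero value must
    be a label code of the taxonomy. The binary channel views ``channel(c)``
    partition the nonzero pixels (each pixel belongs to exactly one class).
    """

    labels: np.ndarray
    taxonomy: ClassTaxonomy

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise AnnotationValidationError("labels must be a 2-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise AnnotationValidationError("labels must be an integer array")
        present = set(np.unique(self.labels).tolist()) - {0}
        known = {e.label_code for e in self.taxonomy.entries}
        bad = sorted(present - known)
        if bad:
            raise TaxonomyError(f"label codes not in taxonomy: {bad}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def channel(self, class_name: str) -> np.ndarray:
        """Binary indicator image I_c for one class."""
        return self.labels == self.taxonomy.code(class_name)

    def copy(self) -> "LabelMask":
        return LabelMask(self.labels.copy(), self.taxonomy)


# ---------------------------------------------------------------------------
# Default study taxonomy
# ---------------------------------------------------------------------------

def default_taxonomy() -> ClassTaxonomy:
    """The breast-cancer region taxonomy used throughout: four predominant
    classes (stroma is the default), common non-predominant classes and a few
    challenging ones, plus a meta 'exclude' class for artifacts."""
    e = TaxonomyEntry
    return ClassTaxonomy((
        e("tumor", "predominant", (255, 0, 0), 1),
        e("stroma", "predominant", (255, 165, 0), 2, is_default=True),
        e("lymphocytic_infiltrate", "predominant", (0, 0, 255), 3),
        e("necrosis", "predominant", (255, 255, 0), 4),
        e("blood", "non_predominant", (128, 0, 0), 5),
        e("fat", "non_predominant", (255, 255, 255), 6),
        e("blood_vessel", "non_predominant", (128, 0, 128), 7),
        e("glandular_secretions", "non_predominant", (0, 128, 128), 8),
        e("mucoid_material", "non_predominant", (0, 255, 255), 9),
        e("plasma_cells", "challenging", (75, 0, 130), 10),
        e("normal_acinus", "challenging", (0, 128, 0), 11),
        e("exclude", "meta", (50, 50, 50), 12),
    ))


# ---------------------------------------------------------------------------
# Taxonomy files (JSON)
# ---------------------------------------------------------------------------

def write_taxonomy(taxonomy: ClassTaxonomy, path) -> None:
    doc = {
        "classes": [
            {
                "name": e.class_name,
                "tier": e.tier,
                "color": list(e.color),
                "label_code": e.label_code,
                "default": e.is_default,
            }
            for e in taxonomy.entries
        ]
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_taxonomy(path) -> ClassTaxonomy:
    with open(path) as fh:
        doc = json.load(fh)
    entries = tuple(
        TaxonomyEntry(
            class_name=c["name"],
            tier=c["tier"],
            color=tuple(c["color"]),
            label_code=int(c["label_code"]),
            is_default=bool(c.get("default", False)),
        )
        for c in doc["classes"]
    )
    return ClassTaxonomy(entries)


# ---------------------------------------------------------------------------
# Annotation documents (JSON dialect)
# ---------------------------------------------------------------------------
# One document per (participant, ROI); elements are closed polylines with
# "points": [[x, y], ...], "group": class_name, "correction": bool, in draw
# order. The ROI geometry and participant identity are carried in the header
# so a document is self-describing.

def write_annotation_document(s: AnnotationSet, path) -> None:
    doc = {
        "format": "crowdseg-annotation/1",
        "roi": {
            "roi_id": s.roi.roi_id,
            "slide_id": s.roi.slide_id,
            "institute_id": s.roi.institute_id,
            "origin": list(s.roi.origin),
            "width": s.roi.width,
            "height": s.roi.height,
            "set": s.roi.set_membership,
        },
        "participant": {"id": s.participant.participant_id, "tier": s.participant.tier},
        "elements": [
            {
                "type": "polyline",
                "closed": True,
                "group": p.class_name,
                "correction": p.is_correction,
                "points": [[float(x), float(y)] for x, y in p.vertices],
            }
            for p in sorted(s.polygons, key=lambda p: p.draw_order)
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_annotation_document(path, taxonomy: ClassTaxonomy) -> AnnotationSet:
    """Read one participant/ROI annotation document.

    Unknown class names raise :class:`TaxonomyError` (never silently dropped);
    polygons with fewer than 3 vertices raise
    :class:`AnnotationValidationError` naming the element index. Draw order is
    document order.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise AnnotationValidationError(
                f"malformed JSON in {path}: {exc.msg} at line {exc.lineno} column {exc.colno}"
            ) from exc
    roi_d = doc["roi"]
    roi = ROI(
        roi_id=roi_d["roi_id"],
        slide_id=roi_d["slide_id"],
        institute_id=roi_d["institute_id"],
        origin=tuple(roi_d["origin"]),
        width=int(roi_d["width"]),
        height=int(roi_d["height"]),
        set_membership=roi_d["set"],
    )
    part = Participant(doc["participant"]["id"], doc["participant"]["tier"])
    polygons = []
    for i, el in enumerate(doc.get("elements", [])):
        group = el["group"]
        if group not in taxonomy:
            raise TaxonomyError(f"element {i}: class {group!r} is not in the taxonomy")
        pts = el["points"]
        if len(pts) < 3:
            raise AnnotationValidationError(
                f"element {i}: polygon needs >= 3 vertices, got {len(pts)}"
            )
        polygons.append(
            PolygonAnnotation(
                class_name=group,
                vertices=tuple((float(x), float(y)) for x, y in pts),
                participant_id=part.participant_id,
                is_correction=bool(el.get("correction", False)),
                draw_order=i,
            )
        )
    return AnnotationSet(roi=roi, participant=part, polygons=tuple(polygons))


# ---------------------------------------------------------------------------
# Label masks (8-bit indexed PNG + JSON label map sidecar)
# ---------------------------------------------------------------------------

def write_label_mask(m: LabelMask, path, labelmap_path) -> None:
    labels = m.labels
    if labels.max(initial=0) > 255 or labels.min(initial=0) < 0:
        raise AnnotationValidationError("label codes must fit an 8-bit indexed image")
    # 8-bit single-channel grayscale: pixel value == label code, bit-exact
    # (PNG palette images get their indices remapped by encoders; class colors
    # live in the sidecar label map instead)
    Image.fromarray(labels.astype(np.uint8), mode="L").save(path, format="PNG")
    write_taxonomy(m.taxonomy, labelmap_path)


def read_label_mask(path, labelmap_path) -> LabelMask:
    taxonomy = read_taxonomy(labelmap_path)
    img = Image.open(path)
    labels = np.asarray(img, dtype=np.int64)
    if labels.ndim != 2:
        raise AnnotationValidationError(f"{path} is not a single-channel indexed image")
    present = set(np.unique(labels).tolist()) - {0}
    known = {e.label_code for e in taxonomy.entries}
    bad = sorted(present - known)
    if bad:
        raise TaxonomyError(f"{path} contains label codes absent from the label map: {bad}")
    return LabelMask(labels, taxonomy)
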