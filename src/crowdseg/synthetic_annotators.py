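"""Synthetic ground-truth tissue scenes and simulated multi-tier annotator cohorts.

The simulator emulates the structure of a crowdsourced region-annotation study
without the real slides: a ground-truth tissue map with predominant classes
(tumor, stroma as the unannotated default, lymphocytic infiltrate, necrosis)
plus small non-predominant regions; per-participant polygon sets degraded by
the three canonical annotator error types — imprecise region boundaries
(boundary jitter), region misclassification (a confusion matrix) and missing
annotations, especially of non-predominant classes (tier-dependent miss
rates); reviewer correction overlays that patch annotations back toward the
truth; and the two-arm study design in which a small *evaluation* ROI set is
annotated by everyone (for concordance analysis) while a larger *core* ROI set
is partitioned among participants (for model training).

Everything is reproducible from integer seeds via ``numpy.random.SeedSequence``
spawning, so a cohort bundle is a pure function of its seed.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from shapely.geometry import Polygon as ShapelyPolygon
from skimage import measure

from .annotation_model import (
    ROI,
    AnnotationSet,
    ClassTaxonomy,
    LabelMask,
    Participant,
    PolygonAnnotation,
    default_taxonomy,
)
from .mask_render import RenderPolicy, extract_regions, render_annotation_set, trace_component_polygon

__all__ = [
    "SceneSpec",
    "AnnotatorErrorModel",
    "CohortBundle",
    "generate_scene",
    "scene_to_truth_annotations",
    "simulate_annotator",
    "simulate_correction",
    "simulate_cohort",
    "render_rgb_image",
    "default_error_model",
    "default_scene_spec",
]


@dataclass(frozen=True)
class SceneSpec:
    """Recipe for one synthetic ground-truth tissue map.

    ``class_mixture`` maps class names to target area fractions (summing to at
    most 1); the remainder is the taxonomy's default class (stroma).
    ``region_scale`` is the characteristic blob size in pixels of the smoothed
    random fields that carve predominant-class regions. Non-predominant and
    challenging classes in the mixture are placed as
    ``n_nonpredominant_regions`` small elliptical regions each.
    """

    height: int
    width: int
    class_mixture: Mapping[str, float] = field(default_factory=dict)
    region_scale: float = 12.0
    n_nonpredominant_regions: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("scene dimensions must be positive")
        if self.region_scale <= 0:
            raise ValueError("region_scale must be positive")
        for name, frac in self.class_mixture.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction for {name!r} must be in [0, 1], got {frac}")
        if sum(self.class_mixture.values()) > 1.0 + 1e-9:
            raise ValueError("class mixture fractions must sum to <= 1")


@dataclass(frozen=True)
class AnnotatorErrorModel:
    """Tier-dependent error structure of one simulated participant.

    ``boundary_jitter_sigma`` (px) is the amplitude of smoothed Gaussian
    displacement applied along vertex normals after resampling the boundary at
    ``vertex_spacing`` px. ``confusion`` maps a true class name to a
    row-stochastic distribution over drawn class names (absent rows mean
    identity). ``miss_prob`` maps a *taxonomy tier* of the region's class
    (predominant / non_predominant / challenging) to the probability of
    omitting the region entirely.
    """

    tier: str  # SP / JP / NP
    boundary_jitter_sigma: float = 0.0
    vertex_spacing: float = 4.0
    confusion: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    miss_prob: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.boundary_jitter_sigma < 0:
            raise ValueError("boundary_jitter_sigma must be >= 0")
        if self.vertex_spacing <= 0:
            raise ValueError("vertex_spacing must be positive")
        for true_class, row in self.confusion.items():
            total = sum(row.values())
            if abs(total - 1.0) > 1e-9 or any(p < 0 for p in row.values()):
                raise ValueError(f"confusion row for {true_class!r} must be a distribution")
        for tier, p in self.miss_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"miss probability for tier {tier!r} must be in [0, 1]")


# ---------------------------------------------------------------------------
# Scene generation
# ---------------------------------------------------------------------------

def generate_scene(spec: SceneSpec, taxonomy: ClassTaxonomy | None = None) -> LabelMask:
    """Generate a ground-truth label mask from a scene recipe.

    Non-predominant/challenging mixture classes are placed first as random
    ellipses; predominant classes are then carved from the remaining pixels as
    the top quantile of an independent smoothed Gaussian field per class, so
    realized predominant fractions match their targets exactly (up to the
    pixel-count rounding). Remaining pixels become the default class.
    Deterministic given ``spec.seed``.
    """
    taxonomy = taxonomy or default_taxonomy()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    n_px = h * w
    labels = np.zeros((h, w), dtype=np.int64)

    predominant, other = [], []
    for name, frac in spec.class_mixture.items():
        entry = taxonomy.entry(name)
        (predominant if entry.tier == "predominant" else other).append((name, frac))

    # small elliptical regions for non-predominant / challenging classes
    yy, xx = np.mgrid[0:h, 0:w]
    for name, frac in other:
        code = taxonomy.code(name)
        n_regions = max(spec.n_nonpredominant_regions, 1)
        area_each = frac * n_px / n_regions
        for _ in range(n_regions):
            cx, cy = rng.uniform(0, w), rng.uniform(0, h)
            aspect = rng.uniform(0.6, 1.6)
            theta = rng.uniform(0, np.pi)
            a = np.sqrt(area_each / np.pi * aspect)
            b = np.sqrt(area_each / np.pi / aspect)
            u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
            v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
            labels[(u / max(a, 0.5)) ** 2 + (v / max(b, 0.5)) ** 2 <= 1.0] = code

    # carve predominant classes from still-unassigned pixels by field quantile
    for name, frac in predominant:
        code = taxonomy.code(name)
        target = int(round(frac * n_px))
        free = labels == 0
        n_free = int(free.sum())
        take = min(target, n_free)
        if take == 0:
            continue
        fld = gaussian_filter(rng.standard_normal((h, w)), sigma=spec.region_scale)
        fld_free = np.where(free, fld, -np.inf).ravel()
        idx = np.argpartition(fld_free, -take)[-take:]
        labels.ravel()[idx] = code

    labels[labels == 0] = taxonomy.default_class.label_code
    return LabelMask(labels, taxonomy)


def _scene_roi(m: LabelMask, roi_id: str = "scene", set_membership: str = "evaluation",
               slide_id: str = "synthetic", institute_id: str = "synthetic") -> ROI:
    h, w = m.shape
    return ROI(roi_id, slide_id, institute_id, (0, 0), w, h, set_membership)


def scene_to_truth_annotations(
    m: LabelMask,
    roi: ROI | None = None,
    participant: Participant | None = None,
) -> AnnotationSet:
    """Trace a label mask into a ground-truth polygon annotation set.

    Regions of every class (including the default, so that holes re-render
    correctly) are traced and ordered by containment depth — enclosing regions
    drawn first — so rendering the set reproduces the mask up to boundary
    pixels.
    """
    participant = participant or Participant("ground_truth", "SP")
    roi = roi or _scene_roi(m)
    regions = extract_regions(m, include_default=True)
    shapes = []
    for reg in regions:
        poly = ShapelyPolygon(reg.polygon)
        if not poly.is_valid:
            poly = poly.buffer(0)
        shapes.append(poly)
    depths = []
    for i, si in enumerate(shapes):
        pt = si.representative_point()
        depth = sum(1 for j, sj in enumerate(shapes) if j != i and sj.contains(pt))
        depths.append(depth)
    order = sorted(range(len(regions)), key=lambda i: (depths[i], -regions[i].area_px))
    polygons = tuple(
        PolygonAnnotation(
            class_name=regions[i].class_name,
            vertices=regions[i].polygon,
            participant_id=participant.participant_id,
            is_correction=False,
            draw_order=k,
        )
        for k, i in enumerate(order)
    )
    return AnnotationSet(roi=roi, participant=participant, polygons=polygons)


# ---------------------------------------------------------------------------
# Annotator simulation
# ---------------------------------------------------------------------------

def _resample_closed(verts: np.ndarray, spacing: float) -> np.ndarray:
    closed = np.vstack([verts, verts[:1]])
    seg = np.hypot(np.diff(closed[:, 0]), np.diff(closed[:, 1]))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        return verts
    n_new = max(int(round(total / spacing)), 8)
    s = np.arange(n_new) * total / n_new
    return np.column_stack([np.interp(s, cum, closed[:, 0]), np.interp(s, cum, closed[:, 1])])


def _jitter_polygon(verts: np.ndarray, sigma: float, spacing: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Resample the boundary and displace vertices along their normals by
    boundary-smoothed Gaussian noise rescaled to sd ``sigma``. Self-intersecting
    results are repaired (buffer(0), largest part) or redrawn."""
    pts = _resample_closed(verts, spacing)
    n = len(pts)
    tangent = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    norm = np.hypot(tangent[:, 0], tangent[:, 1])
    norm[norm == 0] = 1.0
    normals = np.column_stack([tangent[:, 1] / norm, -tangent[:, 0] / norm])
    for _ in range(4):
        disp = gaussian_filter1d(rng.standard_normal(n), sigma=2.0, mode="wrap")
        sd = disp.std()
        if sd > 0:
            disp = disp * (sigma / sd)
        cand = pts + normals * disp[:, None]
        poly = ShapelyPolygon(cand)
        if poly.is_valid and poly.area > 0:
            return cand
        repaired = poly.buffer(0)
        if repaired.geom_type == "MultiPolygon":
            repaired = max(repaired.geoms, key=lambda g: g.area)
        if repaired.geom_type == "Polygon" and repaired.area > 0:
            ext = np.asarray(repaired.exterior.coords)[:-1]
            if len(ext) >= 3:
                return ext
    return pts  # give up on jitter for this polygon rather than emit bad geometry


def simulate_annotator(
    truth: AnnotationSet,
    model: AnnotatorErrorModel,
    taxonomy: ClassTaxonomy | None = None,
    participant: Participant | None = None,
    seed: int | None = None,
) -> AnnotationSet:
    """Degrade a ground-truth annotation set according to an error model.

    Per truth polygon, in draw order: drop it with the miss probability of its
    class's taxonomy tier; otherwise relabel it by sampling the confusion row
    of its class; then jitter its boundary (sigma 0 leaves the geometry
    untouched). Deterministic given the seed (``model.seed`` unless
    overridden).
    """
    taxonomy = taxonomy or default_taxonomy()
    participant = participant or Participant(f"{model.tier}-sim", model.tier)
    rng = np.random.default_rng(model.seed if seed is None else seed)
    class_names = list(taxonomy.class_names)
    out: list[PolygonAnnotation] = []
    for p in sorted(truth.polygons, key=lambda p: p.draw_order):
        tier_of_class = taxonomy.entry(p.class_name).tier
        if rng.random() < model.miss_prob.get(tier_of_class, 0.0):
            continue
        row = model.confusion.get(p.class_name)
        if row:
            targets = [c for c in class_names if c in row]
            probs = np.array([row[c] for c in targets], dtype=float)
            drawn_class = targets[rng.choice(len(targets), p=probs / probs.sum())]
        else:
            drawn_class = p.class_name
        verts = p.vertex_array()
        if model.boundary_jitter_sigma > 0:
            verts = _jitter_polygon(verts, model.boundary_jitter_sigma,
                                    model.vertex_spacing, rng)
        out.append(
            PolygonAnnotation(
                class_name=drawn_class,
                vertices=tuple((float(x), float(y)) for x, y in verts),
                participant_id=participant.participant_id,
                is_correction=False,
                draw_order=len(out),
            )
        )
    return AnnotationSet(roi=truth.roi, participant=participant, polygons=tuple(out))


def simulate_correction(
    annotated: LabelMask,
    truth: LabelMask,
    reviewer_miss: float = 0.0,
    seed: int = 0,
    participant_id: str = "reviewer",
) -> list[PolygonAnnotation]:
    """Reviewer correction overlays: each connected component of the
    annotated/truth disagreement set becomes a correction polygon labeled with
    the truth class, independently dropped with probability ``reviewer_miss``.
    Applying the result with :func:`~crowdseg.mask_render.apply_corrections`
    moves the mask toward the truth (discordance to truth non-increasing)."""
    if annotated.shape != truth.shape:
        raise ValueError("mask shapes differ")
    if not 0.0 <= reviewer_miss <= 1.0:
        raise ValueError("reviewer_miss must be in [0, 1]")
    rng = np.random.default_rng(seed)
    diff = annotated.labels != truth.labels
    corrections: list[PolygonAnnotation] = []
    for entry in truth.taxonomy.entries:
        wrong = diff & (truth.labels == entry.label_code)
        if not wrong.any():
            continue
        lab, n = measure.label(wrong, connectivity=2, return_num=True)
        for comp in range(1, n + 1):
            comp_mask = lab == comp
            keep = rng.random() >= reviewer_miss
            if not keep:
                continue
            rr, cc = np.nonzero(comp_mask)
            r0, r1 = rr.min(), rr.max() + 1
            c0, c1 = cc.min(), cc.max() + 1
            poly = trace_component_polygon(comp_mask[r0:r1, c0:c1])
            poly = tuple((x + c0, y + r0) for x, y in poly)
            if len(poly) < 3:
                continue
            corrections.append(
                PolygonAnnotation(
                    class_name=entry.class_name,
                    vertices=poly,
                    participant_id=participant_id,
                    is_correction=True,
                    draw_order=len(corrections),
                )
            )
    return corrections


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortBundle:
    """One simulated study: ROIs, ground truth, participant annotations and
    reviewer corrections (corrections on core ROIs only, as in the two-arm
    design where evaluation ROIs receive no feedback)."""

    taxonomy: ClassTaxonomy
    participants: tuple[Participant, ...]
    rois: tuple[ROI, ...]
    truth_masks: dict[str, LabelMask]  # roi_id -> mask
    annotations: dict[tuple[str, str], AnnotationSet]  # (participant_id, roi_id)
    corrections: dict[tuple[str, str], tuple[PolygonAnnotation, ...]]
    core_assignment: dict[str, str]  # core roi_id -> participant_id

    @property
    def eval_rois(self) -> tuple[ROI, ...]:
        return tuple(r for r in self.rois if r.set_membership == "evaluation")

    @property
    def core_rois(self) -> tuple[ROI, ...]:
        return tuple(r for r in self.rois if r.set_membership == "core")

    def eval_masks(self, policy: RenderPolicy = RenderPolicy()) -> dict[Participant, list[LabelMask]]:
        """Rendered evaluation-set masks per participant, ROI order fixed —
        the direct input to pairwise discordance."""
        out: dict[Participant, list[LabelMask]] = {}
        for part in self.participants:
            out[part] = [
                render_annotation_set(
                    self.annotations[(part.participant_id, roi.roi_id)], self.taxonomy, policy
                )
                for roi in self.eval_rois
            ]
        return out


def default_scene_spec(seed: int = 0, height: int = 96, width: int = 96) -> SceneSpec:
    """Scene recipe emulating a tumor-rich breast-cancer ROI: tumor-dominated,
    stroma as the default remainder, moderate lymphocytic infiltrate, some
    necrosis and a few small non-predominant regions."""
    return SceneSpec(
        height=height,
        width=width,
        class_mixture={
            "tumor": 0.45,
            "lymphocytic_infiltrate": 0.12,
            "necrosis": 0.08,
            "blood_vessel": 0.03,
        },
        region_scale=12.0,
        n_nonpredominant_regions=3,
        seed=seed,
    )


def default_error_model(tier: str, seed: int = 0) -> AnnotatorErrorModel:
    """Canonical error models per experience tier.

    Boundary jitter grows from 1 px (senior pathologists) to 4 px
    (non-pathologists); misclassification mixes the predominant classes with
    tier-dependent probability; non-predominant regions are missed half the
    time by non-pathologists and challenging regions almost always.
    """
    predominant = ("tumor", "stroma", "lymphocytic_infiltrate", "necrosis")

    def confusion(eps: float) -> dict[str, dict[str, float]]:
        rows = {}
        for c in predominant:
            rows[c] = {c: 1.0 - eps}
            for other in predominant:
                if other != c:
                    rows[c][other] = eps / (len(predominant) - 1)
        return rows

    params = {
        "SP": dict(boundary_jitter_sigma=1.0, eps=0.02,
                   miss={"predominant": 0.0, "non_predominant": 0.05, "challenging": 0.10}),
        "JP": dict(boundary_jitter_sigma=2.0, eps=0.05,
                   miss={"predominant": 0.0, "non_predominant": 0.20, "challenging": 0.50}),
        "NP": dict(boundary_jitter_sigma=4.0, eps=0.10,
                   miss={"predominant": 0.02, "non_predominant": 0.50, "challenging": 0.90}),
    }
    if tier not in params:
        raise ValueError(f"no default error model for tier {tier!r}")
    p = params[tier]
    return AnnotatorErrorModel(
        tier=tier,
        boundary_jitter_sigma=p["boundary_jitter_sigma"],
        vertex_spacing=4.0,
        confusion=confusion(p["eps"]),
        miss_prob=p["miss"],
        seed=seed,
    )


def simulate_cohort(
    scene: SceneSpec,
    roster: Sequence[AnnotatorErrorModel | tuple[str, AnnotatorErrorModel]],
    n_eval_rois: int,
    n_core_rois: int | None = None,
    seed: int = 0,
    reviewer_miss: float = 0.1,
    taxonomy: ClassTaxonomy | None = None,
) -> CohortBundle:
    """Simulate a full two-arm annotation study.

    Evaluation ROIs are annotated by every participant; core ROIs are
    partitioned round-robin among participants (each core ROI annotated
    exactly once) and receive simulated reviewer corrections. Every scene,
    annotator pass and correction pass gets its own seed spawned from ``seed``,
    so the bundle is reproducible bit-for-bit.
    """
    taxonomy = taxonomy or default_taxonomy()
    models = [r[1] if isinstance(r, tuple) else r for r in roster]
    if n_core_rois is None:
        n_core_rois = len(models)
    participants = tuple(
        Participant(f"{m.tier}-{i:02d}", m.tier) for i, m in enumerate(models)
    )
    ss = np.random.SeedSequence(seed)
    n_rois = n_eval_rois + n_core_rois
    # one derived stream per (roi scene), (participant, roi) pass and correction
    state = ss.generate_state(n_rois + len(models) * n_rois + n_core_rois) % (2**31)
    state = state.tolist()
    next_seed = iter(state).__next__

    rois: list[ROI] = []
    truth_masks: dict[str, LabelMask] = {}
    truth_sets: dict[str, AnnotationSet] = {}
    for i in range(n_rois):
        membership = "evaluation" if i < n_eval_rois else "core"
        rid = f"{membership[:4]}-{i:03d}" if membership == "evaluation" else f"core-{i - n_eval_rois:03d}"
        roi_scene = dataclasses.replace(scene, seed=next_seed())
        mask = generate_scene(roi_scene, taxonomy)
        roi = _scene_roi(mask, roi_id=rid, set_membership=membership,
                         slide_id=f"slide-{i:03d}", institute_id=f"inst-{i % 7:02d}")
        rois.append(roi)
        truth_masks[rid] = mask
        truth_sets[rid] = scene_to_truth_annotations(mask, roi=roi)

    annotations: dict[tuple[str, str], AnnotationSet] = {}
    corrections: dict[tuple[str, str], tuple[PolygonAnnotation, ...]] = {}
    core_assignment: dict[str, str] = {}

    eval_rois = [r for r in rois if r.set_membership == "evaluation"]
    core_rois = [r for r in rois if r.set_membership == "core"]

    annotate_seeds = [[next_seed() for _ in range(n_rois)] for _ in models]
    for pi, (part, model) in enumerate(zip(participants, models)):
        for roi in eval_rois:
            annotations[(part.participant_id, roi.roi_id)] = simulate_annotator(
                truth_sets[roi.roi_id], model, taxonomy, part,
                seed=annotate_seeds[pi][rois.index(roi)],
            )
    for ci, roi in enumerate(core_rois):
        pi = ci % len(models)
        part, model = participants[pi], models[pi]
        core_assignment[roi.roi_id] = part.participant_id
        ann = simulate_annotator(
            truth_sets[roi.roi_id], model, taxonomy, part,
            seed=annotate_seeds[pi][rois.index(roi)],
        )
        annotations[(part.participant_id, roi.roi_id)] = ann
        rendered = render_annotation_set(ann, taxonomy)
        corr = simulate_correction(
            rendered, truth_masks[roi.roi_id], reviewer_miss, seed=next_seed()
        )
        corrections[(part.participant_id, roi.roi_id)] = tuple(corr)

    return CohortBundle(
        taxonomy=taxonomy,
        participants=participants,
        rois=tuple(rois),
        truth_masks=truth_masks,
        annotations=annotations,
        corrections=corrections,
        core_assignment=core_assignment,
    )


# ---------------------------------------------------------------------------
# Synthetic RGB rendering (for patch-classification experiments)
# ---------------------------------------------------------------------------

# H&E-like mean colors per class: tissue classes are nearby shades of pink
# (eosinophilic) and purple (basophilic), not saturated display colors, so the
# emulated classification task is learnable but not trivial. Lymphocytic
# regions sit close to tumor (both nuclear-dense purples), the hardest pair.
HE_STAIN_PALETTE: dict[str, tuple[int, int, int]] = {
    "tumor": (120, 70, 150),
    "stroma": (200, 140, 170),
    "lymphocytic_infiltrate": (90, 60, 130),
    "necrosis": (180, 150, 140),
    "blood": (150, 60, 60),
    "fat": (230, 220, 230),
    "blood_vessel": (170, 100, 120),
    "glandular_secretions": (190, 170, 150),
    "mucoid_material": (180, 170, 200),
    "plasma_cells": (110, 80, 140),
    "normal_acinus": (160, 110, 160),
    "exclude": (120, 120, 120),
}


def render_rgb_image(
    mask: LabelMask,
    seed: int = 0,
    pixel_noise_sd: float = 40.0,
    stain_shift_sd: float = 25.0,
    palette: Mapping[str, tuple[int, int, int]] | None = None,
) -> np.ndarray:
    """Map a label mask to a noisy RGB image.

    Each class takes its mean stain color (H&E-like palette by default,
    falling back to the taxonomy display color for unlisted classes); a
    per-image global color shift emulates slide-level stain variation — the
    dominant nuisance in multi-slide histology — and iid pixel noise emulates
    texture. Returns uint8 HxWx3.
    """
    palette = HE_STAIN_PALETTE if palette is None else palette
    rng = np.random.default_rng(seed)
    h, w = mask.shape
    img = np.zeros((h, w, 3), dtype=float)
    for entry in mask.taxonomy.entries:
        sel = mask.labels == entry.label_code
        if sel.any():
            img[sel] = palette.get(entry.class_name, entry.color)
    img += rng.normal(0, stain_shift_sd, size=3)  # slide-level stain shift
    img += rng.normal(0, pixel_noise_sd, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)
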