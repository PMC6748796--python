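"""Multi-class Dice discordance between label masks.

The discordance between two participants i, j with masks I, J over a set of
Nc classes is

    D(I, J) = 1 - 2 * sum_c |I_c & J_c| / sum_c (|I_c| + |J_c|)

where I_c is the binary channel of class c. D lies in [0, 1]; 0 means the
masks agree on every pixel of the evaluated channels, 1 means the channels
have disjoint support. With a single class this reduces to one minus the
Sorensen-Dice similarity of the binary channels.

Pixels with label 0 (outside the ROI / undefined) in either mask are excluded
from all counts — they are not tissue. When the summed channel sizes are zero
the value is defined as 0 (vacuous agreement) and a
:class:`VacuousDiscordanceWarning` is emitted so total matrices stay total
without hiding the emptiness.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_model import ClassTaxonomy, LabelMask, Participant

__all__ = [
    "VacuousDiscordanceWarning",
    "DiscordanceMatrix",
    "DisagreementMap",
    "dice_discordance",
    "dice_counts",
    "per_class_discordance",
    "correction_discordance",
    "pairwise_discordance",
    "disagreement_map",
]


class VacuousDiscordanceWarning(UserWarning):
    """Both masks are empty on the evaluated channels; discordance is vacuously 0."""


def _check_pair(I: LabelMask, J: LabelMask) -> None:
    if I.shape != J.shape:
        raise ValueError(f"mask shapes differ: {I.shape} vs {J.shape}")


def dice_counts(
    I: LabelMask, J: LabelMask, class_subset: Sequence[str]
) -> tuple[int, int]:
    """Summed intersection and channel-size counts of the Dice statistic.

    Returns ``(sum_c |I_c & J_c|, sum_c (|I_c| + |J_c|))`` over the class
    subset, restricted to pixels inside the ROI in both masks. Exposed so
    callers can pool counts across ROIs before taking the ratio.
    """
    _check_pair(I, J)
    if not class_subset:
        raise ValueError("class_subset must be non-empty")
    valid = (I.labels != 0) & (J.labels != 0)
    inter = 0
    sizes = 0
    for name in class_subset:
        code = I.taxonomy.code(name)
        ic = (I.labels == code) & valid
        jc = (J.labels == code) & valid
        inter += int((ic & jc).sum())
        sizes += int(ic.sum()) + int(jc.sum())
    return inter, sizes


def _ratio(inter: int, sizes: int) -> float:
    if sizes == 0:
        warnings.warn(
            "all evaluated channels are empty in both masks; "
            "discordance is vacuously 0",
            VacuousDiscordanceWarning,
            stacklevel=3,
        )
        return 0.0
    return 1.0 - 2.0 * inter / sizes


def dice_discordance(I: LabelMask, J: LabelMask, class_subset: Sequence[str]) -> float:
    """Multi-class Dice discordance of two masks over a class subset."""
    inter, sizes = dice_counts(I, J, class_subset)
    return _ratio(inter, sizes)


def per_class_discordance(I: LabelMask, J: LabelMask, class_name: str) -> float:
    """Binary (single-class) Dice discordance.

    0 when the class is absent from both masks (vacuous, warned); 1 when it is
    present in exactly one of them.
    """
    return dice_discordance(I, J, [class_name])


def correction_discordance(
    pre: LabelMask, post: LabelMask, class_subset: Sequence[str]
) -> float:
    """Discordance between a participant's mask before and after reviewer
    corrections were patched on — the per-ROI measure of how much review
    changed the annotation."""
    return dice_discordance(pre, post, class_subset)


@dataclass
class DiscordanceMatrix:
    """Symmetric participant-by-participant discordance matrix."""

    participants: tuple[Participant, ...]
    values: np.ndarray
    class_subset: tuple[str, ...]
    aggregation: str  # "pooled" or "per_roi_median"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.participants)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} participants")
        if not np.allclose(v, v.T):
            raise ValueError("discordance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("discordance matrix must have a zero diagonal")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("discordance values must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)

    @property
    def n(self) -> int:
        return len(self.participants)

    def n_unique_pairs(self) -> int:
        return self.n * (self.n - 1) // 2

    def unique_pairs(self):
        """Yield (participant_a, participant_b, value) over the strict upper triangle."""
        for a, b in itertools.combinations(range(self.n), 2):
            yield self.participants[a], self.participants[b], float(self.values[a, b])

    def to_dataframe(self) -> pd.DataFrame:
        ids = [p.participant_id for p in self.participants]
        return pd.DataFrame(self.values, index=ids, columns=ids)


def pairwise_discordance(
    masks: Mapping[Participant, Sequence[LabelMask]],
    class_subset: Sequence[str],
    aggregation: str = "pooled",
) -> DiscordanceMatrix:
    """Discordance matrix over all unique participant pairs on shared ROIs.

    ``masks`` maps each participant to their rendered masks for the shared
    (evaluation) ROIs, in a common ROI order. Aggregation across ROIs is
    either ``pooled`` — numerator and denominator counts are summed over ROIs
    before the ratio, i.e. the statistic applied to the stacked channels — or
    ``per_roi_median`` — the median of per-ROI discordance values.
    """
    if aggregation not in ("pooled", "per_roi_median"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    participants = sorted(masks.keys(), key=lambda p: p.participant_id)
    n_rois = {p: len(masks[p]) for p in participants}
    if len(set(n_rois.values())) > 1:
        raise ValueError(f"participants have differing ROI counts: {n_rois}")
    n_shared = next(iter(n_rois.values()))
    for p in participants:
        for r, m in enumerate(masks[p]):
            if m is None:
                raise ValueError(f"missing mask for participant {p.participant_id!r}, ROI index {r}")
    n = len(participants)
    values = np.zeros((n, n), dtype=float)
    for a, b in itertools.combinations(range(n), 2):
        ma, mb = masks[participants[a]], masks[participants[b]]
        if aggregation == "pooled":
            inter = sizes = 0
            for I, J in zip(ma, mb):
                i, s = dice_counts(I, J, class_subset)
                inter += i
                sizes += s
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", VacuousDiscordanceWarning)
                d = _ratio(inter, sizes)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", VacuousDiscordanceWarning)
                per_roi = [dice_discordance(I, J, class_subset) for I, J in zip(ma, mb)]
            d = float(np.median(per_roi)) if per_roi else 0.0
        values[a, b] = values[b, a] = d
    return DiscordanceMatrix(
        participants=tuple(participants),
        values=values,
        class_subset=tuple(class_subset),
        aggregation=aggregation,
    )


@dataclass
class DisagreementMap:
    """Pixel-wise fraction of evaluated cross-group pairs whose labels differ."""

    values: np.ndarray
    pair_population: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.min() < 0 or v.max() > 1:
            raise ValueError("disagreement fractions must lie in [0, 1]")
        self.values = v


def disagreement_map(
    group_a: Sequence[LabelMask],
    group_b: Sequence[LabelMask],
    pair_population: str = "cross pairs",
) -> DisagreementMap:
    """Mean pixel-wise label disagreement over all (a, b) cross pairs of two
    groups of masks of one ROI — e.g. the average SP-NP disagreement image
    that localizes where tiers differ (boundaries vs diffuse regions)."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    shape = group_a[0].shape
    for m in (*group_a, *group_b):
        if m.shape != shape:
            raise ValueError("all masks must share one shape")
    acc = np.zeros(shape, dtype=float)
    n_pairs = 0
    for I in group_a:
        for J in group_b:
            acc += (I.labels != J.labels).astype(float)
            n_pairs += 1
    return DisagreementMap(acc / n_pairs, pair_population)
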