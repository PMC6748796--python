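"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — scalar loops, exhaustive enumeration,
direct pairwise counting — and shares no code with the package.
"""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np

_EPS2 = 1e-9  # squared-distance tolerance for "on the boundary"


def point_in_polygon(x: float, y: float, verts) -> bool:
    """Scalar ray-casting point-in-polygon test, boundary-inclusive
    (points within sqrt(1e-9) of an edge count as inside)."""
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        ex, ey = x2 - x1, y2 - y1
        seg2 = ex * ex + ey * ey
        if seg2 == 0:
            d2 = (x - x1) ** 2 + (y - y1) ** 2
        else:
            t = ((x - x1) * ex + (y - y1) * ey) / seg2
            t = min(max(t, 0.0), 1.0)
            d2 = (x - (x1 + t * ex)) ** 2 + (y - (y1 + t * ey)) ** 2
        if d2 <= _EPS2:
            return True
    inside = False
    j = n - 1
    for i in range(n):
        xi, yi = verts[i]
        xj, yj = verts[j]
        if (yi > y) != (yj > y) and x < (xj - xi) * (y - yi) / (yj - yi) + xi:
            inside = not inside
        j = i
    return inside


def rasterize_oracle(verts, height: int, width: int) -> np.ndarray:
    out = np.zeros((height, width), dtype=bool)
    for r in range(height):
        for c in range(width):
            out[r, c] = point_in_polygon(float(c), float(r), verts)
    return out


def dice_discordance_oracle(labels_i: np.ndarray, labels_j: np.ndarray, codes) -> float:
    """Multi-class Dice discordance by per-pixel set counting."""
    counts = Counter(zip(labels_i.ravel().tolist(), labels_j.ravel().tolist()))
    inter = 0
    sizes = 0
    for (a, b), n in counts.items():
        if a == 0 or b == 0:
            continue
        for c in codes:
            if a == c and b == c:
                inter += n
            if a == c:
                sizes += n
            if b == c:
                sizes += n
    if sizes == 0:
        return 0.0
    return 1.0 - 2.0 * inter / sizes


def _u_statistic(xs, ys) -> float:
    """Mann-Whitney U of xs by direct pairwise comparison."""
    u = 0.0
    for a in xs:
        for b in ys:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u


def mann_whitney_enumeration(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p-value by enumerating every assignment of
    the pooled values to the two groups; U computed by pairwise comparison."""
    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = _u_statistic(x, y)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(_u_statistic(xs, ys))
    us = np.asarray(us)
    tol = 1e-9
    p_lo = float((us <= u_obs + tol).mean())
    p_hi = float((us >= u_obs - tol).mean())
    return u_obs, min(1.0, 2.0 * min(p_lo, p_hi))


def _midranks(values) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def wilcoxon_enumeration(x, y) -> tuple[float, float]:
    """Exact two-sided Wilcoxon signed-rank p-value: zero differences dropped,
    midranks of |d| computed by hand, all 2^n sign patterns enumerated."""
    d = [a - b for a, b in zip(x, y) if a != b]
    if not d:
        return 0.0, 1.0
    r = _midranks([abs(v) for v in d])
    w_obs = sum(ri for ri, di in zip(r, d) if di > 0)
    ws = []
    for signs in itertools.product((0, 1), repeat=len(d)):
        ws.append(sum(ri for ri, s in zip(r, signs) if s))
    ws = np.asarray(ws)
    tol = 1e-9
    p_lo = float((ws <= w_obs + tol).mean())
    p_hi = float((ws >= w_obs - tol).mean())
    return w_obs, min(1.0, 2.0 * min(p_lo, p_hi))


def auc_pairwise_oracle(scores: np.ndarray, positives: np.ndarray) -> float:
    """One-vs-rest ROC AUC as the probability a positive outranks a negative,
    ties counting half, by O(n_pos * n_neg) comparison."""
    pos = scores[positives]
    neg = scores[~positives]
    if pos.size == 0 or neg.size == 0:
        return float("nan")
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (pos.size * neg.size)
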