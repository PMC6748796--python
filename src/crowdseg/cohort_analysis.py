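"""Experience-tier analysis of a discordance matrix.

Groups the unique participant pairs by tier pair (SP-SP, SP-NP, NP-NP, ...),
compares discordance distributions with rank tests, and visual-analysis
orderings: agglomerative leaf order for a biclustered heatmap and a classical
(Torgerson) multidimensional-scaling embedding in which proximity means
concordance.

Rank tests use exact enumeration of the permutation distribution at small
sample sizes (which handles ties by construction) and the tie-corrected normal
approximation with continuity correction otherwise. All p-values are
two-sided: twice the smaller tail of the null distribution, capped at 1.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy

from .annotation_model import PARTICIPANT_TIERS
from .discordance import DiscordanceMatrix

__all__ = [
    "TierComparison",
    "Embedding2D",
    "RankTestResult",
    "DegenerateTestWarning",
    "tier_pair_distributions",
    "rank_test_unpaired",
    "rank_test_paired",
    "bicluster_order",
    "mds_embed",
]

EXACT_LIMIT_UNPAIRED = 12  # enumerate C(n, n1) rank assignments up to this pooled n
EXACT_LIMIT_PAIRED = 15  # enumerate 2**n sign patterns up to this n


class DegenerateTestWarning(UserWarning):
    """The test statistic is degenerate (e.g. all paired differences are zero)."""


class RankTestResult(NamedTuple):
    statistic: float
    pvalue: float


def _two_sided(p_lo: float, p_hi: float) -> float:
    return min(1.0, 2.0 * min(p_lo, p_hi))


# ---------------------------------------------------------------------------
# Tier pair distributions
# ---------------------------------------------------------------------------

_TIER_RANK = {t: i for i, t in enumerate(PARTICIPANT_TIERS)}


def pair_class_label(tier_a: str, tier_b: str) -> str:
    """Canonical, order-insensitive label of a tier pair (e.g. 'SP-NP')."""
    a, b = sorted((tier_a, tier_b), key=lambda t: _TIER_RANK[t])
    return f"{a}-{b}"


@dataclass(frozen=True)
class TierComparison:
    """The discordance values of all unique pairs in one tier-pair class."""

    pair_class: str
    values: tuple[float, ...]
    median: float
    sd: float

    @classmethod
    def from_values(cls, pair_class: str, values: Sequence[float]) -> "TierComparison":
        arr = np.asarray(values, dtype=float)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return cls(pair_class, tuple(float(v) for v in arr), float(np.median(arr)), sd)


def tier_pair_distributions(m: DiscordanceMatrix) -> list[TierComparison]:
    """Partition the C(n, 2) unique off-diagonal entries by tier pair.

    Every unique pair lands in exactly one comparison group, so the group
    sizes sum to the number of unique pairs.
    """
    groups: dict[str, list[float]] = {}
    for pa, pb, value in m.unique_pairs():
        groups.setdefault(pair_class_label(pa.tier, pb.tier), []).append(value)
    order = sorted(groups)
    return [TierComparison.from_values(k, groups[k]) for k in order]


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

def _mann_whitney_u(x_ranksum: float, n1: int) -> float:
    return x_ranksum - n1 * (n1 + 1) / 2.0


def rank_test_unpaired(x: Sequence[float], y: Sequence[float]) -> RankTestResult:
    """Mann-Whitney U test (two-sided).

    Exact permutation enumeration for pooled n <= 12 (correct under ties);
    otherwise the tie-corrected normal approximation with continuity
    correction. The statistic is U of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = _mann_whitney_u(float(ranks[:n1].sum()), n1)
    if n1 + n2 <= EXACT_LIMIT_UNPAIRED:
        us = np.array([
            _mann_whitney_u(float(ranks[list(idx)].sum()), n1)
            for idx in itertools.combinations(range(n1 + n2), n1)
        ])
        tol = 1e-9
        p = _two_sided(float((us <= u_obs + tol).mean()), float((us >= u_obs - tol).mean()))
        return RankTestResult(u_obs, p)
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts) / (n * (n - 1))).sum())
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        warnings.warn("all pooled values tie; test is degenerate", DegenerateTestWarning)
        return RankTestResult(u_obs, 1.0)
    # continuity correction toward the mean
    z = (u_obs - mu - 0.5 * np.sign(u_obs - mu)) / np.sqrt(sigma2)
    return RankTestResult(u_obs, float(2.0 * stats.norm.sf(abs(z))))


def rank_test_paired(x: Sequence[float], y: Sequence[float]) -> RankTestResult:
    """Wilcoxon signed-rank test (two-sided), zero differences dropped.

    Exact enumeration of the 2**n sign patterns for n <= 15 (correct under
    tied |differences|); otherwise the tie-corrected normal approximation with
    continuity correction. The statistic is W+, the positive-rank sum. If all
    differences are zero the test is degenerate and reported as p = 1 with a
    :class:`DegenerateTestWarning`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; test is degenerate",
                      DegenerateTestWarning)
        return RankTestResult(0.0, 1.0)
    r = stats.rankdata(np.abs(d))
    w_pos = float(r[d > 0].sum())
    if n <= EXACT_LIMIT_PAIRED:
        # distribution of W+ over all sign assignments of the observed ranks
        ws = np.zeros(1)
        for ri in r:
            ws = np.concatenate([ws, ws + ri])
        tol = 1e-9
        p = _two_sided(float((ws <= w_pos + tol).mean()), float((ws >= w_pos - tol).mean()))
        return RankTestResult(w_pos, p)
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - float((counts**3 - counts).sum()) / 48.0
    if sigma2 <= 0:
        warnings.warn("all |differences| tie to a degenerate variance", DegenerateTestWarning)
        return RankTestResult(w_pos, 1.0)
    z = (w_pos - mu - 0.5 * np.sign(w_pos - mu)) / np.sqrt(sigma2)
    return RankTestResult(w_pos, float(2.0 * stats.norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# Biclustering order
# ---------------------------------------------------------------------------

def bicluster_order(m: DiscordanceMatrix) -> list[int]:
    """Leaf order of average-linkage hierarchical clustering of the matrix
    rows (Euclidean distance on discordance profiles), as indices into
    ``m.participants``. Deterministic: ties broken by participant_id via a
    lexicographic pre-sort."""
    if m.n < 2:
        raise ValueError("need at least 2 participants to order")
    lex = sorted(range(m.n), key=lambda i: m.participants[i].participant_id)
    rows = m.values[np.ix_(lex, lex)]
    with warnings.catch_warnings():
        # rows of a discordance matrix are observation vectors here, on purpose
        warnings.simplefilter("ignore", hierarchy.ClusterWarning)
        link = hierarchy.linkage(rows, method="average", metric="euclidean")
    leaves = hierarchy.leaves_list(link)
    return [lex[i] for i in leaves]


# ---------------------------------------------------------------------------
# Classical MDS
# ---------------------------------------------------------------------------

@dataclass
class Embedding2D:
    """2-D embedding of participants; only relative configuration (up to
    rotation/translation/reflection) is interpretable."""

    coordinates: np.ndarray  # (n, 2)
    stress: float
    eigenvalues: np.ndarray  # full spectrum of the doubly-centered matrix, descending
    negative_eigenvalue_mass: float


def mds_embed(m: DiscordanceMatrix | np.ndarray, method: str = "classical",
              seed: int | None = None) -> Embedding2D:
    """Embed a discordance matrix in the plane.

    Classical (Torgerson) scaling: double-center the squared dissimilarities,
    take the top-2 eigenpairs, coordinates = eigenvector * sqrt(eigenvalue).
    Negative eigenvalues (non-Euclidean part) are truncated and their total
    magnitude reported. Deterministic; ``method="smacof"`` selects seeded
    iterative majorization instead (scikit-learn) for users who prefer
    metric-stress optimization. Kruskal stress-1 is reported for both.
    """
    D = m.values if isinstance(m, DiscordanceMatrix) else np.asarray(m, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    if method == "smacof":
        from sklearn.manifold import MDS

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            model = MDS(n_components=2, dissimilarity="precomputed",
                        random_state=seed, normalized_stress=False)
            X = model.fit_transform(D)
        eigenvalues = np.full(n, np.nan)
        neg_mass = float("nan")
    elif method == "classical":
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (D**2) @ J
        evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        eigenvalues = evals
        neg_mass = float(np.abs(evals[evals < 0]).sum())
        X = np.zeros((n, 2))
        for k in range(min(2, n)):
            lam = max(evals[k], 0.0)
            v = evecs[:, k]
            if v[np.argmax(np.abs(v))] < 0:  # deterministic sign
                v = -v
            X[:, k] = v * np.sqrt(lam)
    else:
        raise ValueError(f"unknown method {method!r}")
    diff = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    iu = np.triu_indices(n, 1)
    denom = float((D[iu] ** 2).sum())
    stress = float(np.sqrt(((diff[iu] - D[iu]) ** 2).sum() / denom)) if denom > 0 else 0.0
    return Embedding2D(X, stress, eigenvalues, neg_mass)
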