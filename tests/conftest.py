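import numpy as np
import pytest

from crowdseg import ClassTaxonomy, LabelMask, TaxonomyEntry, default_taxonomy


@pytest.fixture(scope="session")
def taxonomy() -> ClassTaxonomy:
    return default_taxonomy()


@pytest.fixture(scope="session")
def small_taxonomy() -> ClassTaxonomy:
    """Four predominant classes only; stroma is the default."""
    e = TaxonomyEntry
    return ClassTaxonomy((
        e("tumor", "predominant", (255, 0, 0), 1),
        e("stroma", "predominant", (255, 165, 0), 2, is_default=True),
        e("lymphocytic_infiltrate", "predominant", (0, 0, 255), 3),
        e("necrosis", "predominant", (255, 255, 0), 4),
    ))


def random_mask(rng: np.random.Generator, taxonomy: ClassTaxonomy,
                shape=(16, 16), n_classes: int | None = None) -> LabelMask:
    """Random blocky label mask over the first n_classes codes of a taxonomy."""
    codes = [e.label_code for e in taxonomy.entries]
    if n_classes is not None:
        codes = codes[:n_classes]
    # coarse random field upsampled -> spatially correlated labels
    coarse = rng.choice(codes, size=(max(shape[0] // 4, 1), max(shape[1] // 4, 1)))
    labels = np.kron(coarse, np.ones((4, 4), dtype=np.int64))[: shape[0], : shape[1]]
    return LabelMask(labels.astype(np.int64), taxonomy)


def random_simple_polygon(rng: np.random.Generator, center, radius_range,
                          n_vertices: int) -> tuple[tuple[float, float], ...]:
    """Star-convex polygon around a center: simple by construction."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = rng.uniform(*radius_range, n_vertices)
    cx, cy = center
    return tuple((cx + r * np.cos(a), cy + r * np.sin(a)) for r, a in zip(radii, angles))
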