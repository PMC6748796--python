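# Methods

## Problem setting

Semantic segmentation models for histology need exhaustive pixel-level ground
truth, which is typically produced by several annotators of mixed experience
drawing labeled polygons over regions of interest (ROIs) cropped from
whole-slide images. `crowdseg` implements the analysis side of such a study:
turning polygon sets into label masks, quantifying how much annotators
disagree and where, relating disagreement to experience tier and tissue class,
measuring what expert review changes, and evaluating pixel-level predictions.
A simulator generates complete synthetic cohorts so that every stage is
testable without slide data.

## Rendering polygons to masks

An annotation set is one participant's closed polygons on one ROI, each with a
class label and a draw order. Rendering uses a pixel-center inclusion test: the
pixel at row *r*, column *c* belongs to a polygon when the point (x=c, y=r)
lies in its interior under the fill rule (nonzero winding by default; even-odd
available) or exactly on its boundary. Boundary inclusion makes integer-vertex
rectangles behave as users expect (a rectangle with corners (1,1)–(4,3) covers
the 4×3 block of centers). Overlaps are resolved by draw order — later wins —
because draw order is the only precedence signal annotation platforms record.
Pixels no polygon covers receive the *default class* (stroma in breast-cancer
taxonomies, where it is the most prevalent tissue and is deliberately left
unannotated); label code 0 is reserved for pixels outside the ROI and is never
a class. Reviewer *correction overlays* are rasterized on top of the finished
mask and change nothing outside their own footprint (a conservation property
the tests assert pixel-by-pixel).

Region extraction is the inverse: connected components (8-connected) of each
non-default class are traced with sub-pixel marching-squares contours that run
midway between set and unset pixels, so re-rasterizing a traced polygon with
the pixel-center rule recovers the component exactly in almost all cases.
Degenerate zero-area polygons rasterize to an empty mask with a warning rather
than an error, since real exports contain slivers.

## Discordance statistic

Disagreement between masks I and J over classes c = 1…N_c is measured as

    Δ(I, J) = 1 − 2 Σ_c |I_c ∩ J_c| / Σ_c (|I_c| + |J_c|)

with I_c the binary channel of class c — one minus a pooled multi-class
Sørensen–Dice similarity. Δ is 0 iff the masks agree on every evaluated pixel,
1 when the channels have disjoint support, and with a single class it reduces
to one minus the familiar binary Dice. Label-0 pixels in either mask are
excluded from all counts (they are not tissue). When every evaluated channel
is empty in both masks the value is defined as 0 and flagged with a warning
("vacuous agreement") so that pairwise matrices stay total without hiding the
emptiness; a class present in exactly one mask gives Δ = 1.

Across several shared ROIs two aggregations are provided: **pooled** (default)
sums numerator and denominator counts over ROIs before taking the ratio —
algebraically identical to evaluating the statistic on the ROI-concatenated
masks, which the tests assert — and **per_roi_median** takes the median of
per-ROI values. Pooled is the default because it is the literal reading of the
statistic applied to stacked channels; the median variant is more robust to a
single aberrant ROI.

Pixel-wise *disagreement maps* average the indicator [label_a ≠ label_b] over
all cross pairs of two participant groups, localizing whether discordance is
boundary-confined (typical for tumor) or diffuse (typical for infiltrates).

## Cohort analysis

Unique participant pairs are partitioned by unordered experience-tier pair
(SP–SP, SP–NP, NP–NP, …; SP = senior pathologist, JP = junior resident, NP =
non-pathologist, AL = algorithm), and each group is summarized by median and
SD. Distribution shifts are tested with a Mann–Whitney U test (unpaired) and a
Wilcoxon signed-rank test (paired, zero differences dropped). Both tests use
exact enumeration of the permutation null at small n (all C(n, n1) group
assignments, or all 2^n sign patterns) — which remains correct under ties —
and the tie-corrected normal approximation with continuity correction
otherwise (thresholds: pooled n ≤ 12 unpaired, n ≤ 15 paired). P-values are
two-sided: twice the smaller tail, capped at 1. These enumeration conventions
are pinned by oracle tests rather than by reference to any library.

The biclustered-heatmap ordering is the leaf order of average-linkage
agglomerative clustering of matrix rows (Euclidean distance on discordance
profiles), with ties broken deterministically by a lexicographic pre-sort on
participant id. The 2-D embedding uses classical (Torgerson) multidimensional
scaling — double-center the squared dissimilarities, take the top-2
eigenpairs, scale eigenvectors by the root eigenvalues — chosen over SMACOF
because it is deterministic and has no initialization; negative eigenvalue
mass (the non-Euclidean part of the discordance matrix) is truncated and
reported, and Kruskal stress-1 accompanies every embedding. A seeded SMACOF
flavor is available for users who prefer metric-stress optimization.

## Synthetic cohorts

The simulator is first-class, tested code; its defaults define the study
conditions used throughout the tests.

**Scenes.** A ground-truth map is generated per ROI: non-predominant classes
are placed first as a few random ellipses; each predominant class then claims
the top quantile of an independent Gaussian random field smoothed at
`region_scale` (12 px), carved from still-unassigned pixels, so realized
predominant fractions match their targets exactly up to rounding; the
remainder is stroma. The default 96×96 recipe is a tumor-rich ROI — tumor
0.45, lymphocytic infiltrate 0.12, necrosis 0.08, blood vessels 0.03, stroma
the rest — reflecting the deliberate selection of tumor-dense regions in
annotation studies. The 96×96 size keeps region counts per ROI (order ten)
and boundary-to-area ratios in a realistic regime at desk scale.

**Annotators.** Each simulated participant applies the three canonical error
types to the truth polygons: (i) *boundary imprecision* — the boundary is
resampled at `vertex_spacing` (4 px) and displaced along vertex normals by
boundary-smoothed Gaussian noise rescaled to sd `boundary_jitter_sigma`;
self-intersecting results are repaired or redrawn; sigma 0 leaves geometry
untouched so the noise-free limit renders identically to truth; (ii)
*misclassification* — the drawn class is sampled from a row-stochastic
confusion matrix mixing the predominant classes; (iii) *missing annotations* —
each region is dropped with a probability keyed to its class's taxonomy tier.
Default tier models: SP jitter 1 px / confusion 0.02 / non-predominant miss
0.05; JP 2 px / 0.05 / 0.20; NP 4 px / 0.10 / 0.50 (challenging classes 0.10 /
0.50 / 0.90). These magnitudes encode the qualitative findings that experience
mainly buys boundary precision and recognition of rare classes.

**Corrections.** A simulated reviewer turns each connected component of the
annotated↔truth disagreement set into a correction polygon labeled with the
truth class, dropping each independently with `reviewer_miss` (default 0.1).
Because corrections only ever move pixels to their true class, applying them
never increases discordance to truth, and a miss-free review restores the
truth exactly — both asserted in tests.

**Study design.** A cohort bundle mirrors the two-arm design: every
participant annotates all *evaluation* ROIs (concordance analysis, no
feedback), while *core* ROIs are partitioned round-robin (training data,
reviewed and corrected). All randomness is spawned from one `SeedSequence`, so
bundles are bit-for-bit reproducible from a single integer seed.

**What the simulator does not model.** Correlated errors from shared training,
intra-participant (test–retest) variability, fatigue and time-on-task effects,
and anything at nucleus scale or below. Passing tests therefore demonstrate
that the *pipeline* recovers planted structure, not that real cohorts have
that structure.

## Segmentation evaluation

Predictions are per-class score planes; hard labels are the argmax. Metrics
follow the five-class scheme (tumor, stroma, inflammatory, necrosis, other —
any class outside the first four collapses to "other"; the mapping is
overridable): one-vs-rest pixel ROC AUC computed from midranks (ties handled
exactly, matched against an O(n²) pairwise oracle), Dice and binary accuracy
per class, micro AUC pooling all pixel-class score/indicator pairs, macro AUC
as the unweighted class mean, and a confusion matrix in percent of total
evaluated pixels (sums to 100). A class absent from the evaluated truth yields
AUC = NaN, never 0. Per-class Dice is exactly 1 − Δ of the argmax mask, a
cross-module identity the tests assert.

## Learning-curve harness

The harness measures how patch-classification macro AUC grows with the number
of training slides. Core slides are split once (seeded) into a training pool
and a held-out test set — strict slide-level separation, as generalization to
unseen slides/institutions is the quantity of interest. For each (count,
replicate), that many pool slides are sampled without replacement, 16-px
patches with ≥0.85 modal-class purity are extracted from seeded synthetic RGB
renderings, a classifier is fitted and test-set macro AUC recorded.

The RGB emulation maps classes to H&E-like mean colors — nearby pinks and
purples, with tumor and lymphocytic infiltrate deliberately the closest pair —
plus a per-slide global color shift (sd 25) emulating stain variation, the
dominant nuisance across slides, and iid pixel noise (sd 40) emulating
texture. Slide-level stain shifts are what make few-slide training genuinely
hard: a model trained on two slides has seen two stain realizations. The
bundled baseline classifier is deliberately shallow (pooled color/gradient
features into an L2 multinomial logistic model): the harness validates the
experimental design — sampling, slide separation, AUC aggregation — not a
segmentation architecture, which is out of scope.

Default experiment sizes (12-participant cohorts, 10 evaluation ROIs, 30-slide
learning-curve bundles, 20 replicates) are chosen so the full pipeline and its
tests run comfortably on a laptop-class single core.

## Numerical conventions

- Rasterization boundary tolerance: points within 1e-9 squared distance of an
  edge count as covered; degenerate polygons (|shoelace area| < 1e-12) warn
  and rasterize empty.
- Discordance values are clipped to [0, 1] against floating-point drift;
  vacuous denominators return 0 + warning rather than NaN.
- MDS eigenvector signs are fixed (largest-magnitude component positive) for
  reproducibility; eigenvalues below 0 are truncated, their mass reported.
- Mask files are 8-bit grayscale PNG with pixel value = label code plus a JSON
  label map sidecar; palette PNGs were rejected because encoders remap palette
  indices.
- All stochastic components accept integer seeds; derived seeds stay below
  2^31.

## Known limitations

- Discordance medians can be reported over pairs, over ROIs, or over pair×ROI
  values; where a single number is shown it is the median over pairs of pooled
  values, and the aggregation is always labeled.
- Region counts are defined post-render: a participant's overlapping same-class
  polygons merge into one region.
- The rasterizer is exact for the pixel-center rule but not anti-aliased;
  sub-pixel area weighting is out of scope.
- The simulator's annotators err independently; real cohorts share training
  and instructions, so real inter-annotator correlation is underestimated.
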