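# crowdseg

Analysis pipeline for **crowdsourced region annotation of histology images**:
from per-participant polygon annotations to label masks, inter-annotator
discordance, experience-tier statistics and pixel-level segmentation metrics —
with a full synthetic multi-annotator simulator so everything runs and is
testable without any slide data.

It is written for groups running multi-annotator studies that produce semantic
segmentation ground truth (e.g. tissue regions in breast-cancer H&E slides
annotated by pathologists, residents and trained non-pathologists), and for
anyone who needs a well-tested multi-class Dice discordance implementation.

## The statistic at the core

Disagreement between two participants' masks I and J over classes
c = 1…N<sub>c</sub> is the pooled multi-class Dice discordance

$$\Delta(I,J) \;=\; 1 - \frac{2\sum_c |I_c \cap J_c|}{\sum_c \left(|I_c| + |J_c|\right)}$$

where I<sub>c</sub> is the binary channel of class c. Δ = 0 means pixel-perfect
agreement on the evaluated channels, Δ = 1 disjoint support; one class gives
1 − (binary Sørensen–Dice). Masks render from polygons with a pixel-center
rule, later-drawn polygons winning overlaps; unannotated pixels take the
*default class* (stroma), and expert correction overlays patch on top without
touching anything outside their footprint.

Around the statistic the package provides:

- `annotation_model` — domain types (taxonomy, participants, ROIs, polygons,
  masks) and JSON/PNG file formats,
- `mask_render` — rasterization, default-class fill, correction patching,
  region tracing,
- `discordance` — Δ, pairwise matrices over shared ROIs (pooled or per-ROI
  median), per-class and pre/post-correction discordance, pixel-wise
  disagreement maps,
- `cohort_analysis` — tier-pair distributions, exact/approximate Mann–Whitney
  and Wilcoxon tests, biclustered heatmap ordering, classical MDS,
- `synthetic_annotators` — seeded scene generator, tier-dependent annotator
  error models (boundary jitter, confusion, miss rates), simulated reviewer
  corrections, full cohort bundles,
- `segmentation_eval` — per-class/micro/macro pixel AUC, Dice, accuracy,
  confusion percentages, patch extraction and the training-set-size
  learning-curve harness.

See `docs/methods.md` for the model and all numerical conventions.

## Worked example

Simulate a small cohort (2 senior pathologists, 4 non-pathologists; five
evaluation ROIs annotated by everyone) and analyze it:

```python
import crowdseg as cs

roster = [cs.default_error_model("SP")] * 2 + [cs.default_error_model("NP")] * 4
bundle = cs.simulate_cohort(cs.default_scene_spec(), roster, n_eval_rois=5, seed=7)

classes = ("tumor", "stroma", "lymphocytic_infiltrate", "necrosis", "blood_vessel")
matrix = cs.pairwise_discordance(bundle.eval_masks(), classes, "pooled")
print(f"{matrix.n} participants, {matrix.n_unique_pairs()} unique pairs")
for comp in cs.tier_pair_distributions(matrix):
    print(f"{comp.pair_class}: median discordance {comp.median:.3f} over {len(comp.values)} pairs")
print(f"MDS stress: {cs.mds_embed(matrix).stress:.3f}")
```

prints

```
6 participants, 15 unique pairs
NP-NP: median discordance 0.674 over 6 pairs
SP-NP: median discordance 0.559 over 8 pairs
SP-SP: median discordance 0.127 over 1 pairs
MDS stress: 0.272
```

The planted structure is recovered: the two senior annotators (1-px boundary
jitter, low confusion and miss rates) agree closely (Δ = 0.127), while pairs
involving non-pathologists (4-px jitter, 50% miss rate on non-predominant
classes) disagree much more, and mixed pairs sit in between. The MDS stress
says how faithfully the 2-D concordance plot preserves the full matrix.

The same pipeline runs from the shell:

```bash
crowdseg simulate --out study --seed 3                # cohort -> JSON + PNGs
crowdseg render   --annotations study/annotations --taxonomy study/labelmap.json \
                  --out masks --corrections study/corrections
crowdseg discord  --masks masks --classes all --agg pooled --out matrix.csv
crowdseg cohort   --matrix matrix.csv --tiers study/tiers.csv --out report/
crowdseg curve    --counts 2,4,8,16 --reps 10 --seed 1 --out curve.csv
```

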