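# specseg

Segmentation and annotation tools for multispectral microscopy images —
FT-IR (and, by extension, Raman/CARS) images in which every pixel carries
an absorbance spectrum reflecting local tissue biochemistry. The package
is aimed at people building label-free spectral-histopathology pipelines
who need (a) a fast, reference-spectrum-driven way to segment a spectral
image into tissue components and (b) a quantitative way to validate the
hierarchical clusterings conventionally used for that task.

Two ideas are at the core.

**Similarity-map segmentation.** After rescaling the whole dataset to the
unit interval (one global affine map: the minimum absorbance occurring at
any wavenumber in any spectrum goes to 0, the maximum to 1), the
similarity between a reference spectrum *R* = (R₁,…,R_B) and a pixel
spectrum *S* is the product

σ_R(S) = ∏ᵢ (1 − |Rᵢ − Sᵢ|^α),

with sensitivity exponent α (default 1.5; common choices lie between 1
and 2 — larger α damps the per-channel penalties and keeps the product
from collapsing to 0). Evaluating σ_R at every pixel yields a *similarity
map*; thresholding one or two maps per tissue class and resolving
conflicts toward the most intense map yields a segmentation. The
complement d_P = 1 − σ is also used as a dissimilarity ("power metric")
for clustering; it is a true metric for α ≤ 1 and only approximately
metric beyond (see `docs/methods.md`).

**Tree assignments: validating dendrograms by optimal non-horizontal
cuts.** A hierarchical clustering is usually turned into a segmentation
by cutting the dendrogram horizontally into k clusters, but the same
dendrogram supports many *non-horizontal* cuts: antichains of Q vertices
whose subtrees partition the items. Given a reference labeling C′, the
best depth-Q cut minimizes the data-dependent part of the Mirkin distance
M(C, C′) = Σᵢ|Cᵢ|² + Σⱼ|C′ⱼ|² − 2Σᵢⱼ m²ᵢⱼ (mᵢⱼ = |Cᵢ ∩ C′ⱼ|), which is
equivalent to maximizing the Rand index via R = 1 − M/(n(n−1)). With
per-vertex weights wᵢ = |Cᵢ|² − 2Σⱼ m²ᵢⱼ the problem is an integer
program — minimize Σ wᵢXᵢ subject to exactly one selected vertex per
root-leaf path and Σ Xᵢ = Q — that is polynomial on trees: the default
solver is an exact dynamic program, with a MILP backend (HiGHS) and a
brute-force oracle for cross-checking. Selection is restricted to the
topmost 255 dendrogram vertices (deeper vertices are not identifiable by
a human annotator), and each selected subtree is labeled by majority vote
over the reference classes. Because real annotated FT-IR datasets of this
kind are not publicly deposited, the package includes a synthetic phantom
generator that reproduces their statistical structure (unbalanced classes,
subtle mean differences, small within-class variability, ~10% invalid
pixels), so every claim is testable end to end.

Three clustering flavors produce the dendrograms: Ward's method on
correlation distance, Ward's method on the power metric, and top-down
*hierarchical two-means* (recursive 2-means bipartitioning, best of five
random restarts per split), which is far cheaper and — as the validation
shows — comparably accurate.

## Worked example

Generate a 5-class, 64×64×200 phantom with 10% planted holes, run quality
control, cluster with Ward on the power metric, and sweep the depth of
segmentation:

```python
import numpy as np
from specseg import synth, spectra_core as sc, hclust, treecut

spec = synth.PhantomSpec(K=5, B=200, H=64, W=64, separability=2.0, seed=7,
                         class_proportions=synth.geometric_proportions(5))
img, gt = synth.generate_image(spec)
img, n_disc, frac = sc.qc_filter(img)
print(f"QC discarded {n_disc} of 4096 pixels ({100*frac:.2f}%)")
img = sc.rescale_unit(img)

y = gt.labels[img.valid_mask]
keep = y >= 0                      # drop hole pixels from the reference
X, y = img.valid_spectra()[keep], y[keep]

t = hclust.cluster_spectra(X, flavor="ward_power", V=255)
table = treecut.depth_sweep(t, y, [5, 9, 13])
print(table[["Q", "objective", "rand_index", "accuracy"]].to_string(index=False))
```

which prints

```
QC discarded 410 of 4096 pixels (10.01%)
 Q  objective  rand_index  accuracy
 5   -2848472    0.992976  0.992132
 9   -2818574    0.995558  0.995117
13   -2817716    0.996044  0.995659
```

QC caught almost exactly the planted 10% of holes; the optimal depth-5
cut already recovers the 5 planted classes at Rand index 0.993, and finer
cuts (larger Q, merged back by majority vote) push both scores higher —
the characteristic depth-of-segmentation trend.

The same workflows are available from the shell via the `specseg` console
script (`specseg simulate`, `specseg simmap`, `specseg cluster`,
`specseg treecut`, `specseg sweep`, `specseg mccv`); every run writes a
`manifest.json` sufficient to reproduce its outputs exactly.

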