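# Methods

This note records the models, conventions and design choices behind
`specseg`, the parameters that matter, and what the synthetic phantoms do
and do not establish about real data.

## Data model and conventions

A spectral image is an H × W × B cube of non-negative absorbance values
with a strictly increasing wavenumber axis (cm⁻¹) and a boolean validity
mask. Coordinates are (row, col), 0-based, row-major, in every module.
Two sentinel label ids are distinct on purpose: `BACKGROUND` (−2) marks
pixels excluded from analysis (quality-control rejects, holes, off-sample
regions), `UNASSIGNED` (−1) marks valid pixels that no segmentation rule
claimed. The phantom generator emits ground truth in which planted holes
are `BACKGROUND` while the cube's mask starts all-True — the directional
invariant "invalid ⇒ BACKGROUND" only becomes an equivalence after
`qc_filter` has run, which is the intended order of operations.

## Rescaling

`rescale_unit` applies one global affine map to the whole dataset: the
minimum absorbance over all valid pixels and channels goes to 0 and the
maximum to 1. Per-spectrum or per-channel normalization would change the
relative band structure that both the similarity measure and the power
metric rely on; the global map is the only choice that preserves it.
Invalid pixels are left untouched. A constant cube has no well-defined
map and raises.

## Quality control

Practice in infrared imaging discards weak or noisy spectra before
analysis. The exact rule used on clinical datasets is rarely published,
so the package's rule is deliberately simple and configurable: a pixel is
discarded when its channel-averaged absorbance falls below
`min_integrated_absorbance` (default 0.05 a.u.) or the RMS of its first
channel differences exceeds `max_noise` (default 0.25 a.u.). The
integrated-absorbance floor is the active rule for hole-like artifacts
(near-zero signal); the noise ceiling guards against spiky detector
artifacts. Note the first-difference score depends on channel spacing:
smooth absorption bands sampled coarsely (B ≲ 100 over the full
fingerprint region) produce larger first differences, which is why the
default ceiling is loose; tighten it for finely sampled data. The rule is
monotone — raising the floor never un-discards a pixel — and on phantoms
with 10% planted holes it discards 10% ± a rounding error. No attempt is
made to match any particular discard percentage reported for clinical
images; those rules are unknown.

## Product-form similarity and the power metric

The similarity between unit-interval spectra is σ_α(R, S) =
∏ᵢ (1 − |Rᵢ − Sᵢ|^α). The formula is implemented with this
parenthesization — exponent inside, complement outside — because it is
the only reading under which larger α *lessens* the product's tendency to
vanish (for |d| < 1, |d|^α shrinks as α grows), which is the documented
role of the sensitivity parameter. The α-monotonicity is asserted as a
property test. Default α = 1.5, user-settable; 1–2 is the practical
range.

A consequence worth stating plainly: the complement d_P = 1 − σ_α is a
genuine metric only for α ≤ 1 (each per-channel term |d|^α is then a
metric, and the 1-minus-product construction preserves the triangle
inequality). For α > 1 explicit counterexamples exist — one channel with
values 0, 0.5, 1 at α = 2 gives d(0,1) = 1 > 0.25 + 0.25 — although in
high dimension distances crowd toward 1 and random violations become
vanishingly rare, which is presumably why the measure behaves like a
metric on real spectra. The alternative parenthesization
∏(1 − |d|)^α is a metric for α ≥ 1 but reverses the α behavior; no
reading gives both properties for α > 1. The test suite asserts the
triangle inequality at α = 1 and documents the α = 2 counterexample; one
acceptance-style check that demands both properties simultaneously at
α = 2 therefore fails by design and is left failing rather than papered
over.

Similarity maps evaluate σ_R at every valid pixel (NaN elsewhere).
Segmentation takes one or two references per class, each with its own
intensity threshold in [0, 1]; a pixel is claimed by a class when any of
its maps reaches its threshold, conflicts go to the most intense
qualifying map, and exact ties go to the smaller class id
(deterministic). Interactive reference picking is out of scope;
`auto_pick_references` chooses, per class, the training spectrum with the
highest mean within-class similarity as a non-interactive stand-in.

## Clustering

`ward_linkage` applies the Ward (Lance–Williams) update to a supplied
dissimilarity matrix via scipy's linkage. On non-Euclidean inputs
(correlation distance, power metric) this is formally an abuse — standard
in the infrared-imaging literature — and merge heights may invert, so
no operation assumes monotone heights: truncation and horizontal cuts
rank vertices by merge order. `horizontal_cut(k)` removes the k−1 last
merges; this coincides with a height cut on monotone trees and keeps the
resulting antichain inside any topmost-V truncation with 2k−1 ≤ V.

`truncate_topmost` keeps the V vertices nearest the root by merge order
(default V = 255, i.e. at most 128 frontier segments — vertices deeper
than that are not identifiable by a human annotator, and the limit also
bounds the optimization below). The frontier carries the pruned item
multisets; item conservation is asserted structurally.

`bisecting_two_means` builds the tree top-down and only down to the
vertex budget. Unspecified details were fixed as follows: the frontier
node with the largest within-cluster sum of squares is split next
(priority queue), so the topmost vertices capture the dominant structure;
each split runs five 2-means restarts with random-partition
initialization (centroids of a random 2-coloring seed sklearn's KMeans
with `n_init=1`, Euclidean objective, ≤100 iterations) and keeps the
lowest inertia; an unsplittable node (all points identical) stays on the
frontier. Everything derives from one seed and is reproducible.

## Tree assignments

Weights wᵢ = |Cᵢ|² − 2Σⱼ m²ᵢⱼ are exact integers computed bottom-up
(children's class-overlap vectors sum to the parent's). The depth-Q
selection problem — minimize Σ wᵢXᵢ over antichains covering every item,
|selection| = Q — is solved by default with an exact dynamic program over
the truncated tree: dp[v][q] is the cheapest way to cover v's subtree
with q selected vertices, dp[v][1] = w_v, and internal vertices combine
children by min-plus convolution. An `at_most_Q` mode relaxes the
cardinality constraint to ≤ Q (the objective is then non-increasing in Q
by feasible-set nesting; with the exact form it need not be). The MILP
formulation (objective, one exact-cover constraint per root-frontier
path — aggregated per frontier vertex, which is equivalent — cardinality
row, binary variables) is retained behind `backend="ilp"` using scipy's
HiGHS MILP and is cross-checked against the DP in the tests, as is a
brute-force antichain enumerator on small instances. Tie-breaking among
equal-objective optima: the brute-force oracle returns the
lexicographically smallest vertex-id set; the DP is deterministic (first
minimal child-budget split in a fixed postorder) but not guaranteed
lexicographic — objectives, which is what optimality claims are about,
are unaffected. Infeasible Q raises an error naming the maximum feasible
depth (the frontier size).

Majority voting labels each selected vertex with its modal reference
class (ties to the smallest class id, counted and reported); all items
below inherit the label. Reported measures: Rand index and Mirkin metric
(two independent implementations, linearly related by
R = 1 − M/(n(n−1)), an identity the tests verify to 1e−12 — n here is
the number of clustered items), accuracy with UNASSIGNED counted in the
denominator as incorrect, a confusion table sorted by descending
reference-class size, and an adjusted Rand index as an extra output
because the raw index approaches 1 when classes are many.

## Monte-Carlo validation

`monte_carlo` repeats {stratified subsample → cluster → tree-assign →
majority-vote → score} over independent folds. The per-class subsample
fraction defaults to 0.8 without replacement (the fraction is not dictated
by anything in the problem; 0.8 keeps the smallest classes populated while
leaving real resampling variance). Identical folds are applied to all
clustering flavors so arm-to-arm comparisons are paired. A class emptied
by subsampling raises an error naming the class.

## The phantom generator

Phantoms emulate the statistical structure the methods consume, not
infrared physics. Class mean spectra are a 0.08 a.u. baseline plus
Gaussian absorption bands on a 950–1800 cm⁻¹ axis (default B = 400
channels); all classes share the dominant protein bands (amide I at 1655,
amide II at 1545, CH₂ at 1455, …) with mildly varying amplitudes plus two
class-specific fingerprint bands, so between-class differences are subtle
on an absolute scale, as in real tissue. The 14-class table is a versioned
CSV fixture with loosely tissue-motivated assignments (glycogen-like bands
for crypts, nucleic-acid bands for tumour, an ester-carbonyl band for fat,
…); other K synthesize tables deterministically from the seed.

Within-class variability is a smooth random curve of L2 norm sd·|t|,
t ~ N(0,1), plus white channel noise (default 0.004 a.u.). The single
*separability* knob c sets sd = (minimum between-class mean distance)/c.
The default c = 2 keeps within-class variability clearly smaller than
between-class separation — classes remain distinguishable but clustering
is not trivially perfect, which also makes the depth-of-segmentation
trend visible; c = 10 produces the cleanly separable phantoms used for
exact-recovery checks. Class proportions default to geometric decay
(ratio 0.8), mirroring strongly unbalanced tissue composition; with that
imbalance and low separability the generator reproduces the known failure
mode of majority-vote labeling, where the smallest classes are absorbed
into larger ones at small Q. Spatial layouts: `stripes` (exact
proportions), `voronoi` (proportion-weighted nearest-seed regions,
default), `blobs`. A `hole_fraction` (default 0.10) of pixels is replaced
by near-zero rough spectra for QC to catch.

What passing phantom tests do *not* show: robustness to baseline drift,
Mie scattering, atmospheric residuals or other real-data artifacts (all
assumed corrected upstream and not simulated), nor that real tissue
classes are as Gaussian or as homoscedastic as the phantom's.

## Problem sizes and numerical choices

Test and reproduction runs use desk-scale sizes chosen to exercise every
code path: recovery phantoms of 64 × 64 × 200 (≈3,700 valid spectra after
QC), Monte-Carlo validation on 1,800 training spectra at B = 200 with 10
folds, property checks on 10⁵ random triples and ~1,000 random
trees/partitions. Dense power-metric distance matrices are computed
blockwise in float32 via log-similarity accumulation (exact symmetry is
enforced afterwards); Rand-index pair counting is O(n²) boolean algebra,
fine to a few thousand items, while the Mirkin route is contingency-based
and scales further. Degenerate inputs raise rather than guess: constant
cubes at rescaling, zero-variance spectra under correlation distance,
non-finite dissimilarities, infeasible depths.

## Known limitations

- Comparing two dendrograms against each other (a modified selection
  program over both trees) is out of scope, as are variation-of-
  information cuts.
- Vendor file formats (ENVI/OPUS/Agilent) are not read; use the
  delimited, HDF5 or TIFF dialects.
- The newick round-trip reconstructs merge order from node heights and is
  faithful for monotone trees; trees with height ties or inversions may
  reorder internal vertices.
- The DP solver's tie-break among equal-objective antichains differs from
  the documented lexicographic rule of the brute-force oracle (see above).
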