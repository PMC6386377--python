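# Methods

## Overview

`morphoquant` re-implements, as a local scriptable toolkit, the two engines
of a click-based bioimage-analysis platform: a staged particle analyser and
a whole-image classifier. The particle analyser runs a fixed stage order —
noise reduction → binarisation → postprocessing (repeatable) → watershed —
where every stage is restricted to a whitelist of vetted operators, and the
chosen sequence is recorded as a JSON *recipe*, the unit of
reproducibility. The classifier extracts higher-order local autocorrelation
(HLAC) and whole-image morphometric features and trains a random forest
under stratified k-fold cross-validation.

## Synthetic data generator

No suitable ground-truthed benchmark data ship with the package, so all
tests and the acceptance script run on synthetic fluorescence-like images:
elliptical particles rendered at a constant foreground intensity over a
constant background, then corrupted with noise.

* **Rasterisation** is by pixel-centre test: a pixel belongs to an ellipse
  iff its centre satisfies the ellipse inequality. This makes brute-force
  pixel counting an exact, unambiguous oracle for areas and moments.
* **Defaults**: 512×512 frames; particle semi-axes 4–12 px with
  minor/major ratio 0.5–1.0; foreground 0.8 ± 0.05, background 0.1 ± 0.03
  (arbitrary units in [0, 1]); Gaussian noise. These emulate well-exposed
  spot-like fluorescence signals (e.g. immunolabelled stress granules)
  at a realistic signal-to-background ratio of ~8.
* **Poisson noise** has no natural scale on [0, 1] data, so intensities are
  scaled to a photon budget (default 1000 counts at intensity 1.0),
  Poisson-sampled, and rescaled.
* **Disjoint placement** uses rejection sampling (bounded at 10,000
  attempts per particle, with an explicit error naming the achieved count)
  and enforces a 2-pixel clearance between particles rather than mere
  pixel-disjointness. Without the clearance two particles can be
  8-adjacent, which both breaks the components-equal-count invariant and
  makes count recovery depend on the denoiser's bandwidth.
* **Class-structured datasets** derive per-image seeds deterministically
  from a master seed (`numpy` `SeedSequence`), so a dataset is a pure
  function of its specs and seed. The built-in seven-class catalogue
  (`default_cell_cycle_specs`) emulates the morphology axis of a
  cell-cycle labelling — classes differ in particle count (1, 2 or 4),
  size, elongation and brightness, the way interphase nuclei differ from
  metaphase plates or anaphase chromosome pairs. Class images are 96×96:
  single-cell crops are small, and no canonical dimensions exist for such
  datasets.

What the generator does *not* emulate: optical blur (no PSF convolution),
intensity gradients and uneven illumination, autofluorescent background
structure, debris, or out-of-focus light. Passing tests therefore
demonstrate correctness of the measurement and classification machinery on
images whose ground truth is exactly known — not segmentation robustness on
adversarial real micrographs.

## Operator catalogue

Three stages with fixed signatures (noise reduction: image→image;
binarisation: image→mask; postprocessing: mask→mask). Numerical choices:

* All convolution/rank filters pad by **reflection**, avoiding dark-border
  artefacts that bias border particles.
* **Difference of Gaussians** requires σ₁ < σ₂ and clamps its output at 0,
  because downstream thresholding expects non-negative intensities.
* **Otsu on a constant image** returns an all-background mask instead of
  raising, so degenerate previews never abort candidate enumeration.
* Adaptive thresholds accept **odd window sizes only** (centred windows).
* Binarisation defaults to bright-foreground polarity (the fluorescence
  convention); an `invert` parameter serves bright-field data.
* `remove_small_objects` keeps exactly the 8-connected components with
  area ≥ `min_area`, computed directly from a component-size table so the
  boundary is inclusive and version-independent.

The **non-local means filter is deliberately blacklisted**: it denoises a
region by averaging intensity distributions borrowed from distant regions
whether or not those regions are biologically identical, which can
fabricate local structure. `integrity_check` rejects it by name with that
reason, and it can never enter a candidate grid.

## Segmentation

Connected components at 4- or 8-connectivity (default 8, the common
particle-analyser convention). Watershed splitting floods the negated
Euclidean distance transform of the mask from markers that are either
distance-transform local maxima separated by at least `min_distance`
(default 5 px) or h-maxima with depth ≥ `h` (default 2.0). Markers are
numbered in raster order, so ties between equidistant markers break
deterministically toward the lower label. The flood runs with watershed
lines enabled; ridge pixels are assigned to background so split particles
are disjoint and their areas unambiguous. Components untouched by any
marker are resurrected as single labels (a marker-free blob is still a
particle); labels are then relabelled consecutively.

## Morphometry

Per-particle features and their pinned formulas:

| feature | formula |
|---|---|
| area | pixel count (µm² only when a physical pixel size is provided) |
| ellipse axes | moment-equivalent ellipse: 4·√(eigenvalues of the central second-moment tensor of the pixel-centre set) |
| roundness | 4·area / (π·major²) — the particle-analyser convention; equals minor/major for an exact ellipse, 1 for a circle |
| circularity | 4π·area / perimeter², reported as a separate, clearly named column |
| perimeter | weighted crack-boundary length with diagonal weighting |
| solidity | area / area of the convex hull of the pixel-centre set |

A single-pixel particle gets both axes = 1 (the moment tensor vanishes;
axes of zero would propagate division-by-zero into roundness).
Circularity of a particle with zero estimated perimeter is NaN.

Perimeter-based circularity and moment-based roundness disagree on
discretised shapes; both are reported so population comparisons can use
either. Shape features on rasterised shapes carry an O(1/r) discretisation
error; tests allow 5% on roundness/solidity and 3% on axes at the radii
they use.

## Group comparison

Two-sided Mann–Whitney U. The exact route enumerates every group
assignment with mid-rank ties and measures two-sidedness as distance of U
from its null mean n₁n₂/2 (the null is symmetric about that centre even
under ties); it is used whenever C(n₁+n₂, n₁) ≤ 200,000. Tie-free problems
with n₁·n₂ ≤ 400 use the exact U distribution; everything else uses the
tie-corrected normal approximation with continuity correction, matching
the convention of R's `wilcox.test` at the sample sizes of a typical
batch-versus-batch comparison (65 images per group).

## Candidate engine

Candidate grids are the context-ordered operator list crossed with each
operator's parameter grid, capped at 12 entries by round-robin over
operators (so the cap keeps variety), in a deterministic order. The
context rules are explicit heuristics of this implementation, not
reconstructions of any particular tool's logic: fluorescence prefers
gaussian/median/DoG denoising and never offers inverted polarity;
bright-field prefers median and allows inversion; electron microscopy
prefers adaptive thresholds. Any whitelisted operator can still be chosen
directly, so the rules only affect ordering and defaults.

Recipes are immutable values: `select_candidate` returns an extended copy,
previews are pure functions of (image, recipe-so-far, spec), and any
result is a function of (image bytes, recipe JSON). Reports embed the
recipe JSON verbatim in a fenced block, and `recipe_from_report` recovers
it, so a report alone suffices for exact re-execution.

## HLAC features

For window half-width d (default 1), the features are sums over all
interior window positions of products of intensities at the cells marked
by a mask pattern, normalised by the number of interior positions. Mask
patterns contain the centre, have 1–3 cells (orders 0–2), and are
deduplicated under translation — translating a displacement set only
shifts the summation index, so translates are redundant. At d=1 this
yields the canonical 25 features (1 + 4 + 20). Normalising by interior
position count makes features comparable across image sizes and makes
translation invariance of interior content exact (tested to 1e-12).

Grayscale HLAC (products of [0,1]-normalised intensities) is the default;
a `binary` flag thresholds at the range midpoint first, and on {0,1}
images the two coincide.

## Morphometric feature bundle

A fixed 22-feature whole-image descriptor: intensity mean/sd/skewness/
kurtosis and five quantiles; foreground fraction, particle count and a
validity flag from a measurement recipe (default: the headless
fluorescence recipe); and mean/sd of area, roundness, solidity and both
ellipse axes over detected particles. Images with no detected particles
carry zeros in the per-particle slots with the validity flag at 0, keeping
the schema length fixed. This bundle is this package's own documented
design — a compact morphometry summary, not a reconstruction of any
proprietary extractor.

## Classification

Random forest (default 500 trees, √#features per split, unlimited depth,
all recorded in the report) on the concatenated HLAC + morphometric
features; either family can be disabled. Evaluation is stratified k-fold
cross-validation, default k = 3, with seeded shuffling; features are
extracted once for the whole dataset (they are per-image pure functions,
so nothing leaks across folds — the chance-level test on shuffled labels
guards this), and each fold trains a fresh forest. Per-class accuracy is
recall: confusion-matrix diagonal over row sum.

Class merging relabels the *stored out-of-fold predictions* and re-scores
without re-training. The built-in map pools prophase/prometaphase/
metaphase into `early_mitotic` and anaphase/telophase into `late_mitotic`,
other labels unchanged (7 → 4 classes). Merging applies one function to
both truth and prediction, so every position-level match is preserved;
accuracy can therefore never decrease — verified exhaustively over all 49
(truth, prediction) label pairs and all 49³ joint length-3 vectors, plus
seeded random length-6 vectors.

## Problem sizes used in tests and the acceptance script

Shape oracles use disks of radius 10/20/40 and a 30/10 semi-axis ellipse;
count recovery uses one 512×512 image with 50 disjoint particles and a
radius-15 disk pair at centre gap 20; group comparison uses 65 samples per
group (the batch-validation design size); classification uses the built-in
seven-class catalogue at 30 images per class (210 images of 96×96), with
ten label-shuffled replicates for the chance-level check. These sizes make
the whole suite run in well under a minute while keeping every class
larger than the number of CV folds.

## Known limitations

* The particle analyser is 2-D only: no stacks, no time series.
* Watershed operates on the binary mask's distance transform only; no
  intensity-gradient watershed.
* The suggestion heuristics are stand-ins; they rank candidates but encode
  no learned knowledge about specimen types.
* Classifier accuracies on the synthetic seven-class catalogue (near 100%)
  reflect its deliberate separability and say nothing quantitative about
  accuracy on real micrograph collections.
* The model file produced by `ImageClassifier.save` uses pickle and is not
  portable across incompatible scikit-learn versions.
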