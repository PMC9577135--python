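# Methods

## Data model

A cohort is a list of ROIs, each an RGB image paired with a label map over
11 tissue classes plus a reserved *avoid* index for unlabeled pixels.
Labels travel as 8-bit RGB PNGs in which each class owns one exact color;
the color palette is a repository convention (the class list names colors,
not RGB values): Stroma (255,0,0), Tumor (0,0,255), Lymphocytes (255,255,0),
Mucosa (135,206,235), Background/Adipose (128,128,128), Blood (0,128,0),
Nerves (255,165,0), Necrosis (0,0,0), Keratin Pearl (0,0,139), Muscle
(128,128,0), Junk (255,192,203), avoid (255,255,255). Decoding is exact
match only — a lenient mode maps unknown colors to avoid, a strict mode
raises — because synthetic data is lossless and silent nearest-color
snapping would hide corrupt inputs. The 12-class pre-merge legend keeps
Background at gray and gives Adipose light gray (211,211,211); merging the
pair produces the canonical 11-class legend.

Splits are at patient level: every ROI of a holdout patient is holdout.
This is an invariant, property-tested over many seeds.

## Preprocessing

ROIs are resampled to a target resolution in microns per pixel (bilinear
for images, nearest-neighbor for labels so no new class indices appear),
optionally center-cropped (padding, when allowed, fills labels with avoid
and images with a chosen color such as the dataset mean), and standardized
per channel against statistics computed **on the training pool only** and
frozen for validation and holdout. "Standardization to the dataset mean" is
read as subtract-mean-divide-by-std; a mean-only mode preserves the literal
reading. A floor of 1e-6 on the per-channel std guards constant-color
degenerate inputs.

## Network

The segmentation model is a U-net variant: `depth` = 4 encoder blocks of
[3×3 same-padding conv → batch-norm → ReLU → 2×2 max-pool], a bottleneck
conv block, and 4 decoder blocks of [nearest ×2 upsample → concatenate the
mirror encoder's pre-pool features → conv → batch-norm → ReLU], then a 1×1
projection to class logits. One conv per block (configurable). Channel
widths double per level from `base_channels` (default 32 → 512 at the
bottleneck; width is not dictated by the architecture description, so it is
a tunable). Dropout (default drop probability 0.8, deliberately aggressive)
applies after each max-pool during training only. Optimization is Adam
(optimizer unspecified in the protocol; Adam is the de-facto default and is
recorded in the config), batch size 1, on the masked loss below. Retraining
at each pipeline iteration starts from fresh initialization, which keeps
the AL/RL comparison clean of warm-start confounds.

Implementation notes:

- Forward/backward are written directly on NumPy arrays (channels-first
  float32). Convolutions are im2col + BLAS matmul; the input gradient is
  the correlation of the output gradient with the flipped, transposed
  kernel, which reuses the same conv routine. The full backward pass is
  verified against central-difference numerical gradients in the tests.
- Batch normalization at batch size 1 normalizes each channel over its
  spatial extent. Inference uses the same per-image statistics rather than
  running averages: deterministic per input, repeatable bitwise, and free
  of stale-statistics artifacts in short training schedules.
- Argmax tissue maps break probability ties toward the lowest class index
  and can never emit the avoid index.

## Loss and metrics

The loss is masked categorical cross-entropy: the mean of −log p(true
class) over non-avoid pixels. Avoid pixels contribute nothing — the loss is
provably invariant to their predicted distributions — because annotators
label only tissue they are confident about, so unlabeled pixels carry no
supervision. True-class probabilities are clamped at 1e-12 with a warning.

Evaluation micro-pools confusion counts (TP/FP/FN/TN per class) over all
holdout pixels before forming any ratio, so N images score identically to
their concatenation. Per-class Dice is 2TP/(2TP+FP+FN); classes absent from
both truth and prediction are flagged undefined and excluded — scoring them
0 would punish a model for classes that are not there. The reported mean
Dice is the unweighted mean over defined classes present in the holdout
truth. One-vs-all AUC uses the rank statistic (tie-corrected, via
scikit-learn), equal to the probability a random positive pixel outranks a
random negative; the test suite checks it against exhaustive pair counting.
Loss curves are smoothed with a centered 3-epoch moving average, truncated
at the edges.

## The AL loop and the simulated pathologist

Each experiment: bootstrap D₀ = 4 ROIs drawn uniformly from the 21-ROI
training pool; train C₀; for i = 0..2, the current classifier segments the
never-selected remainder of the pool, each tissue map is graded, the 4
lowest-scoring ROIs join the training set, and C_{i+1} is trained from
scratch. The RL control replaces grading with uniform random promotion
(without replacement from the never-selected pool, as implied by the finite
pool and growing training sets) and runs in triplicate. C₀ is literally the
same classifier in every arm. Budget parity — |Dᵢ| equal across arms at
every i — is asserted in the tests, as is D₀ ⊂ D₁ ⊂ D₂ ⊂ D₃ nesting.

Human QA grading is replaced by a simulated oracle: for each class present
in an image's ground truth, the per-image Dice d_c maps to the integer
grade round(5·d_c) (half rounds up), optionally perturbed by
integer-rounded Gaussian noise and clamped to 0–5. The per-image ranking
score is the unweighted mean of per-class grades (the aggregation from
per-class grades to a per-image ranking is a design choice); ties break
lexicographically by ROI id so selection is deterministic. With zero noise
the selection equals the k-argmin of independently recomputed mean grades,
which the acceptance tests verify by per-pixel brute force.

Validation: 25 % of the currently selected training set (at least 1 ROI),
chosen per iteration by a derived seed, is held out from gradient updates
and tracked as validation loss (the protocol plots validation loss but
never defines the split; this is the package's definition).

The final comparison pairs per-class holdout Dice of the last AL version
against the per-class mean of the three RL batches and applies a two-sided
paired Wilcoxon signed-rank test (a defensible nonparametric choice at ~8
paired classes; the test identity is recorded with the result). All
randomness in an experiment — bootstrap, RL draws, model init, shuffling,
validation choice, oracle noise — derives from one master seed through
named SeedSequence streams.

## Synthetic cohorts

The generator emulates the *statistical structure* of a pathologist-
annotated ROI cohort, not its appearance: 23 patients, 24 ROIs (one patient
contributes two), 11 classes with strongly skewed prevalence. Label maps
are layered thresholded Gaussian random fields: a stroma background;
background/adipose margins; rare mucosa/muscle/necrosis/nerves/junk/blood
patches, each present in only a per-ROI Bernoulli fraction of images; tumor
nests, half of which carry keratin-pearl cores carved from their interiors
(the tumor threshold is inflated to compensate, keeping realized tumor
prevalence on target); and lymphocyte infiltrates whose field is biased
toward the band just outside tumor nests. Blob scale is fixed in microns —
tissue structures do not grow with the ROI — so larger ROIs average over
more independent blobs and realized class fractions tighten around their
targets (tested at two sizes).

Rendering assigns each class an H&E-like mean color (pink stroma, purple
tumor, dark lymphocyte infiltrate, near-white adipose, bright eosinophilic
keratin), adds one shared per-patient color offset (making patient-level
splitting consequential), and corrupts the image with spatially correlated
plus white Gaussian noise whose amplitudes scale with `hardness` ∈ [0,1]
(default 0.35; the tests verify that hardness 0.8 cohorts are measurably
harder to segment than 0.1). About 10 % of labeled pixels are re-masked to
avoid, preferring class boundaries — mimicking annotators who skip
ambiguous edges. The image is rendered from the pre-avoid label map: the
annotation is withheld, not the tissue.

What passing tests on this cohort do **not** show: real H&E texture,
stain variation, scanner artifacts, annotator disagreement, or realistic
class confusability (classes here are separable mostly by color). The
synthetic experiment demonstrates that the pipeline's selection mechanism
works when informativeness heterogeneity exists; it cannot certify
clinical-scale effect sizes.

## Desk-scale study conditions

The published protocol (2000×2000 ROIs, 300 epochs, 32-channel base width)
is far beyond a CPU test budget. The desk configuration used by the tests
and the acceptance script keeps the cohort shape (24 ROIs / 23 patients /
3 holdout patients / 4-ROI bootstrap / 3 iterations / triplicate RL) and
scales the rest: 64×64 ROIs at 2 µm/px, base width 8, 30 epochs per
training, learning rate 3e-3 (Adam needs the larger step to converge in
the short schedule), dropout 0.25 (dropping 80 % of an 8-channel feature
map leaves no signal at this width). These sizes are the package's desk
defaults; the full-scale settings remain available as
`presets.full_scale_*`. At desk scale the AL-vs-RL claim is directional:
AL's final mean holdout Dice and final validation loss beat the RL-batch
mean in a majority of experiment seeds, with the per-class Wilcoxon
comparison reported but not expected to reach significance at n ≈ 8
classes and this effect size.

## Numerical conventions and edge cases

- Grades and Dice→grade mapping round half up (deterministic across
  platforms, unlike banker's rounding).
- Dice is symmetric under swapping prediction and truth (FP↔FN leave the
  formula unchanged) — used as a property test.
- `select_lowest` with fewer candidates than k returns all with a warning;
  an exhausted pool stops the loop early with a warning and a truncated
  record list.
- An all-avoid training ROI is skipped with a warning (no gradient
  signal); an all-avoid ground truth is ungradeable and an error.
- Forward raises on spatial sizes not divisible by 2^depth, naming the
  required divisor.
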