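# Methods

This document describes the models, the synthetic data generator, the
numerical choices, and the known limitations of `strokekit`. The package
implements a two-stage, segmentation-guided workflow for acute ischemic
stroke lesions in diffusion-weighted MRI (DWI): a slice segmenter produces a
per-patient lesion mask (the *SegMap*), a SegMap-guided 3D classifier labels
the lesion by size (lacune vs non-lacune) and vascular territory
(anterior vs posterior), and an atlas module reports where the lesion sits.

## The two-stage model

### Stage One: slice segmentation (`strokekit.s1_segmenter`)

A 2D U-shaped encoder-decoder segments each transverse slice independently;
the binarized per-slice outputs are stacked in slice order into the 3D
SegMap. Segmenting in 2D reflects clinical DWI geometry: slices are thin
in-plane (here 1 mm) but 7 mm apart, so through-plane context is weak and a
2D network is both cheaper and better conditioned than a 3D one at this
resolution.

Architecture (`S1Config` defaults): depth 3, base width 8 (widths 8/16/32),
one of three block types — `plain` (two 3x3 convolutions), `residual`, or
`dense` — standing in for the full-scale VGG/ResNet/DenseNet U-Net variants.
Max-pool downsampling, nearest-neighbour upsampling, skip concatenation, and
a 1x1 sigmoid head. Training minimizes the Focal Tversky loss (defaults
alpha=0.7, beta=0.3, gamma=4/3) with Adam (lr 3e-3, cosine-annealed),
batch 16 slices, 10 epochs, with slice-level augmentation (rotation up to
10 degrees, horizontal flip, 5% shift and scale). The parameter state with
the best validation Dice over epochs is kept. Lesion voxels are on the
order of 0.1% of a slice, which is exactly the regime the Tversky weighting
(penalizing false negatives more than false positives) is designed for.

### Stage Two: SegMap-guided 3D classification (`strokekit.s2_classifier`)

The classifier input is the voxelwise product volume x SegMap ("extracted
stroke area"): the network sees the lesion's intensities and 3D geometry and
nothing else. `mask_only` and `two_channel` input modes exist for ablation;
both measured worse on replicate phantom cohorts (see the iteration notes
below). The same network trained on the full preprocessed volume is the
traditional one-stage baseline (`train_one_stage`).

Architecture (`Net3D`): three 3x3x3 conv blocks (widths 8/16/16) each
followed by max-pooling (2,2,2), (2,2,2), (2,2,1), then a dense head
(flatten -> 32 -> 1 logit). The head flattens the coarse spatial grid rather
than globally pooling so the classifier keeps location information — needed
for the territory task.

Training (`S2Config` defaults): focal loss (alpha=0.25, gamma=2), Adam
(lr 3e-3, cosine-annealed, weight decay 1e-4), batch 8, 30 epochs,
stratified 75/25 train/validation split. Inputs are stored at full
resolution; augmentation (in-plane isometries plus up to 2-voxel integer
shifts) is applied at full resolution and the 2x in-plane block-mean
downsampling happens per batch, so fine structure such as the 2 mm gap
between scattered lesion components is presented at many phases of the
downsampling blocks. The size task augments over the full dihedral group
(x/y flips and transposition — the size label is invariant to every
in-plane isometry); the territory task flips only left-right, since an
anterior-posterior flip would relabel the territory. Test-time
augmentation averages logits over the same flip group. The epoch state with
the lowest validation focal loss is kept, and the decision threshold is set
by Youden's index on the validation predictions. An optional ensemble
(`n_ensemble`) trains several members on the same split from independent
initializations and averages probabilities; it did not improve accuracy on
replicate cohorts and defaults to 1.

Patients whose lesions span both territories are excluded from the
territory task before training, and the count is recorded
(`n_excluded_both`).

### Labels

A lesion is a *lacune* when it is a single connected component (26-
connectivity) whose maximal in-plane Feret diameter is at most 20 mm;
multiple scattered components or a larger diameter make it *non-lacune*.
Territory is anterior or posterior according to the atlas regions the
lesion occupies; lesions touching both are labeled "both" and excluded from
territory classification.

## Atlas-based lesion mapping (`strokekit.lesion_mapping`)

Three per-region lesion-distribution indices are reported: the lesion voxel
count in the region, the percent of the lesion in the region, and the
percent of the region occupied by the lesion. Counts are computed on a
shared native grid, so region counts plus the out-of-atlas remainder sum
exactly to the lesion total.

The built-in registration estimates a 12-parameter world-to-world affine by
minimizing the mean-squared intensity difference (Powell, multi-start over
principal-axis initializations seeded from centers of mass, on lightly
smoothed images). A hook accepts a precomputed 4x4 matrix from an external
registration tool instead; transforms compose, invert, and round-trip
through plain-text files. Masks and label maps are resampled with
nearest-neighbour interpolation, intensity volumes with trilinear.

## Cohort accounting (`strokekit.cohort_accounting`)

Screening manifests carry per-patient inclusion status and exclusion
reasons; summaries report counts and percentages rounded half-up to one
decimal (`round_half_up`, via `decimal.Decimal`), matching the rounding
convention of clinical tables (e.g. 11/239 -> 4.6%, 111:51 -> 68.5%:31.5%).
The development/test split is chronological: patients are sorted by
acquisition date (ties by patient id) and the earliest `ceil(N * 0.8)` form
the development set — mirroring how a deployed model trains on the past and
is tested on the future.

## The phantom generator (`strokekit.phantom`)

Real DWI with expert lesion outlines cannot ship with a test suite, so the
package generates phantoms with exactly known ground truth.

Geometry: 64x64x8 grids at 1x1x7 mm — clinical DWI anisotropy (fine
in-plane, thick slices) at a CPU-trainable size. A brain-shaped ellipsoidal
mask is partitioned into atlas regions by seeded nearest-centroid growth;
regions anterior of the brain's midline carry the anterior-territory flag.

Signal: background brain tissue at a fixed mean with Gaussian noise
(SD 10), zero outside the brain; lesions are ellipsoids (through-plane
semi-axis matched to slice thickness) brighter than brain by
`intensity_contrast` noise-SDs (default 5, i.e. clearly hyperintense, as
acute infarcts are on DWI). Cohorts are balanced: half lacunes (6-16 mm),
half non-lacunes, the latter split between single large lesions (22-26 mm)
and 2-3 scattered embolic-like components (7-11 mm) with at least a 2-voxel
moat between components. Sub-voxel center jitter decorrelates lesion
boundaries from the grid.

What the phantoms do **not** model: partial-volume and susceptibility
artifacts, T2 shine-through, bilateral chronic changes, intensity
inhomogeneity, anatomy (ventricles, gray/white contrast), or any
correlation between lesion location and appearance. Recovery numbers on
phantoms are an upper bound on clinical performance and validate the
*machinery*, not clinical readiness.

## Numerical choices

- **No deep-learning framework is available**, so `strokekit.nn` implements
  a small reverse-mode autodiff core over numpy: tensors, elementwise ops,
  matmul, im2col-based 2D/3D convolution, max-pool, nearest upsample,
  concat, Adam, and cosine annealing. Forward passes run in float32;
  gradient checks in the test suite use central differences with
  tolerances set by float32 precision.
- **Losses** (`strokekit.losses`) are plain numpy reference implementations
  with the standard reductions: focal loss equals cross-entropy at
  gamma=0, alpha=1, and the Focal Tversky loss equals the soft Dice loss at
  alpha=beta=0.5, gamma=1 (both verified in tests). The graph-building
  variants used in training mirror them.
- **z-score normalization** computes statistics over the nonzero support
  only, and exact zeros stay exactly zero: appended blank padding slices
  neither shift the statistics nor acquire nonzero values.
- **Youden threshold** maximizes sensitivity + specificity - 1 over the
  validation predictions; ties resolve to the smallest qualifying
  threshold, and classification uses probability >= threshold.
- **AUROC** is computed by the exact pairwise concordance (Mann-Whitney)
  formulation with tie correction, verified against a brute-force oracle.
- **Seeds**: every stochastic step takes an explicit seed; pipeline and
  acceptance runs derive per-stage seeds as
  `crc32(stage) XOR (global_seed * 2654435761) mod 2^31`, which decouples
  stages while keeping every derived seed in range.

## Design-iteration notes (Stage Two size task)

The hardest signal at desk scale is multiplicity: compact 2-3 component
scattered lesions (non-lacunes) vs single lacunes of the same overall
extent, distinguishable only by the small gaps between components — with
roughly eight scattered examples in a 48-patient training split. Measured
on replicate phantom cohorts, the adopted design (full-resolution
augmentation with per-batch downsampling, dihedral-group augmentation,
flip-averaged test-time augmentation, best-epoch selection by validation
focal loss) clearly beat: training at full resolution (worse, despite
preserving the gap), `mask_only` and `two_channel` inputs, residual and
larger backbones, smaller batches, and a 3-member seed ensemble (no gain;
the remaining errors are systematic, not initialization variance).

## Limitations

- Held-out accuracy for the size task is measured on 16-patient validation
  sets, so it is quantized in 1/16 steps. Across ten replicate cohorts the
  two-stage classifier measured 0.875-1.000 (mean 0.919); means over
  5-cohort batches ranged from 0.89 to 0.95 depending on the cohorts drawn.
  The AUROC advantage of the two-stage design over the one-stage baseline
  was consistent (10/10 cohorts). Conclusions about a +/-0.02 accuracy
  difference are below the resolution of this sample size.
- The scratch autodiff core is single-threaded numpy: minutes per training
  run, suitable for phantoms only.
- The built-in affine registration assumes overlapping fields of view and
  roughly similar intensity profiles; for real data, use the external
  transform hook with a dedicated registration tool.
- 2D slice segmentation composes SegMaps without through-plane
  regularization; with 7 mm slices this matches acquisition, but isolated
  single-slice false positives are possible and uncorrected.
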