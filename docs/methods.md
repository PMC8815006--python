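# Methods

`woodid` implements a complete macroscopic wood-identification pipeline for
North American diffuse-porous hardwoods: label-space construction,
specimen-exclusive stratified cross-validation, patch-based CNN training
with a two-stage transfer schedule, specimen-level top-k voting, and a
source/sink decomposition of the confusion matrix with typed
misclassification tables. Because the xylarium image collections that
motivate the pipeline are access-restricted, the package ships a procedural
wood-texture simulator that makes every stage testable end to end.

## The classification problem

Transverse-surface macro images (2048 × 2048 px at 3.1 µm/px, i.e. a
6.35 mm × 6.35 mm field of view) are captured from sanded specimen
surfaces. Macroscopic identification is reliable only to genus level, so
taxa are grouped into 22 classes: 18 genera map one-to-one to genus labels
(Aesculus … Tilia); *Acer* splits into hard maple (`AcerH`, *A. saccharum*,
separable by macroscopic ray width) and soft maples (`AcerS`); *Prunus
serotina* stands alone as `Prunus`; and the remaining fruitwood genera
(Crataegus, Malus, other Prunus, Pyrus, Sorbus) collapse into `Fruitwood`.
Species-level rules override genus rules; matching is case-insensitive and
whitespace-normalised, with no fuzzy synonym resolution. Unmapped taxa
raise a lookup error naming the taxon — correctness over fabricated
completeness; the shipped map covers every taxon named in the package's
scope and is user-extensible via a two-column CSV.

## Why splits are specimen-exclusive

All images of one physical specimen share surface preparation, growth
history, and imaging session. Folds are therefore built over specimens, not
images: per class, specimens are shuffled with the fold seed and dealt
round-robin to k folds from a seed-chosen offset, so per-class fold counts
differ by at most one wherever class sizes permit. Classes with fewer
specimens than k simply appear in fewer folds; if the deal leaves a fold
empty (possible only when k exceeds every class size) a single specimen is
moved from the fullest fold. The package also contains the experiment that
justifies the rule: on synthetic data with strong specimen effects,
image-level (leaky) folds overstate accuracy relative to specimen-exclusive
folds (`evaluation.compare_split_strategies`).

## Model and training

The classifier is a convolutional backbone plus a custom head: global
average and global max pooling are concatenated (2C features for a backbone
with C final channels; 1024 for the ResNet-34-style backbone), then
batchnorm → dropout 0.5 → fully connected (512) → ReLU, and batchnorm →
dropout 0.25 → fully connected → softmax over the classes.

Three backbones are provided. `compact_cnn` (four 3×3 conv/batchnorm/ReLU
blocks, 64 final channels) is the desk-scale default so the full pipeline
trains in minutes on one CPU core. `resnet34_style` (basic residual blocks,
3-4-6-3, 512 channels) reproduces the full-scale architecture;
`resnet50_style` (bottleneck blocks, 2048 channels) is available for
capacity comparisons. The network, its backprop, and the Adam optimiser are
implemented in NumPy (`woodid.nn`); gradients are verified against central
finite differences in the test suite, and all randomness flows through
explicitly seeded generators, so training is deterministic on a single
thread.

Training is two-stage: stage 1 freezes the backbone bit-exactly and
optimises the head only (appropriate when the backbone starts from
pretrained weights, which can be loaded from a checkpoint file); stage 2
fine-tunes everything with the backbone learning rate scaled by 0.1. Both
stages use Adam under a two-phase simultaneous cosine annealing applied per
stage: over the first `phase1_frac` (default 0.3) of steps the learning
rate rises from `0.04·lr_max` to `lr_max` while the first-moment
coefficient ("momentum") anneals from 0.95 down to 0.85; the remaining
steps decay the learning rate to `0.01·lr_max` while momentum mirrors back
up. Defaults: 5 + 10 epochs, `lr_max` 1e-3, cross-entropy loss, batch
size 16. The desk-scale experiments in the test suite use 10 + 60 epochs at
`lr_max` 3e-3: with only ~4 batches per epoch on a 72-image training fold,
that step budget (~280 steps) is what the compact backbone needs to fit its
training folds.

### Patches and augmentation

Each mini-batch holds one patch from each of 16 distinct images. A patch
spans the full image width (2048 px at capture scale) and 768 rows at a
uniformly random row offset, and is area-average downsampled 4× to
512 × 192 before augmentation: horizontal/vertical flips (p = 0.5 each), a
small rotation uniform in ±5° with reflect padding, then cutout (one
48 × 48 rectangle filled with the patch mean). Augmentation never changes
patch dimensions or labels. The patch orientation convention — 2048 along
columns, 768 along rows — matches the renderer, whose growth rings run
along rows, so every patch crosses rays and samples a random ring phase.

`PatchConfig.desk_scale` adapts the geometry to small synthetic images
(full width, 3/8 of the rows) but downsamples only 2×: desk-scale images
are rendered at the capture pipeline's *post*-downsampling resolution
(12.4 µm/px), so a further 4× would push vessels (~80 µm ≈ 6.5 px) below
the pixel scale.

### Inference

Inference is deterministic: three full-width patches at the top, centre,
and bottom row offsets are scored and their softmax outputs averaged. A
single centre patch was considered and rejected — it sees only ~37 % of
the image rows, so structure such as the earlywood bands of a wide-ringed
specimen can fall entirely outside it, and the tiling measurably
stabilises image-level calls at no reproducibility cost.

## Specimen-level voting

The deployable unit of prediction is the specimen. Up to five images per
specimen are used, taken in manifest order and fixed before any
evaluation. The top-1 call is the plurality of the image-level argmax
classes; the top-2 call gives each image one equally weighted vote for each
of its two highest-scoring classes and returns the two classes with the
most votes; a specimen is top-2 correct if its true class is either member.
Ties (undefined in the usual description of majority voting) are broken by
the larger score summed over the specimen's images, then by lexicographic
label order. Both operators are verified against exhaustive brute-force
enumeration on small vote tables. Pooled over folds, the confusion-matrix
trace over total equals top-1 accuracy by construction.

## Misclassification analysis

For each class, *source* misclassifications are its own specimens predicted
elsewhere (off-diagonal row sum) and *sink* misclassifications are wrong
predictions it attracts (off-diagonal column sum); both sum to the total
number of misclassified specimens. Each misclassified specimen carries a
type assigned by a human wood anatomist and consumed as an input file,
never inferred: Type 1 (classes anatomically consistent, specimen typical),
Type 2 (specimen atypical for its taxon), Type 3 (classes anatomically
disparate — an error a human identifier would not make). Types 1 and 3 are
mutually exclusive within a (true, predicted) class pair; the ledger
validator flags violations and any disagreement with the confusion-matrix
cells. Report tables give per-type shares of the misclassified specimens
and of all specimens, and per-class source proportions (denominator: the
class's specimen count) and sink proportions (denominator: all
misclassified specimens), rounded to 3 decimals for reports with totals
computed from unrounded values.

## The synthetic-wood simulator

The renderer composes, over a mottled grey background: growth rings
(smooth periodic darkening toward each ring boundary, variable ring widths,
random phase), vessels (dark ellipses at Poisson-distributed positions with
mean `density × field area`), rays (near-vertical dark lines at jittered
spacing), and additive Gaussian noise, clipped to [0, 1]. Ring-porous
classes additionally draw a near-contiguous band of abruptly larger
earlywood vessels at every ring boundary and use a markedly stronger
earlywood/latewood contrast (0.30 vs 0.10 amplitude) — the classic
macroscopic distinction from diffuse-porous wood, where ring boundaries
are visible but subtle. All physical parameters
are in real units (µm, mm, vessels/mm²) and convert to pixels at render
time. The desk-scale default is 512 × 512 px at 12.4 µm/px, the same
6.35 mm field of view as full-scale capture; 256 × 256 px (3.17 mm) is used
throughout the test suite, and full-scale 2048 × 2048 is supported.

Within-specimen correlation is produced by `SpecimenEffects`: one
multiplicative lognormal jitter (sd 0.15 by default) per texture parameter
per specimen, shared by all of its images. This is what makes
specimen-exclusive splitting matter in the synthetic world, and the
leakage experiment raises the sd to 0.4 to make the effect strong.

`example_class_specs(n)` places demo classes on binary contrasts of four
texture axes — background grey 0.35/0.85, vessel density 6/48 mm⁻²,
ring width 0.4/1.0 mm, ray geometry (width 22/38 µm, spacing 90/260 µm) —
and sets porosity to the parity of those bits. The parity axis guarantees
any two classes differ on at least two axes, and porosity is categorical,
immune to the lognormal jitter, so no single tail jitter draw can carry a
specimen across a class boundary. Every metric contrast exceeds roughly
three standard deviations of the between-specimen jitter difference
(e.g. grey: ln(0.85/0.35) ≈ 0.89 ≈ 4.2 × (0.15·√2)), which is the
package's working definition of "well-separated". The high ring-width
extreme is kept below the desk-scale patch height so a ring-porous patch
always contains at least one earlywood band — wide-ringed ring-porous wood
whose patches show only latewood is exactly the spatial-heterogeneity trap
that motivates restricting the scope to diffuse-porous taxa. A
`separation` parameter shrinks all contrasts toward the axis midpoints
(and below 0.5 disables the porosity parity) to create deliberately
overlapping classes for the leakage demonstration.

What the simulator does *not* model: axial parenchyma patterns, sanding
artifacts, dust, illumination gradients, pith/bark orientation, or any
measured anatomy of real taxa — its parameters are invented. Passing tests
therefore demonstrate pipeline correctness (splitting, training mechanics,
voting, bookkeeping) and the qualitative leakage phenomenon, not
performance on real wood.

## Experiment sizes and numerical choices

The end-to-end smoke experiment is 6 well-separated classes × 6 specimens
× 3 images at 256 × 256 px with 3-fold specimen-exclusive CV — about a
hundred training steps per fold and a few minutes on one CPU core — and is
expected to reach ≥ 0.90 pooled specimen top-1 accuracy. The leakage
experiment uses 3 classes at `separation` 0.3 with effect sd 0.4,
4 specimens × 4 images, k = 2, 5 seeds. Batch-norm layers use momentum 0.1
and eps 1e-5; Adam uses β₂ = 0.99 and eps 1e-6; convolutions carry no bias
(batchnorm follows each); weights are He-initialised from the model seed.
Patches are standardised as (x − 0.5)/0.25. Max-pool gradient ties split
the gradient equally; the area downsampler requires the target dims to
divide the patch dims. Degenerate augmentation configs (zero probabilities
and cutout count) are exact no-ops.

## Known limitations

The lognormal specimen jitter has heavy enough tails that a rare (~3σ)
draw can still produce a genuinely ambiguous specimen; the smoke
experiment's accuracy floor is therefore probabilistic, not guaranteed.
The NumPy engine is single-threaded per operation, adequate at desk scale
but not intended for full-scale (2048 px, ResNet-34) training. Checkpoints
store raw arrays with the model config embedded; they are not portable to
other frameworks. Type-1/2/3 labels require wood-anatomy expertise and are
never computed.
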