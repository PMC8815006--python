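# woodid

Field-deployable wood identification screens timber along the forest
products value chain — verifying species claims, flagging fraud, and
supporting legality enforcement — but wood-anatomy experts are scarce.
`woodid` implements a computer-vision identification (CVWID) pipeline for
North American **diffuse-porous hardwoods** from transverse-surface macro
images (6.35 mm × 6.35 mm of sanded end-grain): a 22-class label space
built on macroscopic anatomical similarity, patch-based CNN training with a
two-stage transfer schedule, **specimen-exclusive** stratified k-fold
cross-validation, specimen-level top-1/top-2 voting, and a source/sink
decomposition of the confusion matrix with typed misclassification tables.

Real xylarium image collections are access-restricted, so the package
includes a procedural wood-texture simulator (vessels, rays, growth rings,
ring-porous earlywood bands, per-specimen random effects) that makes the
entire pipeline reproducible and testable with no external data.

## The method in brief

- **Label space.** 18 genera map one-to-one to genus labels; *Acer* splits
  into `AcerH` (*A. saccharum*) and `AcerS`; *Prunus serotina* is its own
  class; Crataegus/Malus/other Prunus/Pyrus/Sorbus collapse into
  `Fruitwood` — 22 classes.
- **Model.** A convolutional backbone (compact 4-block CNN at desk scale;
  ResNet-34-style for full scale) feeds a custom head:
  `concat(global-avg-pool, global-max-pool)` (length 2C; 1024 for
  ResNet-34) → batchnorm → dropout 0.5 → FC(512) → ReLU → batchnorm →
  dropout 0.25 → FC(n_classes) → softmax. Implemented, with its optimiser
  and backprop, in pure NumPy.
- **Training.** Mini-batches of 16 random 2048 × 768 patches (one per
  image), downsampled 4× and augmented (flips, ±5° rotation, cutout).
  Stage 1 freezes the backbone and trains the head; stage 2 fine-tunes
  everything. Adam with two-phase simultaneous cosine annealing of the
  learning rate and momentum.
- **Evaluation.** Folds are stratified by label and mutually exclusive at
  the *specimen* level. Up to 5 images per specimen (fixed a priori) vote:
  top-1 = plurality of image argmaxes, top-2 = equally weighted votes of
  each image's two best classes.
- **Error anatomy.** Per class, `source` = off-diagonal row sum (its
  specimens misclassified), `sink` = off-diagonal column sum
  (misclassifications it attracts); Σsource = Σsink = total errors. Each
  misclassified specimen carries a human-assigned Type 1/2/3 label (read
  from a file, never computed); Types 1 and 3 are mutually exclusive within
  a class pair.

## Worked example

```python
import tempfile
from woodid import (
    ModelConfig, TrainConfig, build_folds, example_class_specs,
    generate_dataset, load_manifest, run_cross_validation,
)
from woodid.patches import PatchConfig

tmp = tempfile.mkdtemp()
manifest = generate_dataset(
    example_class_specs(6), specimens_per_class=6, images_per_specimen=3,
    out_dir=tmp, seed=1, size_px=(256, 256),
)
records = load_manifest(manifest)                  # 36 specimens, 108 images
labels = sorted({r.class_label for r in records})
plan = build_folds(records, k=3, seed=1)           # specimen-exclusive folds
res = run_cross_validation(
    records, plan,
    ModelConfig(backbone="compact_cnn", n_classes=6),
    TrainConfig(epochs_stage1=10, epochs_stage2=60, lr_max=3e-3, seed=1),
    PatchConfig.desk_scale(256, 256), labels, images_root=tmp,
)
print(f"pooled top-1 {res.top1_accuracy:.3f}  top-2 {res.top2_accuracy:.3f}")
print(res.confusion.to_frame())
```

prints (about three minutes on one CPU core):

```
pooled top-1 1.000  top-2 1.000
         Class00  Class01  Class02  Class03  Class04  Class05
Class00        6        0        0        0        0        0
Class01        0        6        0        0        0        0
Class02        0        0        6        0        0        0
Class03        0        0        0        6        0        0
Class04        0        0        0        0        6        0
Class05        0        0        0        0        0        6
```

Each row is a true class of 6 specimens and the diagonal holds correct
specimen-level calls: at this seed all 36 held-out specimens are identified
correctly. Across seeds the pooled top-1 accuracy typically falls between
0.92 and 1.00, with the rare errors landing in anatomically adjacent
synthetic classes; top-2 accuracy (true class among the two voted classes)
is never below top-1.

The same stages are scriptable from the shell:

```sh
woodid simulate --config cfg.yaml --out data --seed 1
woodid split    --manifest data/manifest.csv --k 5 --seed 1 --out folds.csv
woodid train    --manifest data/manifest.csv --folds folds.csv \
                --holdout-fold 0 --config cfg.yaml --out model.npz
woodid evaluate --model model.npz --manifest data/manifest.csv --out results/
woodid analyze  --confusion results/confusion.csv --ledger ledger.csv \
                --manifest data/manifest.csv --out tables/
```

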