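"""Specimen-level voting, cross-validation, and holdout evaluation.

A trained model scores individual images, but the deployable quantity is a
specimen-level call. The top-1 call is the plurality of the image-level
argmax classes; the top-2 call gives every image one vote for each of its
two highest-scoring classes and returns the two classes with the most
votes. A specimen counts as top-2 correct when its true class is either
member of that pair. Ties are broken by larger summed score across the
specimen's images, then lexicographic label order.

Evaluation uses at most the first five images of a specimen (in manifest
order), a cap fixed before any evaluation is run.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .dataset import FoldPlan, SpecimenRecord, build_folds
from .model import (
    ModelConfig, TrainConfig, WoodNet, build_model, load_image,
    predict_image_scores, train_two_stage,
)
from .patches import PatchConfig

__all__ = [
    "ImagePrediction", "SpecimenPrediction", "ConfusionMatrix",
    "specimen_top1", "specimen_top2", "cap_images", "predict_specimen",
    "run_cross_validation", "evaluate_holdout", "CrossValidationResult",
    "compare_split_strategies",
]

DEFAULT_MAX_IMAGES = 5


@dataclasses.dataclass(frozen=True)
class ImagePrediction:
    """Score vector for one image (non-negative, sums to one)."""

    image_path: str
    specimen_id: str
    scores: np.ndarray  # length n_classes
    class_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 1 or len(s) != len(self.class_labels):
            raise ValueError("scores must be one value per class")
        if (s < 0).any() or abs(s.sum() - 1.0) > 1e-5:
            raise ValueError("scores must be a normalised distribution")
        object.__setattr__(self, "scores", s)

    @property
    def argmax_class(self) -> str:
        return self.class_labels[int(np.argmax(self.scores))]

    def top2_classes(self) -> tuple[str, str]:
        order = np.argsort(-self.scores, kind="stable")
        return self.class_labels[order[0]], self.class_labels[order[1]]


@dataclasses.dataclass(frozen=True)
class SpecimenPrediction:
    specimen_id: str
    true_class: str
    top1: str
    top2: tuple[str, str]
    n_images_used: int

    @property
    def top1_correct(self) -> bool:
        return self.top1 == self.true_class

    @property
    def top2_correct(self) -> bool:
        return self.true_class in self.top2


def _check_same_specimen(preds: Sequence[ImagePrediction]) -> None:
    if not preds:
        raise ValueError("need at least one image prediction")
    if len({p.specimen_id for p in preds}) != 1:
        raise ValueError("predictions span multiple specimens")


def _ranked(candidates: Counter, summed: dict[str, float]) -> list[str]:
    # votes, then summed score, then label order
    return sorted(
        candidates, key=lambda c: (-candidates[c], -summed.get(c, 0.0), c)
    )


def specimen_top1(preds: Sequence[ImagePrediction]) -> str:
    """Plurality vote over image-level argmax classes."""
    _check_same_specimen(preds)
    votes = Counter(p.argmax_class for p in preds)
    summed: dict[str, float] = {}
    for p in preds:
        for c, s in zip(p.class_labels, p.scores):
            summed[c] = summed.get(c, 0.0) + float(s)
    return _ranked(votes, summed)[0]


def specimen_top2(preds: Sequence[ImagePrediction]) -> tuple[str, str]:
    """Equally weighted voting over each image's two highest-scoring classes."""
    _check_same_specimen(preds)
    if len(preds[0].class_labels) < 2:
        raise ValueError("top-2 voting needs at least two classes")
    votes: Counter = Counter()
    for p in preds:
        votes.update(p.top2_classes())
    summed: dict[str, float] = {}
    for p in preds:
        for c, s in zip(p.class_labels, p.scores):
            summed[c] = summed.get(c, 0.0) + float(s)
    ranked = _ranked(votes, summed)
    return ranked[0], ranked[1]


def cap_images(record: SpecimenRecord, max_n: int = DEFAULT_MAX_IMAGES) -> tuple[str, ...]:
    """First ``max_n`` images in manifest order (fixed a priori, not tuned)."""
    if max_n < 1:
        raise ValueError("max_n must be at least 1")
    return record.image_paths[:max_n]


# ---------------------------------------------------------------------------
# Confusion matrix


class ConfusionMatrix:
    """Square specimen-count table indexed by (true class, predicted class)."""

    def __init__(self, class_labels: Sequence[str], counts: np.ndarray | None = None):
        self.class_labels = tuple(class_labels)
        n = len(self.class_labels)
        self.counts = (
            np.zeros((n, n), dtype=int) if counts is None else np.asarray(counts, dtype=int)
        )
        if self.counts.shape != (n, n):
            raise ValueError("counts must be square over the class labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def add(self, true_class: str, predicted_class: str, n: int = 1) -> None:
        i = self.class_labels.index(true_class)
        j = self.class_labels.index(predicted_class)
        self.counts[i, j] += n

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))

    def accuracy(self) -> float:
        return self.trace / self.total if self.total else float("nan")

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.class_labels), columns=list(self.class_labels)
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="true\\predicted")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConfusionMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(tuple(df.columns), df.to_numpy())

    @classmethod
    def from_predictions(
        cls, preds: Sequence[SpecimenPrediction], class_labels: Sequence[str]
    ) -> "ConfusionMatrix":
        cm = cls(class_labels)
        for p in preds:
            cm.add(p.true_class, p.top1)
        return cm


# ---------------------------------------------------------------------------
# Model-driven prediction


def predict_specimen(
    model: WoodNet,
    record: SpecimenRecord,
    patch_cfg: PatchConfig,
    class_labels: Sequence[str],
    max_images: int = DEFAULT_MAX_IMAGES,
    image_loader: Callable[[str], np.ndarray] | None = None,
) -> tuple[SpecimenPrediction, list[ImagePrediction]]:
    loader = image_loader or load_image
    img_preds = []
    for path in cap_images(record, max_images):
        scores = predict_image_scores(model, loader(path), patch_cfg)
        img_preds.append(
            ImagePrediction(
                image_path=path,
                specimen_id=record.specimen_id,
                scores=scores,
                class_labels=tuple(class_labels),
            )
        )
    pred = SpecimenPrediction(
        specimen_id=record.specimen_id,
        true_class=record.class_label,
        top1=specimen_top1(img_preds),
        top2=specimen_top2(img_preds),
        n_images_used=len(img_preds),
    )
    return pred, img_preds


@dataclasses.dataclass
class CrossValidationResult:
    models: list[WoodNet]
    predictions: list[SpecimenPrediction]
    confusion: ConfusionMatrix
    top1_accuracy: float
    top2_accuracy: float
    loss_logs: list[pd.DataFrame]


def _make_loader(images_root, image_arrays):
    root = Path(images_root) if images_root else None
    cache: dict[str, np.ndarray] = {}

    def loader(path: str) -> np.ndarray:
        if image_arrays is not None and path in image_arrays:
            return image_arrays[path]
        if path not in cache:
            cache[path] = load_image(root / path if root else path)
        return cache[path]

    return loader


def run_cross_validation(
    records: Sequence[SpecimenRecord],
    fold_plan: FoldPlan,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    patch_cfg: PatchConfig,
    class_labels: Sequence[str],
    images_root: str | Path | None = None,
    image_arrays: dict[str, np.ndarray] | None = None,
    max_images: int = DEFAULT_MAX_IMAGES,
) -> CrossValidationResult:
    """Train one model per fold and pool held-out specimen predictions.

    For fold i the model trains on the specimens of the other k−1 folds and
    predicts the specimens of fold i, so every specimen is predicted exactly
    once; the pooled predictions give the accumulated confusion matrix and
    top-1/top-2 accuracies.
    """
    known = set(fold_plan.assignment)
    ids = [r.specimen_id for r in records]
    unknown = known.symmetric_difference(ids)
    if unknown:
        raise ValueError(f"fold plan and manifest disagree on specimens: {sorted(unknown)}")
    loader = _make_loader(images_root, image_arrays)
    models, preds, logs = [], [], []
    for fold in range(fold_plan.k):
        train_recs = [r for r in records if fold_plan.fold_of(r.specimen_id) != fold]
        test_recs = [r for r in records if fold_plan.fold_of(r.specimen_id) == fold]
        model = build_model(model_cfg, seed=train_cfg.seed + fold)
        fold_cfg = dataclasses.replace(train_cfg, seed=train_cfg.seed + fold)
        model, log = train_two_stage(
            model, train_recs, class_labels, fold_cfg, patch_cfg,
            images_root=images_root, image_arrays=image_arrays,
        )
        for rec in test_recs:
            pred, _ = predict_specimen(
                model, rec, patch_cfg, class_labels, max_images, loader
            )
            preds.append(pred)
        models.append(model)
        logs.append(log)
    cm = ConfusionMatrix.from_predictions(preds, class_labels)
    top1 = float(np.mean([p.top1_correct for p in preds]))
    top2 = float(np.mean([p.top2_correct for p in preds]))
    return CrossValidationResult(
        models=models, predictions=preds, confusion=cm,
        top1_accuracy=top1, top2_accuracy=top2, loss_logs=logs,
    )


def evaluate_holdout(
    models: Sequence[WoodNet],
    holdout_records: Sequence[SpecimenRecord],
    patch_cfg: PatchConfig,
    class_labels: Sequence[str],
    images_root: str | Path | None = None,
    image_arrays: dict[str, np.ndarray] | None = None,
    max_images: int = DEFAULT_MAX_IMAGES,
) -> dict:
    """Evaluate one or more trained models on an independent specimen set.

    With several models (e.g. the k fold models), top-1/top-2 accuracies are
    reported as mean and standard deviation across models; the confusion
    matrix is reported for a single model only (the first).
    """
    if not holdout_records:
        raise ValueError("holdout set is empty")
    if not models:
        raise ValueError("need at least one model")
    loader = _make_loader(images_root, image_arrays)
    top1s, top2s = [], []
    first_preds: list[SpecimenPrediction] = []
    for mi, model in enumerate(models):
        preds = [
            predict_specimen(model, rec, patch_cfg, class_labels, max_images, loader)[0]
            for rec in holdout_records
        ]
        top1s.append(float(np.mean([p.top1_correct for p in preds])))
        top2s.append(float(np.mean([p.top2_correct for p in preds])))
        if mi == 0:
            first_preds = preds
    return {
        "top1_mean": float(np.mean(top1s)),
        "top1_sd": float(np.std(top1s, ddof=1)) if len(models) > 1 else 0.0,
        "top2_mean": float(np.mean(top2s)),
        "top2_sd": float(np.std(top2s, ddof=1)) if len(models) > 1 else 0.0,
        "per_model_top1": top1s,
        "per_model_top2": top2s,
        "confusion": ConfusionMatrix.from_predictions(first_preds, class_labels),
        "predictions": first_preds,
    }


# ---------------------------------------------------------------------------
# Leakage demonstration


def _image_level_records(records: Sequence[SpecimenRecord]) -> list[SpecimenRecord]:
    """Explode specimens so each image becomes its own pseudo-specimen.

    Splitting these ignores specimen identity — the leaky protocol the
    specimen-exclusive fold rule exists to prevent.
    """
    out = []
    for rec in records:
        for i, p in enumerate(rec.image_paths):
            out.append(
                dataclasses.replace(
                    rec,
                    specimen_id=f"{rec.specimen_id}#img{i}",
                    image_paths=(p,),
                )
            )
    return out


def _image_level_accuracy(result: CrossValidationResult) -> float:
    return float(np.mean([p.top1_correct for p in result.predictions]))


def compare_split_strategies(
    records: Sequence[SpecimenRecord],
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    patch_cfg: PatchConfig,
    class_labels: Sequence[str],
    k: int,
    seeds: Sequence[int],
    images_root: str | Path | None = None,
    image_arrays: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Image-level (leaky) vs specimen-level cross-validation accuracy.

    For each seed, runs k-fold cross-validation twice — once with specimen-
    exclusive folds and once with folds built over individual images — and
    reports the pooled image-level top-1 accuracy of each. With strong
    specimen effects the leaky protocol overstates accuracy, which is the
    rationale for specimen-exclusive folds.
    """
    rows = []
    per_image = _image_level_records(records)
    for seed in seeds:
        cfg = dataclasses.replace(train_cfg, seed=int(seed))
        # grouped arm: folds over specimens, inherited by their images, so
        # both arms train and are scored on identical per-image units
        spec_plan = build_folds(records, k, int(seed))
        inherited = FoldPlan(
            k=k,
            assignment={
                r.specimen_id: spec_plan.fold_of(r.specimen_id.split("#img")[0])
                for r in per_image
            },
            seed=int(seed),
        )
        grouped = run_cross_validation(
            per_image, inherited, model_cfg, cfg,
            patch_cfg, class_labels, images_root, image_arrays, max_images=1000,
        )
        leaky = run_cross_validation(
            per_image, build_folds(per_image, k, int(seed)), model_cfg, cfg,
            patch_cfg, class_labels, images_root, image_arrays, max_images=1000,
        )
        rows.append(
            {
                "seed": int(seed),
                "specimen_level_accuracy": _image_level_accuracy(grouped),
                "image_level_accuracy": _image_level_accuracy(leaky),
            }
        )
    return pd.DataFrame(rows)
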