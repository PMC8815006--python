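"""Patch extraction, downsampling, augmentation, and mini-batch assembly.

Training consumes random patches rather than whole images: a patch spanning
the full image width (2048 px at capture scale) and 768 rows is cut at a
random row offset, then area-average downsampled by 4× to 512 × 192 before
augmentation. The 2048-px extent runs along image columns; growth rings in
the renderer run along rows, so a full-width patch always crosses rays and
a random-row patch samples different ring positions.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = ["PatchConfig", "sample_patch", "center_patch", "augment", "make_minibatch"]


@dataclasses.dataclass(frozen=True)
class PatchConfig:
    patch_rows: int = 768
    patch_cols: int = 2048
    down_rows: int = 192
    down_cols: int = 512
    flip_h: float = 0.5
    flip_v: float = 0.5
    rotation_max_deg: float = 5.0
    cutout_count: int = 1
    cutout_size: tuple[int, int] = (48, 48)
    batch_size: int = 16

    def __post_init__(self) -> None:
        if self.patch_rows % self.down_rows or self.patch_cols % self.down_cols:
            raise ValueError(
                "downsampled dims must divide patch dims "
                f"({self.patch_rows}×{self.patch_cols} → {self.down_rows}×{self.down_cols})"
            )
        for p in (self.flip_h, self.flip_v):
            if not 0.0 <= p <= 1.0:
                raise ValueError("flip probabilities must lie in [0, 1]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")

    @classmethod
    def desk_scale(cls, image_rows: int = 256, image_cols: int = 256) -> "PatchConfig":
        """Patch geometry scaled to small synthetic images.

        Keeps the capture-scale patch proportions (full image width, 3/8 of
        the rows) but downsamples only 2× instead of 4×: desk-scale images
        are rendered at the capture pipeline's post-downsampling resolution
        already, so halving once keeps vessels above the pixel scale while
        capping compute.
        """
        pr = (3 * image_rows // 8) // 4 * 4
        return cls(
            patch_rows=pr,
            patch_cols=image_cols,
            down_rows=pr // 2,
            down_cols=image_cols // 2,
            cutout_size=(max(2, pr // 6), max(2, pr // 6)),
        )

    @classmethod
    def from_dict(cls, d: dict) -> "PatchConfig":
        d = dict(d)
        if "cutout_size" in d:
            d["cutout_size"] = tuple(d["cutout_size"])
        return cls(**d)


def _downsample_area(patch: np.ndarray, down_rows: int, down_cols: int) -> np.ndarray:
    r, c = patch.shape
    fr, fc = r // down_rows, c // down_cols
    return patch.reshape(down_rows, fr, down_cols, fc).mean(axis=(1, 3))


def sample_patch(
    image: np.ndarray, cfg: PatchConfig, rng: np.random.Generator
) -> np.ndarray:
    """Cut one random patch and downsample it by area averaging.

    The row offset is uniform on [0, rows − patch_rows]; when the patch
    spans the full image width the column offset is 0, otherwise it is
    uniform as well.
    """
    rows, cols = image.shape
    if rows < cfg.patch_rows or cols < cfg.patch_cols:
        raise ValueError(
            f"image {rows}×{cols} smaller than patch "
            f"{cfg.patch_rows}×{cfg.patch_cols}"
        )
    r0 = int(rng.integers(0, rows - cfg.patch_rows + 1))
    c0 = int(rng.integers(0, cols - cfg.patch_cols + 1))
    patch = image[r0 : r0 + cfg.patch_rows, c0 : c0 + cfg.patch_cols]
    return _downsample_area(patch, cfg.down_rows, cfg.down_cols)


def center_patch(image: np.ndarray, cfg: PatchConfig) -> np.ndarray:
    """Deterministic centred patch used at inference time."""
    rows, cols = image.shape
    if rows < cfg.patch_rows or cols < cfg.patch_cols:
        raise ValueError("image smaller than patch")
    r0 = (rows - cfg.patch_rows) // 2
    c0 = (cols - cfg.patch_cols) // 2
    patch = image[r0 : r0 + cfg.patch_rows, c0 : c0 + cfg.patch_cols]
    return _downsample_area(patch, cfg.down_rows, cfg.down_cols)


def augment(
    patch: np.ndarray, cfg: PatchConfig, rng: np.random.Generator
) -> np.ndarray:
    """Apply flips, a small rotation, then cutout; dims are unchanged.

    Rotation angle is uniform in ±rotation_max_deg with reflect padding;
    cutout fills axis-aligned rectangles with the patch mean.
    """
    out = patch
    if cfg.flip_h > 0 and rng.random() < cfg.flip_h:
        out = out[:, ::-1]
    if cfg.flip_v > 0 and rng.random() < cfg.flip_v:
        out = out[::-1, :]
    if cfg.rotation_max_deg > 0:
        angle = float(rng.uniform(-cfg.rotation_max_deg, cfg.rotation_max_deg))
        out = ndimage.rotate(
            out, angle, reshape=False, mode="reflect", order=1
        )
    if cfg.cutout_count > 0:
        out = np.array(out, copy=True)
        fill = float(out.mean())
        h = min(cfg.cutout_size[0], out.shape[0])
        w = min(cfg.cutout_size[1], out.shape[1])
        for _ in range(cfg.cutout_count):
            r0 = int(rng.integers(0, out.shape[0] - h + 1))
            c0 = int(rng.integers(0, out.shape[1] - w + 1))
            out[r0 : r0 + h, c0 : c0 + w] = fill
    return np.ascontiguousarray(out)


def make_minibatch(
    images: Sequence[np.ndarray],
    labels: Sequence[str],
    cfg: PatchConfig,
    rng: np.random.Generator,
    keys: Sequence[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Assemble one batch of augmented patches, one patch per distinct image.

    ``keys`` (e.g. image paths) are used for the distinctness check; with no
    keys, object identity is used. Returns (batch, labels) with batch shape
    (batch_size, down_rows, down_cols, 1).
    """
    if len(images) != cfg.batch_size:
        raise ValueError(
            f"need exactly batch_size={cfg.batch_size} images, got {len(images)}"
        )
    idents = list(keys) if keys is not None else [id(im) for im in images]
    if len(set(idents)) != len(idents):
        raise ValueError("duplicate image refs in mini-batch")
    batch = np.stack(
        [augment(sample_patch(im, cfg, rng), cfg, rng) for im in images]
    )
    return batch[..., None].astype(np.float32), list(labels)
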