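"""Procedural transverse-surface wood-texture simulator.

Generates specimen-grouped greyscale images whose structure mimics the
anatomical axes that drive macroscopic hardwood identification: vessels
(dark rounded pores at Poisson-distributed positions), rays (near-vertical
dark lines at jittered spacing), and growth rings (horizontal intensity
modulation; ring-porous classes additionally get a band of enlarged
earlywood vessels at every ring boundary). The model is deliberately simple
— ellipses, lines, and smooth ring profiles — because its job is to make
every downstream pipeline stage testable without access to protected
xylarium imagery, not to render botanically faithful wood.

Within-specimen correlation, the property that makes specimen-exclusive
cross-validation folds matter, is created by drawing one multiplicative
lognormal jitter per parameter per specimen: all images of a specimen share
those jitters and differ only through image-level randomness.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .dataset import SpecimenRecord, write_manifest

__all__ = [
    "TextureClassSpec",
    "SpecimenEffects",
    "render_image",
    "generate_specimen",
    "generate_dataset",
    "example_class_specs",
    "default_texture_bank",
    "DEFAULT_SIZE_PX",
    "DEFAULT_RESOLUTION_UM_PER_PX",
]

#: Desk-scale defaults: 512 px at 12.4 µm/px covers the same 6.35 mm field
#: of view as a 2048 px capture at 3.1 µm/px.
DEFAULT_SIZE_PX = (512, 512)
DEFAULT_RESOLUTION_UM_PER_PX = 12.4

_JITTERED_FIELDS = (
    "vessel_density",
    "vessel_diameter_mean",
    "earlywood_vessel_diameter_mean",
    "ray_width_mean",
    "ray_spacing_mean",
    "ring_width_mean",
    "background_grey_mean",
)


@dataclasses.dataclass(frozen=True)
class TextureClassSpec:
    """Texture parameters for one synthetic wood class.

    Physical parameters are in real units (µm, mm, vessels/mm²) and are
    converted to pixels at render time, so one spec renders consistently at
    any resolution.
    """

    class_label: str
    porosity: str = "diffuse"  # "diffuse" or "ring"
    vessel_density: float = 30.0  # vessels per mm²
    vessel_diameter_mean: float = 70.0  # µm
    vessel_diameter_sd: float = 12.0  # µm
    earlywood_vessel_diameter_mean: float = 180.0  # µm, ring porous only
    ray_width_mean: float = 30.0  # µm
    ray_spacing_mean: float = 180.0  # µm
    ring_width_mean: float = 1.2  # mm (radial growth rate)
    ring_width_sd: float = 0.25  # mm
    background_grey_mean: float = 0.62  # intensity in [0, 1]
    background_grey_sd: float = 0.03
    noise_sd: float = 0.02  # additive intensity noise

    def __post_init__(self) -> None:
        if self.porosity not in ("diffuse", "ring"):
            raise ValueError(f"porosity must be 'diffuse' or 'ring', got {self.porosity!r}")
        positive = (
            self.vessel_diameter_mean, self.ray_width_mean,
            self.ray_spacing_mean, self.ring_width_mean,
            self.earlywood_vessel_diameter_mean,
        )
        if any(v <= 0 for v in positive):
            raise ValueError(f"{self.class_label}: physical parameters must be positive")
        if self.vessel_density < 0 or self.noise_sd < 0:
            raise ValueError(f"{self.class_label}: rates and noise must be non-negative")
        if (
            self.porosity == "ring"
            and self.vessel_diameter_mean >= self.earlywood_vessel_diameter_mean
        ):
            raise ValueError(
                f"{self.class_label}: ring porosity needs earlywood vessels larger "
                "than the background vessel diameter"
            )
        if self.ray_width_mean >= self.ray_spacing_mean:
            raise ValueError(f"{self.class_label}: rays must be narrower than their spacing")


@dataclasses.dataclass(frozen=True)
class SpecimenEffects:
    """Per-specimen multiplicative jitters on the class texture parameters.

    One lognormal draw per parameter, shared by every image of the specimen.
    """

    multipliers: dict[str, float]
    seed: int

    @classmethod
    def draw(cls, seed: int, sd: float = 0.15) -> "SpecimenEffects":
        rng = np.random.default_rng(seed)
        mult = {
            f: float(np.exp(rng.normal(0.0, sd))) for f in _JITTERED_FIELDS
        }
        return cls(multipliers=mult, seed=seed)

    @classmethod
    def none(cls) -> "SpecimenEffects":
        return cls(multipliers={f: 1.0 for f in _JITTERED_FIELDS}, seed=-1)

    def apply(self, spec: TextureClassSpec) -> TextureClassSpec:
        updates = {}
        for f in _JITTERED_FIELDS:
            updates[f] = getattr(spec, f) * self.multipliers[f]
        # keep the ring-porosity ordering invariant under independent jitters
        if spec.porosity == "ring":
            updates["earlywood_vessel_diameter_mean"] = max(
                updates["earlywood_vessel_diameter_mean"],
                1.5 * updates["vessel_diameter_mean"],
            )
        updates["ray_spacing_mean"] = max(
            updates["ray_spacing_mean"], 1.5 * updates["ray_width_mean"]
        )
        updates["background_grey_mean"] = float(
            np.clip(updates["background_grey_mean"], 0.05, 0.95)
        )
        return dataclasses.replace(spec, **updates)


# ---------------------------------------------------------------------------
# Rendering


def _draw_vessel_at(img, y, x, d, aspect=1.0):
    rows, cols = img.shape
    ry, rx = (d / 2.0) * aspect, d / 2.0
    y0, y1 = int(max(0, y - ry - 1)), int(min(rows, y + ry + 2))
    x0, x1 = int(max(0, x - rx - 1)), int(min(cols, x + rx + 2))
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = ((yy - y) / max(ry, 0.5)) ** 2 + ((xx - x) / max(rx, 0.5)) ** 2 <= 1.0
    img[y0:y1, x0:x1][mask] *= 0.35  # lumina read dark on the surface


def _draw_vessels(img, rows, cols, n, diam_mean_px, diam_sd_px, rng, row_lo=0, row_hi=None):
    row_hi = rows if row_hi is None else row_hi
    if n <= 0 or row_hi <= row_lo:
        return
    ys = rng.uniform(row_lo, row_hi, size=n)
    xs = rng.uniform(0, cols, size=n)
    diams = np.clip(rng.normal(diam_mean_px, diam_sd_px, size=n), 1.0, None)
    # vessels are slightly elongated tangentially (across columns)
    aspect = rng.uniform(0.8, 1.0, size=n)
    for y, x, d, a in zip(ys, xs, diams, aspect):
        _draw_vessel_at(img, y, x, d, a)


def _ring_profile(rows, width_px_mean, width_px_sd, rng, contrast=0.12):
    """Smooth periodic darkening toward each ring boundary, variable widths.

    Returns (profile, boundary_rows). Boundary rows are where latewood ends.
    """
    boundaries = []
    r = -rng.uniform(0, width_px_mean)  # random phase
    while r < rows:
        w = max(0.2 * width_px_mean, rng.normal(width_px_mean, width_px_sd))
        r += w
        boundaries.append(r)
    profile = np.ones(rows)
    start = boundaries[0] - width_px_mean if boundaries else 0.0
    edges = [start] + boundaries
    row_idx = np.arange(rows)
    for a, b in zip(edges[:-1], edges[1:]):
        sel = (row_idx >= a) & (row_idx < b)
        if not sel.any():
            continue
        t = (row_idx[sel] - a) / max(b - a, 1.0)
        # latewood darkens toward the boundary
        profile[sel] = 1.0 - contrast * 0.5 * (1.0 - np.cos(2 * np.pi * t))
    return profile, np.array(boundaries)


def _draw_rays(img, rows, cols, width_px, spacing_px, rng):
    if spacing_px <= 0:
        return
    n = int(cols / spacing_px) + 2
    xs = (np.arange(n) + rng.uniform(-0.3, 0.3, size=n)) * spacing_px
    xs += rng.uniform(0, spacing_px)
    slopes = rng.normal(0.0, 0.02, size=n)  # near-vertical
    depth = rng.uniform(0.75, 0.9, size=n)
    w = max(1, int(round(width_px)))
    row_idx = np.arange(rows)
    for x0, m, d in zip(xs, slopes, depth):
        xline = (x0 + m * row_idx).astype(int)
        for off in range(w):
            xcol = xline + off
            ok = (xcol >= 0) & (xcol < cols)
            img[row_idx[ok], xcol[ok]] *= d


def render_image(
    spec: TextureClassSpec,
    effects: SpecimenEffects | None = None,
    size_px: tuple[int, int] = DEFAULT_SIZE_PX,
    resolution_um_per_px: float = DEFAULT_RESOLUTION_UM_PER_PX,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Render one greyscale transverse-surface image as float32 in [0, 1].

    Vessel count is Poisson with mean ``vessel_density × field area (mm²)``;
    ring-porous classes get an extra earlywood vessel band at each ring
    boundary. Deterministic given the rng seed.
    """
    rows, cols = size_px
    if rows < 256 or cols < 256:
        raise ValueError("image size must be at least 256×256 px")
    if resolution_um_per_px <= 0:
        raise ValueError("resolution must be positive")
    rng = np.random.default_rng(rng)
    if effects is None:
        effects = SpecimenEffects.none()
    p = effects.apply(spec)

    um = resolution_um_per_px
    area_mm2 = (rows * um / 1000.0) * (cols * um / 1000.0)
    img = np.full((rows, cols), p.background_grey_mean, dtype=np.float64)
    # low-frequency background mottle
    if p.background_grey_sd > 0:
        coarse = rng.normal(0.0, p.background_grey_sd, size=(8, 8))
        zoom = np.kron(coarse, np.ones((rows // 8 + 1, cols // 8 + 1)))
        img += zoom[:rows, :cols]

    ring_w_px = p.ring_width_mean * 1000.0 / um
    ring_sd_px = p.ring_width_sd * 1000.0 / um
    # ring-porous woods show markedly stronger earlywood/latewood contrast
    ring_contrast = 0.30 if p.porosity == "ring" else 0.10
    profile, boundaries = _ring_profile(
        rows, ring_w_px, ring_sd_px, rng, contrast=ring_contrast
    )
    img *= profile[:, None]

    # background (latewood/diffuse) vessels
    n_vessels = rng.poisson(p.vessel_density * area_mm2)
    _draw_vessels(
        img, rows, cols, n_vessels,
        p.vessel_diameter_mean / um, p.vessel_diameter_sd / um, rng,
    )
    if p.porosity == "ring":
        # earlywood pores form a near-contiguous band of abruptly larger
        # vessels at each ring boundary — the classic ring-porous look
        d_early = p.earlywood_vessel_diameter_mean / um
        step = 1.15 * d_early
        for b in boundaries:
            if b >= rows or b + d_early < 0:
                continue
            n_early = max(1, int(cols / step))
            xs = (np.arange(n_early) + 0.5 + rng.uniform(-0.2, 0.2, n_early)) * step
            ys = b + d_early / 2 + rng.uniform(-0.15, 0.15, n_early) * d_early
            diams = np.clip(
                rng.normal(d_early, 0.12 * d_early, n_early), 2.0, None
            )
            for x, y, dd in zip(xs, ys, diams):
                _draw_vessel_at(img, y, x, dd)


    _draw_rays(img, rows, cols, p.ray_width_mean / um, p.ray_spacing_mean / um, rng)

    if p.noise_sd > 0:
        img += rng.normal(0.0, p.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def expected_vessel_count(
    spec: TextureClassSpec,
    size_px: tuple[int, int] = DEFAULT_SIZE_PX,
    resolution_um_per_px: float = DEFAULT_RESOLUTION_UM_PER_PX,
) -> float:
    """Poisson mean of the background vessel count for a given field."""
    rows, cols = size_px
    area_mm2 = (rows * resolution_um_per_px / 1000.0) * (
        cols * resolution_um_per_px / 1000.0
    )
    return spec.vessel_density * area_mm2


# ---------------------------------------------------------------------------
# Specimen and dataset generation


def generate_specimen(
    spec: TextureClassSpec,
    n_images: int,
    seed: int,
    specimen_id: str | None = None,
    xylarium: str = "SYNw",
    size_px: tuple[int, int] = DEFAULT_SIZE_PX,
    resolution_um_per_px: float = DEFAULT_RESOLUTION_UM_PER_PX,
    effect_sd: float = 0.15,
) -> tuple[SpecimenRecord, list[np.ndarray]]:
    """Render all images of one synthetic specimen.

    One set of specimen effects is drawn from the seed and shared by every
    image; images differ only through image-level randomness.
    """
    if n_images < 1:
        raise ValueError("n_images must be at least 1")
    ss = np.random.SeedSequence(seed)
    effect_seed, *img_seeds = ss.spawn(n_images + 1)
    effects = SpecimenEffects.draw(
        int(effect_seed.generate_state(1)[0] % (2**31)), sd=effect_sd
    )
    images = [
        render_image(
            spec, effects, size_px, resolution_um_per_px,
            rng=np.random.default_rng(s),
        )
        for s in img_seeds
    ]
    sid = specimen_id or f"{spec.class_label}-{seed}"
    record = SpecimenRecord(
        specimen_id=sid,
        xylarium=xylarium,
        taxon=f"Synthetica {spec.class_label.lower()}",
        class_label=spec.class_label,
        image_paths=tuple(f"{sid}_{i:02d}.png" for i in range(n_images)),
    )
    return record, images


def generate_dataset(
    class_specs: Sequence[TextureClassSpec],
    specimens_per_class: int,
    images_per_specimen: int,
    out_dir: str | Path,
    seed: int,
    size_px: tuple[int, int] = DEFAULT_SIZE_PX,
    resolution_um_per_px: float = DEFAULT_RESOLUTION_UM_PER_PX,
    effect_sd: float = 0.15,
) -> Path:
    """Write a PNG image tree plus manifest CSV; returns the manifest path.

    Fully reproducible: the byte content of every file is a function of the
    configuration and the seed.
    """
    if len(class_specs) < 2:
        raise ValueError("need at least two classes")
    labels = [s.class_label for s in class_specs]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate class labels in config: {sorted(labels)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    records: list[SpecimenRecord] = []
    for spec, class_ss in zip(class_specs, ss.spawn(len(class_specs))):
        for j, spec_ss in enumerate(class_ss.spawn(specimens_per_class)):
            sid = f"{spec.class_label}-{j:03d}"
            rec, images = generate_specimen(
                spec, images_per_specimen,
                seed=int(spec_ss.generate_state(1)[0] % (2**31)),
                specimen_id=sid, size_px=size_px,
                resolution_um_per_px=resolution_um_per_px,
                effect_sd=effect_sd,
            )
            cdir = out_dir / spec.class_label
            cdir.mkdir(exist_ok=True)
            paths = []
            for name, img in zip(rec.image_paths, images):
                path = cdir / name
                Image.fromarray(
                    (img * 255).round().astype(np.uint8), mode="L"
                ).save(path)
                paths.append(str(path.relative_to(out_dir)))
            records.append(dataclasses.replace(rec, image_paths=tuple(paths)))
    manifest = out_dir / "manifest.csv"
    write_manifest(records, manifest, resolution_um_per_px)
    return manifest


def manifest_checksum(manifest_path: str | Path) -> str:
    """SHA-256 over the manifest and every image it references."""
    manifest_path = Path(manifest_path)
    h = hashlib.sha256(manifest_path.read_bytes())
    import pandas as pd

    df = pd.read_csv(manifest_path)
    for p in df["image_path"]:
        h.update(Path(manifest_path.parent, p).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Parameter banks


def example_class_specs(
    n_classes: int,
    separation: float = 1.0,
    noise_sd: float = 0.02,
) -> list[TextureClassSpec]:
    """Demo classes placed on binary contrasts of independent texture axes.

    Class ``i`` takes the low or high extreme of four texture axes
    (background grey, vessel density, growth-ring width, ray spacing)
    according to the bits of ``i``, and its porosity is the parity of those
    bits. The parity axis guarantees that any two classes differ on at
    least two independent axes, and porosity is categorical — immune to the
    lognormal specimen jitter — so no single unlucky specimen effect can
    move a specimen across a class boundary: well-separated by
    construction. ``separation`` in (0, 1] shrinks every contrast toward
    the axis midpoint and, below 0.5, also disables the porosity parity:
    small values give classes that overlap once specimen effects are added
    (useful for demonstrating split leakage). Beyond 16 classes the vessel
    diameter adds a continuous ramp so labels stay distinguishable.
    """
    if n_classes < 2:
        raise ValueError("need at least two classes")
    if not 0.0 < separation <= 1.0:
        raise ValueError("separation must lie in (0, 1]")

    def pick(lo: float, hi: float, bit: int) -> float:
        c = (lo + hi) / 2.0
        return c + (hi - c) * separation if bit else c - (c - lo) * separation

    specs = []
    for i in range(n_classes):
        bits = [(i >> a) & 1 for a in range(4)]
        parity = bits[0] ^ bits[1] ^ bits[2] ^ bits[3]
        ramp = (i // 16) / max((n_classes - 1) // 16, 1)
        specs.append(
            TextureClassSpec(
                class_label=f"Class{i:02d}",
                porosity="ring" if (parity and separation > 0.5) else "diffuse",
                vessel_density=pick(6.0, 48.0, bits[1]),
                vessel_diameter_mean=float(80.0 + 30.0 * ramp),
                vessel_diameter_sd=10.0,
                earlywood_vessel_diameter_mean=float(260.0 + 60.0 * ramp),
                ray_width_mean=pick(22.0, 38.0, bits[3]),
                ray_spacing_mean=pick(90.0, 260.0, bits[3]),
                # high extreme kept below the desk-scale patch height so a
                # ring-porous patch always contains an earlywood band
                ring_width_mean=pick(0.4, 1.0, bits[2]),
                ring_width_sd=0.15,
                background_grey_mean=pick(0.35, 0.85, bits[0]),
                background_grey_sd=0.02,
                noise_sd=noise_sd,
            )
        )
    return specs


def default_texture_bank() -> list[TextureClassSpec]:
    """One invented texture spec per class label of the default 22-class map.

    Parameters vary across labels along vessel, ray, and ring axes; they are
    artifact plumbing for pipeline testing, not measured wood anatomy.
    """
    from .dataset import default_taxon_map

    labels = default_taxon_map().labels()
    base = example_class_specs(len(labels))
    return [
        dataclasses.replace(spec, class_label=label)
        for spec, label in zip(base, labels)
    ]
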