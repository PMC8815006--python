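"""Specimen/image data model, label-space construction, and fold building.

Macroscopic wood identification is usually reliable only to genus level, so
the label space groups species into classes by macroscopic anatomical
similarity: 18 genera map one-to-one to genus labels, the maples split into
hard (``AcerH``, Acer saccharum) and soft (``AcerS``), Prunus serotina is its
own class, and the remaining fruitwood genera (Crataegus, Malus, Prunus,
Pyrus, Sorbus) collapse into ``Fruitwood`` — 22 classes in all.

The physical specimen — not the image — is the unit of cross-validation
splitting and of prediction, because images from one specimen share surface
preparation, growth history, and imaging session and therefore leak identity
information across an image-level split.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpecimenRecord",
    "TaxonClassMap",
    "FoldPlan",
    "ManifestError",
    "UnmappedTaxonError",
    "default_taxon_map",
    "assign_class_label",
    "count_classes",
    "load_manifest",
    "write_manifest",
    "build_folds",
    "field_of_view_mm",
]

MANIFEST_COLUMNS = [
    "specimen_id",
    "xylarium",
    "taxon",
    "class_label",
    "image_path",
    "resolution_um_per_px",
]

#: Genera that map one-to-one onto a genus-level class label.
ONE_TO_ONE_GENERA = (
    "Aesculus", "Alnus", "Arbutus", "Betula", "Carpinus", "Fagus",
    "Frangula", "Liquidambar", "Liriodendron", "Magnolia", "Nyssa",
    "Ostrya", "Oxydendrum", "Platanus", "Populus", "Rhamnus", "Salix",
    "Tilia",
)

#: Multi-genus fruitwood group (Prunus serotina is carved out by a species
#: override because it is anatomically distinct from the other fruitwoods).
FRUITWOOD_GENERA = ("Crataegus", "Malus", "Prunus", "Pyrus", "Sorbus")


class ManifestError(ValueError):
    """Raised for structurally invalid specimen manifests."""


class UnmappedTaxonError(KeyError):
    """Raised when a taxon resolves to no class label."""


@dataclasses.dataclass(frozen=True)
class SpecimenRecord:
    """One physical wood specimen: the unit of splitting and prediction."""

    specimen_id: str
    xylarium: str
    taxon: str
    class_label: str
    image_paths: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.image_paths) < 1:
            raise ManifestError(
                f"specimen {self.specimen_id!r} has no images"
            )

    @property
    def n_images(self) -> int:
        return len(self.image_paths)


@dataclasses.dataclass(frozen=True)
class TaxonClassMap:
    """Rules mapping taxon names to class labels.

    ``genus_rules`` maps a genus to a label; ``species_rules`` maps a full
    binomial to a label and takes precedence. Matching is case-insensitive
    on whitespace-normalised names.
    """

    genus_rules: Mapping[str, str]
    species_rules: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "genus_rules",
            {_norm(k): v for k, v in self.genus_rules.items()},
        )
        object.__setattr__(
            self, "species_rules",
            {_norm(k): v for k, v in self.species_rules.items()},
        )

    def labels(self) -> tuple[str, ...]:
        """Distinct class labels reachable from the map, sorted."""
        reachable = set(self.genus_rules.values())
        reachable.update(self.species_rules.values())
        return tuple(sorted(reachable))

    @classmethod
    def from_csv(cls, path: str | Path) -> "TaxonClassMap":
        """Load a two-column CSV (taxon_or_genus, class_label).

        Rows whose first column contains whitespace are treated as species
        overrides; single-word rows are genus rules.
        """
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ManifestError(f"{path}: need two columns (taxon, label)")
        genus, species = {}, {}
        for taxon, label in zip(df.iloc[:, 0], df.iloc[:, 1]):
            taxon = str(taxon).strip()
            (species if " " in taxon else genus)[taxon] = str(label).strip()
        return cls(genus_rules=genus, species_rules=species)

    def to_csv(self, path: str | Path) -> None:
        rows = [(k.capitalize(), v) for k, v in sorted(self.genus_rules.items())]
        rows += [
            (k.capitalize(), v) for k, v in sorted(self.species_rules.items())
        ]
        pd.DataFrame(rows, columns=["taxon_or_genus", "class_label"]).to_csv(
            path, index=False
        )


def _norm(name: str) -> str:
    return " ".join(name.split()).lower()


def default_taxon_map() -> TaxonClassMap:
    """The shipped 22-class map covering all main-text taxa.

    User extension files (``TaxonClassMap.from_csv``) may add further taxa.
    """
    genus = {g: g for g in ONE_TO_ONE_GENERA}
    genus.update({g: "Fruitwood" for g in FRUITWOOD_GENERA})
    genus["Acer"] = "AcerS"  # soft maples are the genus default
    species = {
        "Acer saccharum": "AcerH",  # hard maple: macroscopically wider rays
        "Prunus serotina": "Prunus",
    }
    return TaxonClassMap(genus_rules=genus, species_rules=species)


def assign_class_label(taxon: str, class_map: TaxonClassMap) -> str:
    """Resolve a taxon to its class label.

    Species-level overrides take precedence over genus rules; matching is
    case-insensitive on normalised whitespace.
    """
    if not taxon or not taxon.strip():
        raise ValueError("taxon must be non-empty")
    key = _norm(taxon)
    if key in class_map.species_rules:
        return class_map.species_rules[key]
    genus = key.split()[0]
    if genus in class_map.genus_rules:
        return class_map.genus_rules[genus]
    raise UnmappedTaxonError(f"taxon {taxon!r} is not covered by the class map")


def count_classes(class_map: TaxonClassMap) -> int:
    """Number of distinct class labels reachable from the map."""
    return len(class_map.labels())


def field_of_view_mm(pixels: int, resolution_um_per_px: float) -> float:
    """Linear field of view in mm for a square sensor dimension.

    2048 px at 3.1 µm/px shows 6.35 mm of tissue; the desk-scale default of
    512 px at 12.4 µm/px preserves that field of view.
    """
    if pixels <= 0 or resolution_um_per_px <= 0:
        raise ValueError("pixels and resolution must be positive")
    return pixels * resolution_um_per_px / 1000.0


# ---------------------------------------------------------------------------
# Manifest I/O


def load_manifest(path: str | Path) -> list[SpecimenRecord]:
    """Read a manifest CSV and group rows into specimen records.

    One CSV row per image. Image order within a specimen is preserved as
    written (it defines the "first n images" used by the evaluation cap).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"specimen_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns and c != "resolution_um_per_px"]
    if missing:
        raise ManifestError(f"{path}: missing columns {missing}")
    dup = df.duplicated(subset=["specimen_id", "image_path"])
    if dup.any():
        raise ManifestError(
            f"{path}: duplicate (specimen_id, image_path) rows: "
            f"{df.loc[dup, 'image_path'].tolist()}"
        )
    records: list[SpecimenRecord] = []
    for sid, grp in df.groupby("specimen_id", sort=False):
        for col in ("xylarium", "taxon", "class_label"):
            if grp[col].nunique() != 1:
                raise ManifestError(
                    f"{path}: specimen {sid!r} has inconsistent {col!r} values"
                )
        records.append(
            SpecimenRecord(
                specimen_id=str(sid),
                xylarium=str(grp["xylarium"].iloc[0]),
                taxon=str(grp["taxon"].iloc[0]),
                class_label=str(grp["class_label"].iloc[0]),
                image_paths=tuple(grp["image_path"].astype(str)),
            )
        )
    return records


def write_manifest(
    records: Iterable[SpecimenRecord],
    path: str | Path,
    resolution_um_per_px: float = 12.4,
) -> None:
    rows = []
    for rec in records:
        for p in rec.image_paths:
            rows.append(
                (rec.specimen_id, rec.xylarium, rec.taxon, rec.class_label,
                 p, resolution_um_per_px)
            )
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Fold construction


@dataclasses.dataclass(frozen=True)
class FoldPlan:
    """Assignment of specimens to k mutually exclusive, stratified folds."""

    k: int
    assignment: Mapping[str, int]
    seed: int

    def fold_of(self, specimen_id: str) -> int:
        return self.assignment[specimen_id]

    def members(self, fold: int) -> tuple[str, ...]:
        return tuple(s for s, f in self.assignment.items() if f == fold)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.assignment.items()), columns=["specimen_id", "fold"]
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, seed: int = -1) -> "FoldPlan":
        df = pd.read_csv(path, dtype={"specimen_id": str})
        assignment = dict(zip(df["specimen_id"], df["fold"].astype(int)))
        return cls(k=int(df["fold"].max()) + 1, assignment=assignment, seed=seed)


def build_folds(
    specimens: Sequence[SpecimenRecord], k: int, seed: int
) -> FoldPlan:
    """Label-stratified, specimen-exclusive k-fold assignment.

    Per class, specimens are shuffled with the seed and dealt round-robin to
    folds starting at a seed-chosen offset, so per-class fold counts differ
    by at most one wherever class sizes permit. Every image of a specimen
    follows its specimen into a single fold.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > len(specimens):
        raise ValueError(
            f"k={k} exceeds the number of specimens ({len(specimens)})"
        )
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[str]] = defaultdict(list)
    for rec in specimens:
        by_class[rec.class_label].append(rec.specimen_id)

    assignment: dict[str, int] = {}
    for label in sorted(by_class):
        ids = sorted(by_class[label])
        rng.shuffle(ids)
        offset = int(rng.integers(k))
        for i, sid in enumerate(ids):
            assignment[sid] = (offset + i) % k

    # The deal can leave a fold empty only when k exceeds every class size;
    # repair by pulling one specimen out of the fullest fold.
    counts = np.bincount(list(assignment.values()), minlength=k)
    for empty in np.flatnonzero(counts == 0):
        donor = int(np.argmax(counts))
        sid = next(s for s, f in assignment.items() if f == donor)
        assignment[sid] = int(empty)
        counts[donor] -= 1
        counts[empty] += 1
    return FoldPlan(k=k, assignment=assignment, seed=seed)
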