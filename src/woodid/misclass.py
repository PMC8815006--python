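"""Source/sink decomposition of the confusion matrix and the typed
misclassification ledger.

Off-diagonal confusion-matrix cells are misclassifications and can be read
two ways per class: *source* misclassifications are a class's own specimens
wrongly predicted as something else (off-diagonal row sum), while *sink*
misclassifications are wrong predictions the class draws in from others
(off-diagonal column sum). Both views conserve the total: the sources and
the sinks each sum to the number of misclassified specimens.

Each misclassified specimen additionally carries a type assigned by a human
wood anatomist — never computed here:

* Type 1 — the true and predicted classes are anatomically consistent and
  the specimen is typical; an error a human field inspector might make.
* Type 2 — the specimen is atypical for its taxon.
* Type 3 — the classes are anatomically disparate; an error a human
  identifier would not be expected to make.

Typing is per specimen, so within one (true, predicted) class pair Types 1
and 3 are mutually exclusive while every other combination may co-occur.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .evaluation import ConfusionMatrix

__all__ = [
    "MisclassLedger",
    "source_sink_counts",
    "validate_ledger",
    "type_proportion_table",
    "classwise_table",
]

TYPES = (1, 2, 3)


@dataclasses.dataclass(frozen=True)
class MisclassLedger:
    """One row per misclassified specimen, plus the population it came from.

    ``class_sizes`` maps each class label to its total specimen count in the
    evaluated set; ``n_total_specimens`` is the evaluated-set size (row sums
    of the confusion matrix).
    """

    rows: pd.DataFrame  # columns: specimen_id, true_class, predicted_class, mtype
    n_total_specimens: int
    class_sizes: Mapping[str, int]

    REQUIRED = ("specimen_id", "true_class", "predicted_class", "mtype")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.rows, columns=list(self.REQUIRED)).copy()
        df["mtype"] = df["mtype"].astype(int)
        if not df["mtype"].isin(TYPES).all():
            raise ValueError("mtype must be 1, 2, or 3")
        if (df["true_class"] == df["predicted_class"]).any():
            raise ValueError("ledger rows must have true_class != predicted_class")
        if df["specimen_id"].duplicated().any():
            raise ValueError("each specimen may appear at most once in the ledger")
        if len(df) > self.n_total_specimens:
            raise ValueError("more ledger rows than specimens evaluated")
        object.__setattr__(self, "rows", df)

    def __len__(self) -> int:
        return len(self.rows)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        n_total_specimens: int,
        class_sizes: Mapping[str, int],
    ) -> "MisclassLedger":
        return cls(pd.read_csv(path), n_total_specimens, class_sizes)

    def to_csv(self, path: str | Path) -> None:
        self.rows.to_csv(path, index=False)


def source_sink_counts(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class source and sink misclassification counts.

    source = row sum − diagonal; sink = column sum − diagonal. Both columns
    sum to the total number of misclassified specimens.
    """
    counts = np.asarray(cm.counts)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError(f"confusion matrix must be square, got {counts.shape}")
    diag = np.diag(counts)
    return pd.DataFrame(
        {
            "source": counts.sum(axis=1) - diag,
            "sink": counts.sum(axis=0) - diag,
        },
        index=list(cm.class_labels),
    )


def validate_ledger(ledger: MisclassLedger, cm: ConfusionMatrix) -> list[str]:
    """Check a ledger against its confusion matrix; returns violations.

    An empty list means the ledger is consistent: its row count equals the
    off-diagonal total, its per-(true, predicted) counts equal the matrix
    cells, and no class pair mixes Type 1 with Type 3.
    """
    violations: list[str] = []
    labels = set(cm.class_labels)
    bad = set(ledger.rows["true_class"]) | set(ledger.rows["predicted_class"])
    if not bad <= labels:
        violations.append(f"unknown classes in ledger: {sorted(bad - labels)}")
        return violations

    off_total = cm.total - cm.trace
    if len(ledger) != off_total:
        violations.append(
            f"ledger has {len(ledger)} rows but the confusion matrix has "
            f"{off_total} off-diagonal specimens"
        )
    cell_counts = ledger.rows.groupby(["true_class", "predicted_class"]).size()
    for i, t in enumerate(cm.class_labels):
        for j, p in enumerate(cm.class_labels):
            if i == j:
                continue
            expected = int(cm.counts[i, j])
            got = int(cell_counts.get((t, p), 0))
            if expected != got:
                violations.append(
                    f"cell ({t} → {p}): ledger has {got} rows, matrix has {expected}"
                )
    for (t, p), grp in ledger.rows.groupby(["true_class", "predicted_class"]):
        types = set(grp["mtype"])
        if {1, 3} <= types:
            violations.append(
                f"pair ({t} → {p}) mixes Type 1 and Type 3, which are mutually exclusive"
            )
    return violations


def type_proportion_table(ledger: MisclassLedger) -> pd.DataFrame:
    """Counts and shares of misclassified specimens by type.

    ``share_of_misclassified`` sums to 1 over the three types (when the
    ledger is non-empty); ``share_of_all`` uses the full evaluated specimen
    count as denominator, so the Total row gives the overall
    misclassification rate.
    """
    n_mis = len(ledger)
    n_all = ledger.n_total_specimens
    counts = {t: int((ledger.rows["mtype"] == t).sum()) for t in TYPES}
    rows = []
    for t in TYPES:
        rows.append(
            {
                "mtype": f"Type {t}",
                "count": counts[t],
                "share_of_misclassified": counts[t] / n_mis if n_mis else 0.0,
                "share_of_all": counts[t] / n_all if n_all else 0.0,
            }
        )
    rows.append(
        {
            "mtype": "Total",
            "count": n_mis,
            "share_of_misclassified": 1.0 if n_mis else 0.0,
            "share_of_all": n_mis / n_all if n_all else 0.0,
        }
    )
    return pd.DataFrame(rows).set_index("mtype")


def classwise_table(ledger: MisclassLedger, round_to: int | None = None) -> pd.DataFrame:
    """Per-class source and sink proportions, split by type.

    Source proportions divide a class's misclassified-specimen counts by
    that class's specimen count; sink proportions divide the wrong
    predictions a class draws by the total number of misclassified
    specimens. ``round_to`` rounds for report output (totals are computed
    from unrounded values first); machine output keeps zeros where reports
    would leave cells blank.
    """
    n_mis = len(ledger)
    classes = sorted(ledger.class_sizes)
    src = ledger.rows.groupby(["true_class", "mtype"]).size()
    snk = ledger.rows.groupby(["predicted_class", "mtype"]).size()
    rows = []
    for c in classes:
        size = ledger.class_sizes[c]
        if size == 0 and any(src.get((c, t), 0) for t in TYPES):
            raise ValueError(f"class {c!r} has size 0 but source misclassifications")
        row: dict[str, float | str | int] = {"class": c, "n_specimens": size}
        for t in TYPES:
            row[f"source_type{t}"] = src.get((c, t), 0) / size if size else 0.0
        row["source_total"] = sum(row[f"source_type{t}"] for t in TYPES)
        for t in TYPES:
            row[f"sink_type{t}"] = snk.get((c, t), 0) / n_mis if n_mis else 0.0
        row["sink_total"] = sum(row[f"sink_type{t}"] for t in TYPES)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("class")
    if round_to is not None:
        num = df.columns.drop("n_specimens")
        df[num] = df[num].round(round_to)
    return df
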