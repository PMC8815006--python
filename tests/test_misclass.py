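"""Source/sink decomposition and typed-misclassification tables."""

import numpy as np
import pandas as pd
import pytest

from woodid.evaluation import ConfusionMatrix
from woodid.misclass import (
    MisclassLedger,
    classwise_table,
    source_sink_counts,
    type_proportion_table,
    validate_ledger,
)


def ledger_from_rows(rows, n_total, class_sizes):
    return MisclassLedger(
        rows=pd.DataFrame(
            rows, columns=["specimen_id", "true_class", "predicted_class", "mtype"]
        ),
        n_total_specimens=n_total,
        class_sizes=class_sizes,
    )


class TestSourceSink:
    def test_symbolic_four_class_matrix(self):
        """For class B: source = i + k + l, sink = f + n + r, with the cells
        named e..t row-major over a 4×4 matrix (diagonal e, j, o, t)."""
        cells = np.arange(16).reshape(4, 4) + 1  # e..t as 1..16
        cm = ConfusionMatrix(("A", "B", "C", "D"), cells)
        tab = source_sink_counts(cm)
        i, k, l = cells[1, 0], cells[1, 2], cells[1, 3]
        f, n, r = cells[0, 1], cells[2, 1], cells[3, 1]
        assert tab.loc["B", "source"] == i + k + l
        assert tab.loc["B", "sink"] == f + n + r

    def test_worked_four_class_example(self):
        cm = ConfusionMatrix(
            ("A", "B", "C", "D"),
            np.array([[5, 1, 0, 0], [0, 6, 2, 0], [1, 0, 7, 0], [0, 0, 0, 4]]),
        )
        tab = source_sink_counts(cm)
        assert tab["source"].tolist() == [1, 2, 1, 0]
        assert tab["sink"].tolist() == [1, 1, 2, 0]

    def test_diagonal_matrix_has_no_flows(self):
        cm = ConfusionMatrix(("A", "B"), np.diag([5, 7]))
        tab = source_sink_counts(cm)
        assert (tab == 0).all().all()

    def test_conservation_on_random_matrices(self):
        """Σ source = Σ sink = off-diagonal total, against a per-cell loop."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(2, 7))
            counts = rng.integers(0, 9, size=(n, n))
            labels = tuple(f"C{i}" for i in range(n))
            cm = ConfusionMatrix(labels, counts)
            tab = source_sink_counts(cm)
            off_total = counts.sum() - np.trace(counts)
            assert tab["source"].sum() == off_total
            assert tab["sink"].sum() == off_total
            # brute-force per-cell accumulation
            src = dict.fromkeys(labels, 0)
            snk = dict.fromkeys(labels, 0)
            for i in range(n):
                for j in range(n):
                    if i != j:
                        src[labels[i]] += counts[i, j]
                        snk[labels[j]] += counts[i, j]
            assert tab["source"].to_dict() == src
            assert tab["sink"].to_dict() == snk

    def test_non_square_rejected(self):
        cm = ConfusionMatrix(("A", "B"), np.zeros((2, 2), dtype=int))
        cm.counts = np.zeros((2, 3), dtype=int)
        with pytest.raises(ValueError, match="square"):
            source_sink_counts(cm)


class TestLedgerValidation:
    CM = ConfusionMatrix(
        ("A", "B", "C"), np.array([[4, 2, 0], [0, 5, 1], [0, 0, 6]])
    )
    SIZES = {"A": 6, "B": 6, "C": 6}

    def good_ledger(self):
        return ledger_from_rows(
            [
                ("s1", "A", "B", 1),
                ("s2", "A", "B", 2),
                ("s3", "B", "C", 3),
            ],
            18,
            self.SIZES,
        )

    def test_consistent_ledger_passes(self):
        assert validate_ledger(self.good_ledger(), self.CM) == []

    def test_type1_and_type3_in_same_pair_flagged(self):
        led = ledger_from_rows(
            [("s1", "A", "B", 1), ("s2", "A", "B", 3), ("s3", "B", "C", 2)],
            18,
            self.SIZES,
        )
        violations = validate_ledger(led, self.CM)
        assert any("A → B" in v and "mutually exclusive" in v for v in violations)

    def test_missing_specimen_is_count_violation(self):
        led = ledger_from_rows(
            [("s1", "A", "B", 1), ("s3", "B", "C", 3)], 18, self.SIZES
        )
        violations = validate_ledger(led, self.CM)
        assert any("A → B" in v for v in violations)
        assert any("2 rows" in v or "1 rows" in v for v in violations)

    def test_type1_type2_mix_allowed(self):
        led = ledger_from_rows(
            [("s1", "A", "B", 1), ("s2", "A", "B", 2), ("s3", "B", "C", 2)],
            18,
            self.SIZES,
        )
        assert validate_ledger(led, self.CM) == []

    def test_ledger_rejects_diagonal_rows(self):
        with pytest.raises(ValueError, match="true_class"):
            ledger_from_rows([("s1", "A", "A", 1)], 10, self.SIZES)

    def test_ledger_rejects_repeat_specimens(self):
        with pytest.raises(ValueError, match="at most once"):
            ledger_from_rows(
                [("s1", "A", "B", 1), ("s1", "A", "C", 2)], 10, self.SIZES
            )

    def test_synthesized_ledger_never_violates_counts(self):
        """Soundness: a ledger generated from a matrix always validates."""
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(2, 5))
            counts = rng.integers(0, 4, size=(n, n))
            labels = tuple(f"C{i}" for i in range(n))
            cm = ConfusionMatrix(labels, counts)
            rows, sid = [], 0
            for i in range(n):
                for j in range(n):
                    if i == j:
                        continue
                    mtype = int(rng.choice([1, 3])) if rng.random() < 0.5 else 2
                    for _ in range(counts[i, j]):
                        rows.append((f"s{sid}", labels[i], labels[j], mtype))
                        sid += 1
            led = ledger_from_rows(
                rows, int(counts.sum()), {l: int(counts[i].sum()) for i, l in enumerate(labels)}
            )
            assert validate_ledger(led, cm) == []


class TestTypeProportionTable:
    def make_study_scale_ledger(self, counts=(34, 10, 11), n_total=284):
        sizes = {"A": 150, "B": 134}
        rows, sid = [], 0
        for mtype, n in zip((1, 2, 3), counts):
            for _ in range(n):
                rows.append((f"s{sid}", "A", "B", mtype))
                sid += 1
        # keep Type1/Type3 exclusivity per pair: spread types over pairs
        df = pd.DataFrame(rows, columns=["specimen_id", "true_class", "predicted_class", "mtype"])
        df.loc[df.mtype == 3, "true_class"] = "B"
        df.loc[df.mtype == 3, "predicted_class"] = "A"
        return MisclassLedger(df, n_total, sizes)

    def test_field_scale_shares(self):
        """55 misclassified of 284 split 34/10/11 across the types."""
        tab = type_proportion_table(self.make_study_scale_ledger())
        assert tab.loc["Type 1", "share_of_misclassified"] == pytest.approx(0.618, abs=5e-4)
        assert tab.loc["Type 2", "share_of_misclassified"] == pytest.approx(0.182, abs=5e-4)
        assert tab.loc["Type 3", "share_of_misclassified"] == pytest.approx(0.200, abs=5e-4)
        assert tab.loc["Type 1", "share_of_all"] == pytest.approx(0.12, abs=5e-3)
        assert tab.loc["Total", "share_of_all"] == pytest.approx(0.194, abs=5e-4)
        assert tab.loc["Total", "count"] == 55

    def test_single_error_ledger(self):
        led = ledger_from_rows([("s1", "A", "B", 1)], 10, {"A": 5, "B": 5})
        tab = type_proportion_table(led)
        assert tab.loc["Type 1", "share_of_misclassified"] == 1.0
        assert tab.loc["Type 2", "share_of_misclassified"] == 0.0
        assert tab.loc["Total", "share_of_all"] == pytest.approx(0.1)

    def test_share_identity_between_columns(self):
        led = self.make_study_scale_ledger()
        tab = type_proportion_table(led)
        rate = len(led) / led.n_total_specimens
        for t in ("Type 1", "Type 2", "Type 3"):
            assert tab.loc[t, "share_of_all"] == pytest.approx(
                tab.loc[t, "share_of_misclassified"] * rate
            )

    def test_empty_ledger_zero_table(self):
        led = ledger_from_rows([], 10, {"A": 10})
        tab = type_proportion_table(led)
        assert (tab["count"] == 0).all()
        assert (tab["share_of_misclassified"] == 0).all()

    def test_shares_sum_to_one_when_nonempty(self):
        led = self.make_study_scale_ledger(counts=(3, 2, 1), n_total=50)
        tab = type_proportion_table(led)
        assert tab.drop("Total").loc[:, "share_of_misclassified"].sum() == pytest.approx(1.0)


class TestClasswiseTable:
    def field_model_ledger(self):
        """Ledger reproducing the reference field-model source/sink rows for
        the Liriodendron source and Populus sink entries (55 of 284)."""
        sizes = {
            "Liriodendron": 14, "Populus": 26, "Magnolia": 25, "Nyssa": 23,
            "Betula": 33, "Salix": 13, "Other": 150,
        }
        rows, sid = [], 0

        def add(n, true, pred, mtype):
            nonlocal sid
            for _ in range(n):
                rows.append((f"s{sid}", true, pred, mtype))
                sid += 1

        # Liriodendron sources: 2 Type-2, 7 Type-3 (all drawn into Populus)
        add(2, "Liriodendron", "Populus", 2)
        add(7, "Liriodendron", "Populus", 3)
        # other Populus sinks: 10 Type-1 + 3 more Type-2 (from Magnolia/Betula)
        add(10, "Salix", "Populus", 1)
        add(3, "Magnolia", "Populus", 2)
        # fill the remaining 33 misclassifications elsewhere
        add(33, "Betula", "Nyssa", 1)
        return MisclassLedger(
            pd.DataFrame(rows, columns=["specimen_id", "true_class", "predicted_class", "mtype"]),
            284,
            sizes,
        )

    def test_liriodendron_source_row(self):
        tab = classwise_table(self.field_model_ledger())
        row = tab.loc["Liriodendron"]
        assert row["source_type1"] == pytest.approx(0.0)
        assert row["source_type2"] == pytest.approx(0.143, abs=5e-4)
        assert row["source_type3"] == pytest.approx(0.500, abs=5e-4)
        assert row["source_total"] == pytest.approx(0.643, abs=5e-4)

    def test_populus_sink_row(self):
        tab = classwise_table(self.field_model_ledger())
        row = tab.loc["Populus"]
        assert row["sink_type1"] == pytest.approx(0.182, abs=5e-4)
        assert row["sink_type2"] == pytest.approx(0.091, abs=5e-4)
        assert row["sink_type3"] == pytest.approx(0.127, abs=5e-4)
        assert row["sink_total"] == pytest.approx(0.400, abs=5e-4)

    def test_empty_ledger_all_zero(self):
        led = ledger_from_rows([], 10, {"A": 5, "B": 5})
        tab = classwise_table(led)
        num = tab.columns.drop("n_specimens")
        assert (tab[num] == 0).all().all()

    def test_conservation_sources_equal_sinks_equal_rows(self):
        led = self.field_model_ledger()
        tab = classwise_table(led)
        total_sources = (tab["source_total"] * tab["n_specimens"]).sum()
        total_sinks = tab["sink_total"].sum() * len(led)
        assert total_sources == pytest.approx(len(led))
        assert total_sinks == pytest.approx(len(led))

    def test_rounding_only_affects_report(self):
        led = self.field_model_ledger()
        exact = classwise_table(led)
        rounded = classwise_table(led, round_to=3)
        assert rounded.loc["Liriodendron", "source_total"] == 0.643
        assert exact.loc["Liriodendron", "source_total"] == pytest.approx(9 / 14)
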