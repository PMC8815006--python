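"""Voting operators, the image cap, and confusion-matrix bookkeeping."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from woodid.evaluation import (
    ConfusionMatrix,
    SpecimenPrediction,
    cap_images,
    evaluate_holdout,
    specimen_top1,
    specimen_top2,
)

from .conftest import make_prediction, make_records

LABELS4 = ("A", "B", "C", "D")


def brute_force_top1(preds):
    """Independent oracle: enumerate candidates, compare (votes, score, label)."""
    votes = {}
    summed = {}
    for p in preds:
        a = p.argmax_class
        votes[a] = votes.get(a, 0) + 1
        for c, s in zip(p.class_labels, p.scores):
            summed[c] = summed.get(c, 0.0) + s
    best = None
    for c in votes:
        key = (votes[c], summed[c], tuple(-ord(ch) for ch in c))
        if best is None or key > best[0]:
            best = (key, c)
    return best[1]


def brute_force_top2(preds):
    votes = {}
    summed = {}
    for p in preds:
        for c in p.top2_classes():
            votes[c] = votes.get(c, 0) + 1
        for c, s in zip(p.class_labels, p.scores):
            summed[c] = summed.get(c, 0.0) + s
    ranked = sorted(
        votes, key=lambda c: (-votes[c], -summed[c], c)
    )
    return ranked[0], ranked[1]


class TestTop1:
    def test_simple_majority(self):
        preds = [
            make_prediction("s", [0.9, 0.1, 0.0], "ABC"),
            make_prediction("s", [0.8, 0.2, 0.0], "ABC"),
            make_prediction("s", [0.1, 0.9, 0.0], "ABC"),
        ]
        assert specimen_top1(preds) == "A"

    def test_single_image_is_its_argmax(self):
        preds = [make_prediction("s", [0.2, 0.7, 0.1], "ABC")]
        assert specimen_top1(preds) == "B"

    def test_tie_broken_by_summed_score(self):
        preds = [
            make_prediction("s", [0.7, 0.3], "AB"),
            make_prediction("s", [0.4, 0.6], "AB"),
        ]
        # votes 1:1; summed A = 1.1, B = 0.9
        assert specimen_top1(preds) == "A"

    def test_full_tie_broken_lexicographically(self):
        preds = [
            make_prediction("s", [0.6, 0.4], "AB"),
            make_prediction("s", [0.4, 0.6], "AB"),
        ]
        assert specimen_top1(preds) == "A"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            specimen_top1([])

    def test_mixed_specimens_rejected(self):
        preds = [
            make_prediction("s1", [1, 0], "AB"),
            make_prediction("s2", [1, 0], "AB"),
        ]
        with pytest.raises(ValueError):
            specimen_top1(preds)


class TestTop2:
    def test_unanimous_pair(self):
        preds = [make_prediction("s", [0.5, 0.4, 0.1], "ABC") for _ in range(3)]
        assert set(specimen_top2(preds)) == {"A", "B"}

    def test_vote_totals_rank_pair(self):
        # votes A:3, B:2, C:1
        preds = [
            make_prediction("s", [0.6, 0.3, 0.1], "ABC"),
            make_prediction("s", [0.6, 0.3, 0.1], "ABC"),
            make_prediction("s", [0.6, 0.1, 0.3], "ABC"),
        ]
        assert specimen_top2(preds) == ("A", "B")

    def test_slot2_tie_resolved_by_summed_score(self):
        preds = [
            make_prediction("s", [0.5, 0.4, 0.1], "ABC"),
            make_prediction("s", [0.5, 0.1, 0.4], "ABC"),
        ]
        # votes A:2, B:1, C:1; summed B = 0.5, C = 0.5 → lexicographic B
        assert specimen_top2(preds) == ("A", "B")

    def test_two_class_floor(self):
        preds = [make_prediction("s", [1.0], "A")]
        with pytest.raises(ValueError):
            specimen_top2(preds)


class TestVotingAgainstBruteForce:
    """Both operators equal exhaustive enumeration on small vote tables."""

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        n_images=st.integers(1, 4),
        n_classes=st.integers(2, 4),
        data=st.data(),
    )
    def test_random_tables(self, n_images, n_classes, data):
        labels = LABELS4[:n_classes]
        preds = []
        for i in range(n_images):
            raw = data.draw(
                st.lists(
                    st.integers(1, 5), min_size=n_classes, max_size=n_classes
                )
            )
            preds.append(make_prediction("s", raw, labels))
        assert specimen_top1(preds) == brute_force_top1(preds)
        assert specimen_top2(preds) == brute_force_top2(preds)

    def test_exhaustive_argmax_patterns(self):
        """All argmax/top-2 assignments over 3 images × 3 classes."""
        labels = ("A", "B", "C")
        score_options = [
            (0.6, 0.3, 0.1), (0.3, 0.6, 0.1), (0.1, 0.3, 0.6),
            (0.45, 0.45, 0.1), (0.4, 0.1, 0.5),
        ]
        for combo in itertools.product(score_options, repeat=3):
            preds = [make_prediction("s", list(sc), labels) for sc in combo]
            assert specimen_top1(preds) == brute_force_top1(preds)
            assert specimen_top2(preds) == brute_force_top2(preds)


class TestCapImages:
    def test_cap_keeps_first_five_in_manifest_order(self):
        rec = make_records(["A"])[0]
        rec = type(rec)(
            specimen_id="s", xylarium="X", taxon="T a", class_label="A",
            image_paths=tuple(f"im{i}.png" for i in range(7)),
        )
        assert cap_images(rec) == tuple(f"im{i}.png" for i in range(5))
        assert cap_images(rec, 3) == ("im0.png", "im1.png", "im2.png")

    def test_fewer_images_than_cap_all_kept(self):
        rec = make_records(["A"])[0]
        assert cap_images(rec, 5) == rec.image_paths

    def test_zero_cap_rejected(self):
        with pytest.raises(ValueError):
            cap_images(make_records(["A"])[0], 0)


class TestConfusionMatrix:
    def test_row_sums_are_specimens_per_class(self):
        preds = [
            SpecimenPrediction("s1", "A", "A", ("A", "B"), 3),
            SpecimenPrediction("s2", "A", "B", ("B", "A"), 3),
            SpecimenPrediction("s3", "B", "B", ("B", "A"), 3),
        ]
        cm = ConfusionMatrix.from_predictions(preds, ("A", "B"))
        assert cm.row_sums().tolist() == [2, 1]
        assert cm.total == 3

    def test_trace_over_total_equals_top1_accuracy(self):
        preds = [
            SpecimenPrediction(f"s{i}", "A", "A" if i < 3 else "B", ("A", "B"), 1)
            for i in range(5)
        ]
        cm = ConfusionMatrix.from_predictions(preds, ("A", "B"))
        acc = np.mean([p.top1_correct for p in preds])
        assert cm.trace / cm.total == pytest.approx(acc)

    def test_csv_round_trip(self, tmp_path):
        cm = ConfusionMatrix(("A", "B"), np.array([[3, 1], [0, 2]]))
        path = tmp_path / "cm.csv"
        cm.to_csv(path)
        loaded = ConfusionMatrix.from_csv(path)
        assert loaded.class_labels == cm.class_labels
        assert np.array_equal(loaded.counts, cm.counts)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(("A", "B"), np.array([[1, -1], [0, 2]]))


class _StubModel:
    """Deterministic scorer keyed on image mean intensity."""

    def __init__(self, score_fn, n_classes):
        self.score_fn = score_fn
        self.n_classes = n_classes

    def predict_proba(self, x):
        return np.stack([self.score_fn(row) for row in x])


class TestEvaluateHoldout:
    def _records_and_arrays(self, labels, n_spec=2, value_of=None):
        import dataclasses as dc

        records, arrays = [], {}
        i = 0
        for lab in labels:
            for _ in range(n_spec):
                paths = (f"im{i}a.png", f"im{i}b.png")
                rec = make_records([lab])[0]
                rec = dc.replace(rec, specimen_id=f"s{i}", image_paths=paths)
                records.append(rec)
                for p in paths:
                    arrays[p] = np.full((256, 256), value_of(lab), dtype=np.float32)
                i += 1
        return records, arrays

    def _perfect_scorer(self, labels, invert=False):
        def fn(row):
            # recover the constant intensity from the normalised patch
            val = float(row.mean() * 0.25 + 0.5)
            idx = int(round(val * 10)) - 1
            scores = np.full(len(labels), 0.01)
            if invert:
                scores[(idx + 1) % len(labels)] = 1.0  # always wrong argmax
                scores[idx] = 0.5  # true class always second
            else:
                scores[idx] = 1.0
            return scores / scores.sum()

        return fn

    def test_perfect_scorer_scores_100(self, small_patch_cfg):
        labels = ("L1", "L2", "L3")
        records, arrays = self._records_and_arrays(
            labels, value_of=lambda lab: (int(lab[1])) / 10
        )
        model = _StubModel(self._perfect_scorer(labels), 3)
        res = evaluate_holdout(
            [model], records, small_patch_cfg, labels, image_arrays=arrays
        )
        assert res["top1_mean"] == 1.0
        assert res["top2_mean"] == 1.0

    def test_always_second_scorer_top1_zero_top2_full(self, small_patch_cfg):
        labels = ("L1", "L2", "L3")
        records, arrays = self._records_and_arrays(
            labels, value_of=lambda lab: (int(lab[1])) / 10
        )
        model = _StubModel(self._perfect_scorer(labels, invert=True), 3)
        res = evaluate_holdout(
            [model], records, small_patch_cfg, labels, image_arrays=arrays
        )
        assert res["top1_mean"] == 0.0
        assert res["top2_mean"] == 1.0

    def test_mean_sd_over_five_models(self, small_patch_cfg):
        labels = ("L1", "L2")
        records, arrays = self._records_and_arrays(
            labels, value_of=lambda lab: (int(lab[1])) / 10
        )

        accs = [1.0, 1.0, 0.75, 0.5, 0.5]

        class PartialModel(_StubModel):
            def __init__(self, frac):
                self.frac = frac
                self.count = 0
                super().__init__(None, 2)

            def predict_proba(self, x):
                out = []
                for row in x:
                    val = float(row.mean() * 0.25 + 0.5)
                    idx = int(round(val * 10)) - 1
                    self.count += 1
                    good = (self.count % 4) / 4.0 < self.frac
                    scores = np.array([0.1, 0.1])
                    scores[idx if good else 1 - idx] = 0.8
                    out.append(scores / scores.sum())
                return np.stack(out)

        models = [PartialModel(a) for a in accs]
        res = evaluate_holdout(
            models, records, small_patch_cfg, labels, image_arrays=arrays
        )
        assert len(res["per_model_top1"]) == 5
        assert res["top1_mean"] == pytest.approx(np.mean(res["per_model_top1"]))
        assert res["top1_sd"] == pytest.approx(
            np.std(res["per_model_top1"], ddof=1)
        )

    def test_top1_never_exceeds_top2(self, small_patch_cfg):
        labels = ("L1", "L2", "L3")
        records, arrays = self._records_and_arrays(
            labels, value_of=lambda lab: (int(lab[1])) / 10
        )
        rng = np.random.default_rng(0)

        class NoisyModel(_StubModel):
            def __init__(self):
                super().__init__(None, 3)

            def predict_proba(self, x):
                s = rng.random((len(x), 3))
                return s / s.sum(axis=1, keepdims=True)

        res = evaluate_holdout(
            [NoisyModel()], records, small_patch_cfg, labels, image_arrays=arrays
        )
        assert res["top1_mean"] <= res["top2_mean"]

    def test_empty_holdout_rejected(self, small_patch_cfg):
        with pytest.raises(ValueError):
            evaluate_holdout([_StubModel(None, 2)], [], small_patch_cfg, ("A", "B"))
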