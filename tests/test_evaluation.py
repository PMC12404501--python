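"""Evaluation metrics: confusion counting, per-class rates, the
clinical-alert metric against a brute-force oracle, and PR curves."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ramantissue.evaluation import (
    ClinicalAlertReport,
    ConfusionMatrix,
    OntologyError,
    TissueOntology,
    clinical_alert,
    confusion_matrix,
    per_class_metrics,
    precision_recall,
)

ONT = TissueOntology.default()
CLASSES = ONT.classes


def brute_force_clinical_alert(cm: ConfusionMatrix, ontology: TissueOntology):
    """Independent oracle: enumerate every off-diagonal cell and classify
    it by the ontology of its predicted column."""
    out = {}
    for cls in ontology.malignant_classes:
        i = ontology.classes.index(cls)
        tp = int(cm.counts[i, i])
        fn = fnm = 0
        for j, pred_cls in enumerate(ontology.classes):
            if j == i:
                continue
            n = int(cm.counts[i, j])
            fn += n
            if ontology.category[pred_cls] == "malignant":
                fnm += n
        fnc = fn - fnm
        out[cls] = {"TP": tp, "FN": fn, "FNM": fnm, "FNC": fnc,
                    "CA": fnc / (tp + fn) if tp + fn else 0.0}
    return out


class TestOntology:
    def test_default_has_four_malignant_classes(self):
        assert len(ONT.malignant_classes) == 4
        assert set(ONT.malignant_classes) == {"MLS", "PLS", "LEI", "HMS"}

    def test_every_class_has_one_category(self):
        assert set(ONT.category) >= set(ONT.classes)
        for c in ONT.classes:
            assert ONT.category[c] in ("normal", "benign", "malignant")

    def test_roundtrips_through_dict(self):
        assert TissueOntology.from_dict(ONT.to_dict()) == ONT

    def test_invalid_category_rejected(self):
        with pytest.raises(OntologyError):
            TissueOntology(classes=("A",), category={"A": "weird"})


class TestConfusionMatrix:
    def test_perfect_predictions_diagonal(self):
        y = list(CLASSES) * 3
        cm = confusion_matrix(y, y, ONT)
        assert np.trace(cm.counts) == len(y)
        assert cm.counts.sum() == len(y)

    def test_single_misclassification_cell(self):
        cm = confusion_matrix(["FAT"], ["MLS"], ONT)
        i, j = CLASSES.index("FAT"), CLASSES.index("MLS")
        assert cm.counts[i, j] == 1
        assert cm.counts.sum() == 1

    def test_row_sums_match_label_tallies(self):
        rng = np.random.default_rng(0)
        y_true = rng.choice(CLASSES, size=1000)
        y_pred = rng.choice(CLASSES, size=1000)
        cm = confusion_matrix(y_true, y_pred, ONT)
        assert cm.counts.sum() == 1000
        for i, cls in enumerate(CLASSES):
            assert cm.counts[i].sum() == int(np.sum(y_true == cls))

    def test_unknown_label_rejected(self):
        with pytest.raises(KeyError):
            confusion_matrix(["FAT"], ["BONE"], ONT)

    def test_accuracy_is_trace_over_total(self):
        rng = np.random.default_rng(1)
        y_true = rng.choice(CLASSES, size=500)
        y_pred = rng.choice(CLASSES, size=500)
        cm = confusion_matrix(y_true, y_pred, ONT)
        assert cm.accuracy() == pytest.approx(np.mean(y_true == y_pred))


class TestPerClassMetrics:
    def test_diagonal_matrix_perfect_metrics(self):
        cm = ConfusionMatrix(np.eye(8, dtype=int) * 5, CLASSES)
        rep = per_class_metrics(cm)
        for vals in rep.per_class.values():
            assert vals["sensitivity"] == 1.0
            assert vals["specificity"] == 1.0
            assert vals["precision"] == 1.0
        assert rep.accuracy == 1.0

    def test_two_class_hand_values(self):
        cm = ConfusionMatrix(np.array([[8, 2], [1, 9]]), ("A", "B"))
        rep = per_class_metrics(cm)
        assert rep.per_class["A"]["sensitivity"] == pytest.approx(0.8)
        assert rep.per_class["A"]["precision"] == pytest.approx(8 / 9)
        assert rep.per_class["B"]["specificity"] == pytest.approx(0.8)

    def test_no_predicted_positives_flagged_zero(self):
        counts = np.array([[0, 5], [0, 5]])
        rep = per_class_metrics(ConfusionMatrix(counts, ("A", "B")))
        assert rep.per_class["A"]["precision"] == 0.0
        assert "A" in rep.degenerate

    def test_weighted_f1_between_extremes(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 30, size=(8, 8))
        counts += np.eye(8, dtype=int) * 30
        rep = per_class_metrics(ConfusionMatrix(counts, CLASSES))
        f1s = [v["f1"] for v in rep.per_class.values()]
        assert min(f1s) <= rep.weighted["f1"] <= max(f1s)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            per_class_metrics(ConfusionMatrix(np.zeros((8, 8), dtype=int), CLASSES))


class TestClinicalAlert:
    def test_hand_worked_example(self):
        """Malignant row with TP=90 and errors {other-malignant: 4,
        normal: 5, benign: 1}: FN=10, FNM=4, FNC=6, CA=0.06."""
        counts = np.zeros((8, 8), dtype=int)
        i = CLASSES.index("MLS")
        counts[i, i] = 90
        counts[i, CLASSES.index("PLS")] = 4   # other malignant
        counts[i, CLASSES.index("MSC")] = 5   # normal
        counts[i, CLASSES.index("LEM")] = 1   # benign
        rep = clinical_alert(ConfusionMatrix(counts, CLASSES), ONT)
        row = rep.per_class["MLS"]
        assert (row["TP"], row["FN"], row["FNM"], row["FNC"]) == (90, 10, 4, 6)
        assert row["CA"] == pytest.approx(0.06)

    def test_all_errors_malignant_gives_zero_ca(self):
        counts = np.zeros((8, 8), dtype=int)
        i = CLASSES.index("LEI")
        counts[i, i] = 50
        counts[i, CLASSES.index("HMS")] = 7
        rep = clinical_alert(ConfusionMatrix(counts, CLASSES), ONT)
        assert rep.per_class["LEI"]["CA"] == 0.0

    def test_no_false_negatives_gives_zero_ca(self):
        counts = np.zeros((8, 8), dtype=int)
        i = CLASSES.index("HMS")
        counts[i, i] = 42
        rep = clinical_alert(ConfusionMatrix(counts, CLASSES), ONT)
        assert rep.per_class["HMS"]["CA"] == 0.0

    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(31415)
        for _ in range(200):
            counts = rng.integers(0, 51, size=(8, 8))
            cm = ConfusionMatrix(counts, CLASSES)
            rep = clinical_alert(cm, ONT)
            oracle = brute_force_clinical_alert(cm, ONT)
            for cls in ONT.malignant_classes:
                for key in ("TP", "FN", "FNM", "FNC"):
                    assert rep.per_class[cls][key] == oracle[cls][key]
                assert rep.per_class[cls]["CA"] == pytest.approx(
                    oracle[cls]["CA"], abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_bounds_hold_for_any_matrix(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 51, size=(8, 8))
        rep = clinical_alert(ConfusionMatrix(counts, CLASSES), ONT)
        for row in rep.per_class.values():
            assert 0 <= row["FNM"] <= row["FN"]
            assert 0.0 <= row["CA"] <= 1.0
        assert 0.0 <= rep.overall_ca <= 1.0

    def test_overall_ca_is_pooled_ratio(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 51, size=(8, 8))
        rep = clinical_alert(ConfusionMatrix(counts, CLASSES), ONT)
        num = sum(rep.per_class[c]["FNC"] for c in ONT.malignant_classes)
        den = sum(rep.per_class[c]["TP"] + rep.per_class[c]["FN"]
                  for c in ONT.malignant_classes)
        assert rep.overall_ca == pytest.approx(num / den)

    def test_merging_malignant_classes_preserves_or_raises_sensitivity(self):
        """Coarsening the ontology (one pooled malignant class) cannot
        lower the pooled malignant sensitivity: within-malignant
        confusions become correct."""
        rng = np.random.default_rng(11)
        counts = rng.integers(0, 51, size=(8, 8))
        mal = [CLASSES.index(c) for c in ONT.malignant_classes]
        fine_tp = sum(counts[i, i] for i in mal)
        fine_total = sum(counts[i].sum() for i in mal)
        coarse_tp = sum(counts[i, j] for i in mal for j in mal)
        assert coarse_tp >= fine_tp
        assert coarse_tp / fine_total >= fine_tp / fine_total

    def test_no_malignant_class_rejected(self):
        ont = TissueOntology(classes=("A", "B"),
                             category={"A": "normal", "B": "benign"})
        cm = ConfusionMatrix(np.eye(2, dtype=int), ("A", "B"))
        with pytest.raises(OntologyError):
            clinical_alert(cm, ont)


class TestPrecisionRecall:
    def test_perfectly_separated_scores_ap_one(self):
        y = np.repeat(CLASSES, 5)
        scores = np.zeros((len(y), 8))
        for i, cls in enumerate(y):
            scores[i, CLASSES.index(cls)] = 1.0
        curves = precision_recall(scores, y, CLASSES)
        for cls in CLASSES:
            assert curves[cls]["average_precision"] == pytest.approx(1.0)

    def test_two_point_toy_ap_one(self):
        curves = precision_recall(
            np.array([[0.9, 0.1], [0.1, 0.9]]), np.array(["A", "B"]),
            ("A", "B"))
        assert curves["A"]["average_precision"] == pytest.approx(1.0)

    def test_random_scores_ap_near_prevalence(self):
        """With label-independent scores, AP concentrates near the class
        prevalence p (permutation argument)."""
        rng = np.random.default_rng(123)
        n, p = 4000, 0.2
        y = np.where(rng.random(n) < p, "A", "B")
        scores = rng.random((n, 2))
        scores[:, 1] = 1 - scores[:, 0]
        ap = precision_recall(scores, y, ("A", "B"))["A"]["average_precision"]
        prevalence = float(np.mean(y == "A"))
        # Standard error of AP under permutation is O(1/sqrt(n*p)).
        assert abs(ap - prevalence) < 3.0 / np.sqrt(n * prevalence)

    def test_absent_class_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            curves = precision_recall(
                np.array([[1.0, 0.0]]), np.array(["A"]), ("A", "B"))
        assert "B" not in curves
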