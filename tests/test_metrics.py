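import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from hotseq.calibration import CalibrationTable, apply_correction, fit_correction_from_probabilities
from hotseq.metrics import (
    ConfusionCounts,
    auroc,
    confusion,
    per_amino_acid_report,
    scalar_metrics,
    weighted_metrics,
)


def brute_force_confusion(predicted, actual):
    tp = tn = fp = fn = 0
    for p, a in zip(predicted, actual):
        if p == "HS" and a == "HS":
            tp += 1
        elif p == "NS" and a == "NS":
            tn += 1
        elif p == "HS" and a == "NS":
            fp += 1
        else:
            fn += 1
    return tp, tn, fp, fn


def brute_force_auroc(scores, actual):
    """Exhaustive concordant/discordant/tied pair enumeration."""
    pos = [s for s, a in zip(scores, actual) if a == "HS"]
    neg = [s for s, a in zip(scores, actual) if a == "NS"]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_prediction(self):
        actual = ["NS"] * 7 + ["HS"] * 3
        counts = confusion(actual, actual)
        assert (counts.TP, counts.TN, counts.FP, counts.FN) == (3, 7, 0, 0)

    def test_total_inversion(self):
        actual = ["NS"] * 7 + ["HS"] * 3
        flipped = ["HS" if a == "NS" else "NS" for a in actual]
        counts = confusion(flipped, actual)
        assert counts.TP == 0 and counts.TN == 0
        assert counts.FP == 7 and counts.FN == 3

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        predicted = rng.choice(["HS", "NS"], size=50)
        actual = rng.choice(["HS", "NS"], size=50)
        counts = confusion(predicted, actual)
        assert (counts.TP, counts.TN, counts.FP, counts.FN) == brute_force_confusion(predicted, actual)
        assert counts.total == 50

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(["HS"], ["HS", "NS"])

    def test_integer_encoding_accepted(self):
        counts = confusion([1, 0, 1], [1, 1, 0])
        assert (counts.TP, counts.TN, counts.FP, counts.FN) == (1, 0, 1, 1)


class TestScalarMetrics:
    def test_worked_example(self):
        metrics = scalar_metrics(ConfusionCounts(TP=2, TN=6, FP=1, FN=1))
        assert metrics["accuracy"] == pytest.approx(0.8)
        assert metrics["precision"] == pytest.approx(2 / 3)
        assert metrics["recall"] == pytest.approx(2 / 3)
        assert metrics["fpr"] == pytest.approx(1 / 7)
        assert metrics["f1"] == pytest.approx(2 / 3)

    def test_zero_fp_with_tp_gives_precision_one(self):
        assert scalar_metrics(ConfusionCounts(TP=4, TN=5, FP=0, FN=1))["precision"] == 1.0

    def test_zero_over_zero_yields_undefined_marker(self):
        metrics = scalar_metrics(ConfusionCounts(TP=0, TN=5, FP=0, FN=0))
        assert math.isnan(metrics["precision"])
        assert math.isnan(metrics["recall"])
        assert math.isnan(metrics["f1"])

    @pytest.mark.parametrize("seed", range(10))
    def test_identities_hold_on_random_counts(self, seed):
        rng = np.random.default_rng(seed)
        tp, tn, fp, fn = (int(x) for x in rng.integers(1, 40, size=4))
        m = scalar_metrics(ConfusionCounts(tp, tn, fp, fn))
        assert m["accuracy"] == pytest.approx((tp + tn) / (tp + tn + fp + fn))
        assert m["precision"] == pytest.approx(tp / (tp + fp))
        assert m["recall"] == pytest.approx(tp / (tp + fn))
        assert m["fpr"] == pytest.approx(fp / (fp + tn))
        assert m["f1"] == pytest.approx(2 * m["precision"] * m["recall"] / (m["precision"] + m["recall"]))

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            scalar_metrics(ConfusionCounts(0, 0, 0, 0))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.1, 0.2], ["HS", "HS", "NS", "NS"]) == 1.0

    def test_uninformative_constant_scores(self):
        assert auroc([0.5] * 6, ["HS", "NS"] * 3) == 0.5

    def test_single_class_undefined(self):
        assert math.isnan(auroc([0.3, 0.6], ["HS", "HS"]))

    @pytest.mark.parametrize("seed", range(100))
    def test_rank_statistic_equals_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        scores = np.round(rng.random(n), 2)  # rounding induces ties
        actual = rng.choice(["HS", "NS"], size=n)
        if len(set(actual)) < 2:
            actual[0], actual[1] = "HS", "NS"
        assert auroc(scores, actual) == pytest.approx(brute_force_auroc(scores, actual), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_trapezoidal_reference(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(60)
        actual = rng.choice(["HS", "NS"], size=60)
        if len(set(actual)) < 2:
            actual[0], actual[1] = "HS", "NS"
        y = (np.asarray(actual) == "HS").astype(int)
        assert auroc(scores, actual) == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_invariant_under_strictly_increasing_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.random(40)
        actual = rng.choice(["HS", "NS"], size=40)
        actual[0], actual[1] = "HS", "NS"
        assert auroc(scores, actual) == pytest.approx(auroc(np.exp(5 * scores), actual), abs=1e-12)


class TestPerAminoAcidReport:
    def _predictions(self, raw, aas, correction=None):
        frame = pd.DataFrame(
            {
                "chain_id": "c",
                "position": range(1, len(raw) + 1),
                "amino_acid": aas,
                "raw_hs_probability": raw,
            }
        )
        return apply_correction(frame, correction or CalibrationTable())

    def test_single_amino_acid_row_equals_overall(self):
        out = self._predictions([0.9, 0.2, 0.7], ["Y", "Y", "Y"])
        report = per_amino_acid_report(out, ["HS", "NS", "HS"])
        overall = report[(report.amino_acid == "ALL") & (report.stage == "original")].iloc[0]
        y_row = report[(report.amino_acid == "Y") & (report.stage == "original")].iloc[0]
        for col in ("TP", "TN", "FP", "FN", "accuracy"):
            assert overall[col] == y_row[col]

    def test_pooled_counts_are_sums_of_rows(self):
        rng = np.random.default_rng(8)
        aas = rng.choice(list("YLW"), size=60)
        out = self._predictions(rng.random(60), aas)
        actual = rng.choice(["HS", "NS"], size=60)
        report = per_amino_acid_report(out, actual)
        original = report[report.stage == "original"]
        pooled = original[original.amino_acid == "ALL"]
        per_aa = original[original.amino_acid != "ALL"]
        for col in ("TP", "TN", "FP", "FN"):
            assert pooled[col].iloc[0] == per_aa[col].sum()

    def test_fitted_calibration_never_raises_per_row_fp_on_tuning_set(self):
        rng = np.random.default_rng(9)
        aas = rng.choice(list("YLWFK"), size=100)
        raw = rng.random(100)
        actual = np.where(rng.random(100) < 0.3, "HS", "NS")
        table = fit_correction_from_probabilities(raw, actual, aas)
        out = self._predictions(raw, aas, table)
        report = per_amino_acid_report(out, actual)
        for aa in set(aas):
            rows = report[report.amino_acid == aa].set_index("stage")
            assert rows.loc["corrected", "FP"] <= rows.loc["original", "FP"]

    def test_empty_predictions_rejected(self):
        with pytest.raises(ValueError):
            per_amino_acid_report(pd.DataFrame(), [])


class TestWeightedVariants:
    def test_weighted_metrics_on_balanced_perfect_prediction(self):
        actual = ["HS", "NS"] * 5
        out = weighted_metrics(actual, actual)
        assert out["accuracy"] == 1.0
        assert out["weighted_precision"] == pytest.approx(1.0)
        assert out["weighted_f1"] == pytest.approx(1.0)
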