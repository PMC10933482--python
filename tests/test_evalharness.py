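"""Metrics, AUC, SMOTE balancing and the evaluation protocols."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from ifrmi.evalharness import (
    ConfusionCounts,
    auc_score,
    classification_metrics,
    confusion_counts,
    evaluate_protocol,
    knn_adapter,
    oracle_adapter,
    smote_balance,
)
from ifrmi.ifis import AttributeSchema, MixedDataset
from ifrmi.synthdata import SyntheticSpec, generate_mixed


class TestConfusion:
    def test_all_correct_positive(self):
        c = confusion_counts(["+"] * 4, ["+"] * 4, "+")
        assert (c.TRP, c.TRN, c.FLP, c.FLN) == (4, 0, 0, 0)

    def test_inverted_predictions(self):
        c = confusion_counts(["+", "-"], ["-", "+"], "+")
        assert c.TRP == 0 and c.TRN == 0 and c.FLP == 1 and c.FLN == 1

    def test_enumerated_mixed_case(self):
        c = confusion_counts(list("++--"), list("+--+"), "+")
        assert (c.TRP, c.TRN, c.FLP, c.FLN) == (1, 1, 1, 1)

    def test_multiclass_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            confusion_counts(["a", "b", "c"], ["a", "b", "c"], "a")

    def test_unseen_positive_label(self):
        with pytest.raises(ValueError, match="absent"):
            confusion_counts(["a", "b"], ["a", "b"], "z")


class TestMetrics:
    def test_perfect_counts(self):
        rec = classification_metrics(ConfusionCounts(50, 50, 0, 0))
        assert rec.Sn == rec.Sp == rec.Ac == 100.0
        assert rec.MCC == pytest.approx(1.0)

    def test_uniform_counts(self):
        rec = classification_metrics(ConfusionCounts(1, 1, 1, 1))
        assert rec.Sn == rec.Sp == rec.Ac == 50.0
        assert rec.MCC == pytest.approx(0.0)

    def test_sensitivity_arithmetic(self):
        rec = classification_metrics(ConfusionCounts(86, 10, 5, 14))
        assert rec.Sn == pytest.approx(86.0)

    def test_zero_denominator_mcc_logged_as_zero(self, caplog):
        rec = classification_metrics(ConfusionCounts(3, 0, 0, 1))
        assert rec.MCC == 0.0

    def test_label_swap_swaps_sn_sp_and_keeps_mcc_magnitude(self):
        truth = np.array(list("++--+-"))
        pred = np.array(list("+--++-"))
        a = classification_metrics(confusion_counts(truth, pred, "+"))
        b = classification_metrics(confusion_counts(truth, pred, "-"))
        assert a.Sn == pytest.approx(b.Sp)
        assert a.Sp == pytest.approx(b.Sn)
        assert abs(a.MCC) == pytest.approx(abs(b.MCC))


class TestAUC:
    def test_perfect_separation(self):
        assert auc_score([0.9, 0.8, 0.2, 0.1], list("++--"), "+") == 1.0

    def test_all_ties_give_half(self):
        assert auc_score([0.5] * 6, list("++--+-"), "+") == 0.5

    def test_two_pair_enumeration(self):
        assert auc_score([0.9, 0.4, 0.6], ["+", "-", "+"], "+") == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_score([0.1, 0.2], ["+", "+"], "+")

    def test_rank_auc_matches_trapezoidal_roc(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(4, 40))
            truth = rng.choice(["+", "-"], size=n)
            if len(np.unique(truth)) < 2:
                continue
            scores = np.round(rng.random(n), 2)  # induce ties
            expected = roc_auc_score((truth == "+").astype(int), scores)
            assert auc_score(scores, truth, "+") == pytest.approx(
                expected, abs=1e-12
            )


def imbalanced_dataset(n_pos=102, n_neg=83, seed=0):
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    labels = np.array(["PL+"] * n_pos + ["PL-"] * n_neg)
    frame = pd.DataFrame(
        {
            "x1": rng.normal(size=n) + (labels == "PL+"),
            "x2": rng.normal(size=n),
            "g": rng.choice(["u", "v"], size=n),
            "d": labels,
        }
    )
    schema = (
        AttributeSchema("x1", "numeric"),
        AttributeSchema("x2", "numeric"),
        AttributeSchema("g", "nominal"),
        AttributeSchema("d", "nominal", "decision"),
    )
    return MixedDataset(frame=frame, schema=schema)


class TestSmote:
    def test_balances_102_vs_83_to_parity(self):
        out = smote_balance(imbalanced_dataset(), seed=1)
        labels, counts = np.unique(out.decision_labels(), return_counts=True)
        assert dict(zip(labels, counts)) == {"PL+": 102, "PL-": 102}

    def test_balanced_input_returned_unchanged(self):
        data = imbalanced_dataset(n_pos=50, n_neg=50)
        assert smote_balance(data, seed=1) is data

    def test_synthetic_numerics_lie_between_parents(self):
        data = imbalanced_dataset(n_pos=40, n_neg=20, seed=3)
        out = smote_balance(data, seed=5)
        minority = data.frame[data.frame["d"] == "PL-"]
        for col in ("x1", "x2"):
            new_vals = out.frame[col].iloc[len(data.frame):]
            assert new_vals.min() >= minority[col].min() - 1e-9
            assert new_vals.max() <= minority[col].max() + 1e-9

    def test_nominal_values_copied_from_minority(self):
        out = smote_balance(imbalanced_dataset(), seed=2)
        new_rows = out.frame.iloc[185:]
        assert set(new_rows["g"]) <= {"u", "v"}
        assert set(new_rows["d"]) == {"PL-"}

    def test_tiny_minority_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            smote_balance(imbalanced_dataset(n_pos=5, n_neg=1), seed=0)

    def test_deterministic(self):
        a = smote_balance(imbalanced_dataset(), k=3, seed=9)
        b = smote_balance(imbalanced_dataset(), k=3, seed=9)
        pd.testing.assert_frame_equal(a.frame, b.frame)


class TestProtocols:
    def test_oracle_adapter_scores_100_everywhere(self):
        data = imbalanced_dataset(n_pos=30, n_neg=30)
        for proto in ({"kfold": 5}, {"split": 66.0}):
            table = evaluate_protocol(data, ("x1", "x2"), proto, oracle_adapter)
            assert (table["Ac"] == 100.0).all()

    def test_tenfold_shape_on_synthetic_data(self):
        data, _ = generate_mixed(SyntheticSpec(seed=0, n=200))
        attrs = tuple(a.name for a in data.conditional_attributes[:3])
        table = evaluate_protocol(data, attrs, {"kfold": 10}, knn_adapter(), seed=1)
        assert len(table) == 11  # 10 folds + mean row
        assert table["fold"].iloc[-1] == "mean"
        assert "Ac_std" in table.columns

    def test_same_seed_reproduces_table(self):
        data = imbalanced_dataset()
        t1 = evaluate_protocol(data, ("x1", "x2"), {"kfold": 5}, knn_adapter(), 7)
        t2 = evaluate_protocol(data, ("x1", "x2"), {"kfold": 5}, knn_adapter(), 7)
        pd.testing.assert_frame_equal(t1, t2)

    def test_empty_reduct_and_excess_folds_rejected(self):
        data = imbalanced_dataset(n_pos=6, n_neg=4)
        with pytest.raises(ValueError, match="empty"):
            evaluate_protocol(data, (), {"kfold": 2}, oracle_adapter)
        with pytest.raises(ValueError, match="fold count"):
            evaluate_protocol(data, ("x1",), {"kfold": 5}, oracle_adapter)
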