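"""Confusion-matrix metrics, ROC/PR curves and printed-tuple inversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cpgnet import evaluate
from cpgnet.evaluate import (
    ConfusionMatrix,
    confusion,
    pr_curve,
    roc_curve,
    scalar_metrics,
    solve_confusion_matrix,
)


class TestConfusion:
    def test_perfect_prediction(self):
        y = ["methylated"] * 10 + ["unmethylated"] * 10
        cm = confusion(y, y)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (10, 10, 0, 0)

    def test_all_positive_prediction(self):
        y_true = [1] * 10 + [0] * 10
        cm = confusion(y_true, [1] * 20)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (10, 10, 0, 0)

    def test_hand_tally(self):
        y_true = [1, 0, 1, 1, 0, 0]
        y_pred = [1, 1, 0, 1, 0, 1]
        # element-wise: TP, FP, FN, TP, TN, FP
        cm = confusion(y_true, y_pred)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (2, 2, 1, 1)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])

    def test_unknown_label(self):
        with pytest.raises(ValueError):
            confusion(["hemimethylated"], ["methylated"])

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import confusion_matrix as sk_cm

        rng = np.random.default_rng(0)
        t = rng.integers(0, 2, 100)
        p = rng.integers(0, 2, 100)
        cm = confusion(t, p)
        tn, fp, fn, tp = sk_cm(t, p).ravel()
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (tp, fp, tn, fn)


class TestScalarMetrics:
    def test_perfect_classifier(self):
        rep = scalar_metrics(ConfusionMatrix(tp=50, fp=0, tn=50, fn=0))
        assert rep.sn == rep.sp == rep.acc == rep.precision == rep.f1 == 1.0
        assert rep.mcc == 1.0

    def test_all_positive_degenerate(self):
        rep = scalar_metrics(ConfusionMatrix(tp=10, fp=10, tn=0, fn=0))
        assert rep.sn == 1.0 and rep.sp == 0.0
        assert rep.acc == 0.5 and rep.precision == 0.5
        assert rep.mcc is None  # zero denominator -> undefined marker

    def test_undefined_markers_not_zero(self):
        rep = scalar_metrics(ConfusionMatrix(tp=0, fp=0, tn=5, fn=0))
        assert rep.sn is None and rep.precision is None and rep.f1 is None

    def test_symmetry_under_class_swap(self):
        a = scalar_metrics(ConfusionMatrix(tp=30, fp=7, tn=50, fn=13))
        b = scalar_metrics(ConfusionMatrix(tp=50, fp=13, tn=30, fn=7))
        assert a.acc == pytest.approx(b.acc)
        assert a.mcc == pytest.approx(b.mcc)
        assert a.sn == pytest.approx(b.sp)  # SN<->SP under relabeling

    def test_acc_identity_exact(self):
        cm = ConfusionMatrix(tp=3, fp=2, tn=4, fn=1)
        assert scalar_metrics(cm).acc == (3 + 4) / 10


class TestCurves:
    def test_perfect_separation(self):
        y = [0, 0, 1, 1]
        s = [0.1, 0.2, 0.8, 0.9]
        _, auroc = roc_curve(y, s)
        _, auprc = pr_curve(y, s)
        assert auroc == 1.0 and auprc == 1.0

    def test_anticorrelated(self):
        y = [1, 1, 0, 0]
        s = [0.1, 0.2, 0.8, 0.9]
        _, auroc = roc_curve(y, s)
        assert auroc == 0.0

    def test_constant_scores_auprc_is_prevalence(self):
        y = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        _, auprc = pr_curve(y, [0.5] * 10)
        assert auprc == pytest.approx(0.3)

    def test_single_class_undefined(self):
        pts, auroc = roc_curve([1, 1, 1], [0.1, 0.5, 0.9])
        assert auroc is None
        _, auprc = pr_curve([0, 0], [0.1, 0.2])
        assert auprc is None

    def test_roc_monotone(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 50)
        s = rng.random(50)
        pts, _ = roc_curve(y, s)
        xs, ys = zip(*pts)
        assert all(b >= a for a, b in zip(xs, xs[1:]))
        assert all(b >= a for a, b in zip(ys, ys[1:]))

    @given(st.integers(0, 2**16))
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_auroc_equals_mann_whitney(self, seed):
        """Trapezoid AUROC equals the normalized Mann-Whitney U statistic."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        s = np.round(rng.random(n), 1)  # coarse grid forces score ties
        _, auroc = roc_curve(y, s)
        pos, neg = s[y == 1], s[y == 0]
        u = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert auroc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)

    def test_auroc_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(11)
        y = rng.integers(0, 2, 200)
        s = rng.random(200)
        _, auroc = roc_curve(y, s)
        assert auroc == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_pr_matches_threshold_brute_force(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 10)
        y[:2] = 1
        s = np.round(rng.random(10), 1)
        pts, _ = pr_curve(y, s)
        got = {(round(r, 9), round(p, 9)) for r, p in pts[1:]}  # drop recall-0 anchor
        expected = set()
        for thr in np.unique(s):
            pred = s >= thr
            tp = int(((y == 1) & pred).sum())
            expected.add(
                (round(tp / (y == 1).sum(), 9), round(tp / pred.sum(), 9))
            )
        assert got == expected


class TestSolveConfusionMatrix:
    def test_unique_solution_at_1000_samples(self):
        sols = solve_confusion_matrix(1000, acc=91.60, sn=96.71, sp=87.32)
        assert len(sols) == 1
        cm = sols[0]
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (441, 15, 69, 475)

    def test_metric_identity_round_trip(self):
        """Re-applying the metric formulas reproduces the printed tuple."""
        for n, acc, sn, sp in [
            (1000, 91.60, 96.71, 87.32),
            (2000, 87.15, 83.84, 88.53),
            (1000, 74.00, 55.95, 82.15),
        ]:
            for cm in solve_confusion_matrix(n, acc, sn, sp):
                rep = scalar_metrics(cm)
                assert evaluate._round2(100 * rep.acc) == acc
                assert evaluate._round2(100 * rep.sn) == sn
                assert evaluate._round2(100 * rep.sp) == sp

    def test_inconsistent_tuple_empty(self):
        assert solve_confusion_matrix(10, acc=99.99, sn=1.00, sp=1.00) == []

    def test_input_validation(self):
        with pytest.raises(ValueError):
            solve_confusion_matrix(1, 50, 50, 50)
        with pytest.raises(ValueError):
            solve_confusion_matrix(100, 150, 50, 50)


class TestReportSerialization:
    def test_report_files(self, tmp_path):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 100)
        s = np.clip(y * 0.6 + rng.random(100) * 0.4, 0, 1)
        rep = evaluate.evaluate_predictions(y, s)
        evaluate.write_report(rep, tmp_path / "report")
        evaluate.write_curves(rep, tmp_path / "curves")
        import json

        d = json.loads((tmp_path / "report.json").read_text())
        assert set(d["metrics"]) >= {"acc", "sn", "sp", "mcc", "precision", "f1"}
        header = (tmp_path / "report.tsv").read_text().splitlines()[0]
        assert header == "ACC\tSN\tSP\tMCC\tPRECISION\tF-1".replace("F-1", "F1")
        assert (tmp_path / "curves_roc.tsv").exists()
        assert (tmp_path / "curves_pr.tsv").exists()
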