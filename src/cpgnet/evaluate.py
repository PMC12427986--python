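"""Binary-classification evaluation: confusion matrix, scalar metrics, curves.

Positive class is *methylated* throughout.  Scalar metrics follow the
standard confusion-matrix definitions

    SN = TP/(TP+FN)            SP = TN/(TN+FP)
    ACC = (TP+TN)/total        precision = TP/(TP+FP)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    F1  = 2*precision*SN / (precision + SN)

Metrics with a zero denominator are reported as None (an explicit
"undefined" marker) rather than coerced to 0, so degenerate classifiers
stay visible.  ROC and PR curves sweep the distinct score values (ties
grouped) and areas use the trapezoidal rule.

``solve_confusion_matrix`` inverts a printed (ACC, SN, SP) tuple at 2-dp
rounding back to the integer confusion matrices consistent with it — a
verification utility for published results tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqdata import CLASS_ORDER, METHYLATED

_POSITIVE_INDEX = CLASS_ORDER.index(METHYLATED)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvalReport:
    """Scalar metrics (fractions in [0,1], None = undefined) plus curves."""

    cm: ConfusionMatrix
    sn: float | None = None
    sp: float | None = None
    acc: float | None = None
    mcc: float | None = None
    precision: float | None = None
    f1: float | None = None
    auroc: float | None = None
    auprc: float | None = None
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    pr_points: list[tuple[float, float]] = field(default_factory=list)


def _as_indices(y: Sequence) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "iub":
        out = y.astype(int)
        if not np.isin(out, (0, 1)).all():
            raise ValueError("integer labels must be 0 or 1")
        return out
    try:
        return np.array([CLASS_ORDER.index(v) for v in y], dtype=int)
    except ValueError:
        raise ValueError(f"unknown label among {set(map(str, y))}") from None


def confusion(y_true: Sequence, y_pred: Sequence) -> ConfusionMatrix:
    """Tally a 2x2 confusion matrix (positive = methylated = class 1)."""
    t, p = _as_indices(y_true), _as_indices(y_pred)
    if len(t) != len(p) or len(t) == 0:
        raise ValueError("y_true and y_pred must have equal nonzero length")
    pos = _POSITIVE_INDEX
    return ConfusionMatrix(
        tp=int(((t == pos) & (p == pos)).sum()),
        fp=int(((t != pos) & (p == pos)).sum()),
        tn=int(((t != pos) & (p != pos)).sum()),
        fn=int(((t == pos) & (p != pos)).sum()),
    )


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def scalar_metrics(cm: ConfusionMatrix) -> EvalReport:
    """All scalar metrics from a confusion matrix; zero denominators -> None."""
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    sn = _ratio(tp, tp + fn)
    sp = _ratio(tn, tn + fp)
    acc = _ratio(tp + tn, cm.total)
    precision = _ratio(tp, tp + fp)
    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = None if mcc_den == 0 else (tp * tn - fp * fn) / np.sqrt(float(mcc_den))
    if precision is None or sn is None or (precision + sn) == 0:
        f1 = None
    else:
        f1 = 2 * precision * sn / (precision + sn)
    return EvalReport(cm=cm, sn=sn, sp=sp, acc=acc, mcc=mcc, precision=precision, f1=f1)


def roc_curve(
    y_true: Sequence, scores: Sequence[float]
) -> tuple[list[tuple[float, float]], float | None]:
    """ROC points (FPR, TPR) over distinct thresholds and the trapezoid AUROC.

    Returns (points, None) when only one class is present.
    """
    t = _as_indices(y_true)
    s = np.asarray(scores, dtype=float)
    if len(t) != len(s):
        raise ValueError("labels and scores must have equal length")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    n_pos = int((t == _POSITIVE_INDEX).sum())
    n_neg = len(t) - n_pos
    if n_pos == 0 or n_neg == 0:
        return [], None
    order = np.argsort(-s, kind="stable")
    s_sorted, t_sorted = s[order], t[order]
    tps = np.cumsum(t_sorted == _POSITIVE_INDEX)
    fps = np.cumsum(t_sorted != _POSITIVE_INDEX)
    # keep one point per distinct score (the last index of each tie group)
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auroc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auroc


def pr_curve(
    y_true: Sequence, scores: Sequence[float]
) -> tuple[list[tuple[float, float]], float | None]:
    """PR points (recall, precision) over distinct thresholds, trapezoid AUPRC.

    The recall = 0 endpoint takes the first threshold's precision.  With a
    constant score the curve collapses to the single point
    (recall 1, precision = positive fraction), so the area equals that
    fraction.  Returns (points, None) when there are no positives.
    """
    t = _as_indices(y_true)
    s = np.asarray(scores, dtype=float)
    if len(t) != len(s):
        raise ValueError("labels and scores must have equal length")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    n_pos = int((t == _POSITIVE_INDEX).sum())
    if n_pos == 0:
        return [], None
    order = np.argsort(-s, kind="stable")
    s_sorted, t_sorted = s[order], t[order]
    tps = np.cumsum(t_sorted == _POSITIVE_INDEX)
    pred_pos = np.arange(1, len(s_sorted) + 1)
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    recall = tps[distinct] / n_pos
    precision = tps[distinct] / pred_pos[distinct]
    recall = np.r_[0.0, recall]
    precision = np.r_[precision[0], precision]
    auprc = float(np.trapezoid(precision, recall))
    return list(zip(recall.tolist(), precision.tolist())), auprc


def evaluate_predictions(
    y_true: Sequence, scores: Sequence[float], y_pred: Sequence | None = None
) -> EvalReport:
    """Full report: confusion at the argmax labels plus both curves.

    ``scores`` are positive-class (methylated) probabilities; when
    ``y_pred`` is omitted, scores >= 0.5 predict methylated (probability
    ties at exactly 0.5 go to the unmethylated class, matching the model's
    argmax tie-break toward class index 0 at p = (0.5, 0.5)).
    """
    s = np.asarray(scores, dtype=float)
    if y_pred is None:
        y_pred = (s > 0.5).astype(int)
    rep = scalar_metrics(confusion(y_true, y_pred))
    rep.roc_points, rep.auroc = roc_curve(y_true, s)
    rep.pr_points, rep.auprc = pr_curve(y_true, s)
    return rep


def _round2(x: float) -> float:
    """Half-up rounding to 2 decimals, matching printed results tables."""
    return float(
        Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    )


def solve_confusion_matrix(
    n: int, acc: float, sn: float, sp: float
) -> list[ConfusionMatrix]:
    """All integer confusion matrices on n samples printing as (ACC, SN, SP).

    Inputs are percentages printed at 2 dp.  Exhaustive search over the
    positive count P with TP = round(SN*P/100), TN = round(SP*(n-P)/100);
    a candidate is kept when its recomputed ACC/SN/SP all round (half-up,
    2 dp) back to the inputs.  An empty result signals an inconsistent
    tuple.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    for name, v in (("acc", acc), ("sn", sn), ("sp", sp)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} = {v} outside [0, 100]")
    solutions = []
    for p_count in range(1, n):
        neg = n - p_count
        tp = int(round(sn * p_count / 100.0))
        tn = int(round(sp * neg / 100.0))
        cm = ConfusionMatrix(tp=tp, fp=neg - tn, tn=tn, fn=p_count - tp)
        got = scalar_metrics(cm)
        if (
            _round2(100 * got.acc) == _round2(acc)
            and _round2(100 * got.sn) == _round2(sn)
            and _round2(100 * got.sp) == _round2(sp)
        ):
            solutions.append(cm)
    return solutions


def report_to_dict(rep: EvalReport) -> dict:
    """JSON-ready dict: fractions plus a 0-100 convenience block."""
    scalars = {
        "acc": rep.acc, "sn": rep.sn, "sp": rep.sp, "mcc": rep.mcc,
        "precision": rep.precision, "f1": rep.f1,
        "auroc": rep.auroc, "auprc": rep.auprc,
    }
    return {
        "confusion": {"tp": rep.cm.tp, "fp": rep.cm.fp, "tn": rep.cm.tn, "fn": rep.cm.fn},
        "metrics": scalars,
        "metrics_percent": {
            k: (None if v is None else _round2(100 * v)) for k, v in scalars.items()
        },
    }


#: column order used by published comparison tables
TABLE_COLUMNS = ("acc", "sn", "sp", "mcc", "precision", "f1")


def write_report(rep: EvalReport, path: str | Path) -> None:
    """Serialize a report as JSON plus a flat one-row TSV of the six columns."""
    path = Path(path)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(report_to_dict(rep), fh, indent=1)
    pct = report_to_dict(rep)["metrics_percent"]
    with open(path.with_suffix(".tsv"), "w") as fh:
        fh.write("\t".join(c.upper() for c in TABLE_COLUMNS) + "\n")
        fh.write("\t".join(
            "NA" if pct[c] is None else f"{pct[c]:.2f}" for c in TABLE_COLUMNS
        ) + "\n")


def write_curves(rep: EvalReport, path_prefix: str | Path) -> None:
    """Write ROC and PR points as two-column TSVs for external plotting."""
    prefix = Path(path_prefix)
    with open(f"{prefix}_roc.tsv", "w") as fh:
        fh.write("fpr\ttpr\n")
        for x, y in rep.roc_points:
            fh.write(f"{x:.6g}\t{y:.6g}\n")
    with open(f"{prefix}_pr.tsv", "w") as fh:
        fh.write("recall\tprecision\n")
        for x, y in rep.pr_points:
            fh.write(f"{x:.6g}\t{y:.6g}\n")
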