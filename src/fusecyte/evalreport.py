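"""Metrics, generalization-gap / improvement arithmetic, and summary tables.

All percentages are reported on the 0–100 scale to 2 decimals.  Conventions,
fixed for determinism: argmax ties resolve to the lowest class index; a
precision or recall with an empty denominator is defined as 0 (flagged in the
report rather than NaN, keeping macro averages stable on small folds);
macro scores are unweighted means over the three classes.

The generalization gap is validation accuracy minus test accuracy in
percentage points; relative improvement is ``100 * (candidate - reference) /
reference``, displayed to one decimal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from fusecyte.constants import CLASSES, N_CLASSES

__all__ = [
    "MetricsReport", "compute_metrics", "metrics_from_predictions", "pr_curve",
    "pr_auc", "generalization_gap", "relative_improvement", "build_summary",
]


@dataclass
class MetricsReport:
    """Accuracy, per-class and macro P/R/F1, confusion matrix, PR curves."""

    n: int
    accuracy: float
    per_class: dict[str, dict[str, float]]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: np.ndarray
    pr_curves: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    n_unparseable: int = 0
    zero_division_classes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n": self.n, "accuracy": self.accuracy, "per_class": self.per_class,
            "macro_precision": self.macro_precision, "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1, "confusion": self.confusion.tolist(),
            "pr_curves": {k: [list(p) for p in v] for k, v in self.pr_curves.items()},
            "n_unparseable": self.n_unparseable,
            "zero_division_classes": self.zero_division_classes,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def metrics_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> MetricsReport:
    """Report from hard predictions; ``y_pred = -1`` marks unparseable outputs.

    Unparseable predictions count against accuracy but enter no class's
    predicted-positive tally, so they lower recall of their true class
    without touching any precision denominator.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    n = y_true.size
    if n == 0:
        raise ValueError("empty input")
    confusion = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    valid = y_pred >= 0
    np.add.at(confusion, (y_true[valid], y_pred[valid]), 1)
    accuracy = 100.0 * np.trace(confusion) / n

    per_class: dict[str, dict[str, float]] = {}
    zero_div: list[str] = []
    precs, recs, f1s = [], [], []
    for c, name in enumerate(CLASSES):
        tp = confusion[c, c]
        pp = confusion[:, c].sum()
        pos = int(np.sum(y_true == c))
        if pp == 0 or pos == 0:
            zero_div.append(name)
        prec = tp / pp if pp else 0.0
        rec = tp / pos if pos else 0.0
        f1 = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
        per_class[name] = {"precision": 100.0 * prec, "recall": 100.0 * rec,
                           "f1": 100.0 * f1}
        precs.append(prec)
        recs.append(rec)
        f1s.append(f1)
    return MetricsReport(
        n=n, accuracy=round(accuracy, 10), per_class=per_class,
        macro_precision=100.0 * float(np.mean(precs)),
        macro_recall=100.0 * float(np.mean(recs)),
        macro_f1=100.0 * float(np.mean(f1s)),
        confusion=confusion, n_unparseable=int(np.sum(~valid)),
        zero_division_classes=zero_div)


def compute_metrics(y_true: np.ndarray, probs: np.ndarray,
                    include_pr: bool = True) -> MetricsReport:
    """Full metrics report from class probabilities.

    Predictions are the per-row argmax (ties resolve to the lowest class
    index).  PR curves are computed one-vs-rest for every class present in
    ``y_true``.
    """
    y_true = np.asarray(y_true, dtype=int)
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    if y_true.size == 0:
        raise ValueError("empty input")
    if probs.shape != (y_true.size, N_CLASSES):
        raise ValueError(f"probs must be ({y_true.size}, {N_CLASSES})")
    report = metrics_from_predictions(y_true, probs.argmax(axis=1))
    if include_pr:
        for c, name in enumerate(CLASSES):
            if np.any(y_true == c):
                report.pr_curves[name] = pr_curve(y_true, probs, c)
    return report


def pr_curve(y_true: np.ndarray, probs: np.ndarray,
             class_index: int) -> list[tuple[float, float]]:
    """One-vs-rest precision–recall sweep over all distinct score thresholds.

    Thresholds descend, so recall is non-decreasing along the returned list
    of ``(recall, precision)`` points.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.atleast_2d(np.asarray(probs, dtype=np.float64))[:, class_index]
    positive = y_true == class_index
    n_pos = int(positive.sum())
    if n_pos == 0:
        raise ValueError(f"class {class_index} absent from y_true; recall undefined")
    points: list[tuple[float, float]] = []
    for tau in sorted(set(scores), reverse=True):
        pred_pos = scores >= tau
        tp = int(np.sum(pred_pos & positive))
        points.append((tp / n_pos, tp / int(pred_pos.sum())))
    return points


def pr_auc(points: Sequence[tuple[float, float]]) -> float:
    """Step-integral of precision over recall (average-precision convention)."""
    area = 0.0
    prev_r = 0.0
    for r, p in points:
        area += (r - prev_r) * p
        prev_r = r
    return area


def generalization_gap(val_accuracy: float, test_accuracy: float) -> float:
    """Validation accuracy minus test accuracy, both in percent."""
    for v in (val_accuracy, test_accuracy):
        if not 0.0 <= v <= 100.0:
            raise ValueError("accuracies must lie in [0, 100]")
    return round(val_accuracy - test_accuracy, 10)


def relative_improvement(candidate: float, reference: float) -> float:
    """``100 * (candidate - reference) / reference``, rounded to 1 decimal."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return round(100.0 * (candidate - reference) / reference, 1)


def build_summary(runs: Sequence[dict], reference_label: str | None = None,
                  out_csv: str | Path | None = None,
                  out_fig: str | Path | None = None) -> pd.DataFrame:
    """Consolidated cross-approach summary table (one row per approach).

    Each run is a mapping with keys ``label``, ``category``,
    ``val_accuracy``, ``test_accuracy`` and ``f1`` (percent scales).  The
    improvement column is relative to ``reference_label`` (default: the run
    with the lowest test accuracy); a single-run table leaves it empty.
    Optionally writes a CSV and a grouped-bar comparison figure of accuracy
    and macro-F1 per approach.
    """
    if not runs:
        raise ValueError("at least one run is required")
    seen: dict[str, int] = {}
    rows = []
    for run in runs:
        label = str(run["label"])
        if label in seen:
            seen[label] += 1
            warnings.warn(f"duplicate run label {label!r}; suffixing")
            label = f"{label}_{seen[run['label']]}"
        else:
            seen[label] = 1
        val = run.get("val_accuracy")
        test = float(run["test_accuracy"])
        rows.append({
            "label": label,
            "category": run.get("category", ""),
            "best_accuracy": test,
            "best_f1": float(run.get("f1", float("nan"))),
            "generalization_gap": (generalization_gap(float(val), test)
                                   if val is not None else float("nan")),
        })
    df = pd.DataFrame(rows).sort_values(
        ["category", "best_accuracy"], ascending=[True, False]).reset_index(drop=True)

    if len(df) > 1:
        if reference_label is None:
            reference_label = df.loc[df["best_accuracy"].idxmin(), "label"]
        ref_acc = float(df.loc[df["label"] == reference_label, "best_accuracy"].iloc[0])
        df["relative_improvement"] = [
            float("nan") if lbl == reference_label
            else relative_improvement(acc, ref_acc)
            for lbl, acc in zip(df["label"], df["best_accuracy"])]
    else:
        df["relative_improvement"] = float("nan")

    if out_csv is not None:
        df.to_csv(out_csv, index=False, float_format="%.2f")
    if out_fig is not None:
        _comparison_figure(df, out_fig)
    return df


def _comparison_figure(df: pd.DataFrame, path: str | Path) -> None:
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    fig = Figure(figsize=(max(6, 1.6 * len(df)), 4))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    x = np.arange(len(df))
    ax.bar(x - 0.2, df["best_accuracy"], width=0.4, label="accuracy (%)")
    ax.bar(x + 0.2, df["best_f1"], width=0.4, label="macro F1")
    ax.set_xticks(x)
    ax.set_xticklabels(df["label"], rotation=20, ha="right", fontsize=8)
    ax.set_ylabel("percent")
    ax.set_title("Performance comparison across approaches")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
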