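"""Per-class efficiency metrics and run-level report tables.

Every classifier decision is a *set* of classes (a singleton for non-fused
models; possibly larger after high-level fusion).  Per class, one-vs-rest
confusion counts treat a sample as a positive prediction for class c
whenever c is in its predicted set, so a multiple discrimination adds a
false positive to each spurious class.  Per-class quality is summarized by

    SEN = TP / (TP + FN),   SPE = TN / (TN + FP),
    efficiency = sqrt(SEN * SPE),

and the overall accuracy is the fraction of samples whose true class is in
the predicted set (multiple discrimination therefore never lowers accuracy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ClassMetrics:
    """One class's confusion counts, SEN/SPE and efficiency."""

    class_id: int
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def sen(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def spe(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def efficiency(self) -> float:
        return efficiency(self.sen, self.spe)


def _as_sets(predicted_sets) -> list[frozenset]:
    out = []
    for s in predicted_sets:
        if isinstance(s, (set, frozenset, list, tuple, np.ndarray)):
            fs = frozenset(int(c) for c in s)
        else:
            fs = frozenset([int(s)])
        if not fs:
            raise ValueError("empty predicted set")
        out.append(fs)
    return out


def confusion_counts(true_labels, predicted_sets, classes=None) -> dict[int, ClassMetrics]:
    """One-vs-rest TP/TN/FP/FN per class for set-valued predictions."""
    true = [int(t) for t in true_labels]
    preds = _as_sets(predicted_sets)
    if len(true) != len(preds):
        raise ValueError("true labels and predictions differ in length")
    if classes is None:
        classes = sorted(set(true) | {c for s in preds for c in s})
    out: dict[int, ClassMetrics] = {}
    for c in classes:
        tp = sum(1 for t, s in zip(true, preds) if t == c and c in s)
        fn = sum(1 for t, s in zip(true, preds) if t == c and c not in s)
        fp = sum(1 for t, s in zip(true, preds) if t != c and c in s)
        tn = sum(1 for t, s in zip(true, preds) if t != c and c not in s)
        out[int(c)] = ClassMetrics(int(c), tp, tn, fp, fn)
    return out


def efficiency(sen: float, spe: float) -> float:
    """Geometric mean of sensitivity and specificity."""
    if not (0.0 <= sen <= 1.0 and 0.0 <= spe <= 1.0):
        raise ValueError("SEN and SPE must lie in [0,1]")
    return math.sqrt(sen * spe)


def accuracy(true_labels, predicted_sets) -> float:
    """Fraction of samples whose true class is in the predicted set."""
    true = [int(t) for t in true_labels]
    preds = _as_sets(predicted_sets)
    if len(true) != len(preds):
        raise ValueError("true labels and predictions differ in length")
    return sum(1 for t, s in zip(true, preds) if t in s) / len(true)


def metrics_row(true_labels, predicted_sets, classes) -> dict[str, float]:
    """One report row: per-class efficiency plus overall accuracy."""
    counts = confusion_counts(true_labels, predicted_sets, classes=classes)
    row = {f"Class{c}": counts[c].efficiency for c in classes}
    row["Accuracy"] = accuracy(true_labels, predicted_sets)
    return row


def build_report(results: dict[str, dict[str, tuple]], classes,
                 meta: dict | None = None) -> dict[str, pd.DataFrame]:
    """Assemble calibration/validation tables of per-class efficiency + accuracy.

    ``results`` maps a row label (dataset x model, e.g. ``"FT-MIR / PLS-DA"``)
    to ``{"calibration": (true, predicted_sets), "validation": (...)}``.
    Returns one DataFrame per set tag; ``meta`` (seeds, config, warnings) is
    attached to each frame's ``attrs``.
    """
    tables: dict[str, pd.DataFrame] = {}
    for tag in ("calibration", "validation"):
        rows = {}
        for label, sets in results.items():
            if tag not in sets:
                continue
            true, preds = sets[tag]
            rows[label] = metrics_row(true, preds, classes)
        df = pd.DataFrame.from_dict(rows, orient="index")
        if meta:
            df.attrs.update(meta)
        tables[tag] = df
    return tables


def format_percent(fraction: float) -> str:
    """Render an accuracy fraction the way the report tables print it."""
    return f"{100.0 * fraction:.2f}%"
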