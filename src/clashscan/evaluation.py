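"""Confusion-matrix bookkeeping and binary performance measures.

The positive class is "clash": TP counts clash-causing variants
predicted as not fitting, TN counts structure-compatible variants
predicted as fitting.  Six scores are computed — accuracy, PPV, NPV,
sensitivity (TPR), specificity (TNR) and the Matthews correlation
coefficient — each reported as None when its denominator is zero rather
than silently zero-filled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "PerformanceScores",
    "confusion",
    "scores",
    "average_scores",
    "read_label_table",
    "round2",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


@dataclass(frozen=True)
class PerformanceScores:
    accuracy: float | None
    ppv: float | None
    npv: float | None
    tpr: float | None
    tnr: float | None
    mcc: float | None

    def display(self) -> dict[str, str]:
        """Two-decimal, half-up rounding for tabular display."""
        out = {}
        for name in ("accuracy", "ppv", "npv", "tpr", "tnr", "mcc"):
            v = getattr(self, name)
            out[name] = "-" if v is None else str(round2(v))
        return out


def round2(value: float) -> Decimal:
    return Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)


def _verdict(p) -> str:
    v = getattr(p, "verdict", p)
    if v not in ("clash", "fits"):
        raise ValueError(f"verdict must be 'clash' or 'fits', got {v!r}")
    return v


def confusion(predictions, labels) -> ConfusionMatrix:
    """Count TP/FP/TN/FN with clash as the positive class.

    ``predictions`` may be Prediction objects or plain verdict strings;
    ``labels`` are "clash"/"fits" ground truths in the same order.
    """
    if len(predictions) != len(labels):
        raise ValueError(
            f"{len(predictions)} predictions vs {len(labels)} labels"
        )
    tp = fp = tn = fn = 0
    for p, lab in zip(predictions, labels):
        pred, truth = _verdict(p), _verdict(lab)
        if truth == "clash":
            if pred == "clash":
                tp += 1
            else:
                fn += 1
        else:
            if pred == "clash":
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp, fp, tn, fn)


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def scores(cm: ConfusionMatrix) -> PerformanceScores:
    """The six performance measures; None where a denominator is zero."""
    if cm.total == 0:
        raise ValueError("cannot score an empty confusion matrix")
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    mcc_den = math.sqrt(
        float(tp + fn) * float(tp + fp) * float(tn + fn) * float(tn + fp)
    )
    return PerformanceScores(
        accuracy=_ratio(tp + tn, cm.total),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        tpr=_ratio(tp, tp + fn),
        tnr=_ratio(tn, tn + fp),
        mcc=None if mcc_den == 0 else (tp * tn - fp * fn) / mcc_den,
    )


def average_scores(matrices: list[ConfusionMatrix], mode: str = "macro") -> PerformanceScores:
    """Summary row over datasets.

    mode="macro": unweighted mean of per-dataset scores (None values are
    skipped).  mode="pooled": recompute scores from summed counts.
    """
    if mode == "pooled":
        total = ConfusionMatrix()
        for cm in matrices:
            total = total + cm
        return scores(total)
    if mode != "macro":
        raise ValueError(f"unknown averaging mode {mode!r}")
    per = [scores(cm) for cm in matrices]
    vals = {}
    for name in ("accuracy", "ppv", "npv", "tpr", "tnr", "mcc"):
        defined = [getattr(s, name) for s in per if getattr(s, name) is not None]
        vals[name] = sum(defined) / len(defined) if defined else None
    return PerformanceScores(**vals)


def read_label_table(path) -> pd.DataFrame:
    """Read a labelled-variant TSV: structure_id, chain, position, icode,
    to_aa, label (clash|fits)."""
    df = pd.read_csv(path, sep="\t", dtype={"chain": str, "icode": str}, keep_default_na=False)
    required = {"structure_id", "chain", "position", "icode", "to_aa", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"label table lacks columns: {sorted(missing)}")
    bad = set(df["label"]) - {"clash", "fits"}
    if bad:
        raise ValueError(f"labels must be 'clash' or 'fits', found {sorted(bad)}")
    return df
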