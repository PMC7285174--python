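"""Sensitivity/specificity/balanced-accuracy metrics and ROC operating point.

Shockable (SH) detection is the "positive" task: Se = TP / (TP + FN) over
shockable cases, Sp = TN / (TN + FP) over nonshockable cases, and
BAC = (Se + Sp) / 2.  Because the network emits p -> 0 for shockable and
p -> 1 for nonshockable, a strip is called shockable when its probability
falls *below* the decision threshold; the operating point is the ROC point
with maximal Se + Sp (ties broken toward higher Se), not a fixed 0.5.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import Y_SH, DatasetSplit, build_split
from .synthetic import ECGStrip, Source


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int  # correctly detected shockable
    fn: int  # shockable called nonshockable
    tn: int  # correctly detected nonshockable
    fp: int  # nonshockable called shockable


def confusion(scores: np.ndarray, y: np.ndarray, threshold: float) -> ConfusionCounts:
    """Counts at a given threshold: predicted SH iff score < threshold."""
    scores = np.asarray(scores, dtype=np.float64)
    sh = np.asarray(y) == Y_SH
    pred_sh = scores < threshold
    return ConfusionCounts(
        tp=int(np.sum(sh & pred_sh)),
        fn=int(np.sum(sh & ~pred_sh)),
        tn=int(np.sum(~sh & ~pred_sh)),
        fp=int(np.sum(~sh & pred_sh)),
    )


def se_sp(counts: ConfusionCounts) -> tuple[float, float]:
    """Sensitivity and specificity in percent."""
    if counts.tp + counts.fn == 0:
        raise ValueError("no shockable cases: sensitivity undefined")
    if counts.tn + counts.fp == 0:
        raise ValueError("no nonshockable cases: specificity undefined")
    se = 100.0 * counts.tp / (counts.tp + counts.fn)
    sp = 100.0 * counts.tn / (counts.tn + counts.fp)
    return se, sp


def bac(se: float, sp: float) -> float:
    """Balanced accuracy: arithmetic mean of Se and Sp (percent)."""
    return (se + sp) / 2.0


@dataclasses.dataclass
class ROCCurve:
    thresholds: np.ndarray  # increasing; SH decided when score < threshold
    se: np.ndarray          # percent
    sp: np.ndarray          # percent
    selected: int           # index of the max-BAC operating point

    @property
    def selected_threshold(self) -> float:
        return float(self.thresholds[self.selected])

    @property
    def selected_bac(self) -> float:
        return bac(float(self.se[self.selected]), float(self.sp[self.selected]))


def roc_bac_max(scores: np.ndarray, y: np.ndarray) -> ROCCurve:
    """Sweep all distinct scores (plus +/-inf sentinels) as thresholds.

    Selects the point maximizing Se + Sp; among ties the point with the
    highest Se (largest SH-decision region) wins.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    sh = y == Y_SH
    n_sh = int(sh.sum())
    n_nsh = int((~sh).sum())
    if n_sh == 0 or n_nsh == 0:
        raise ValueError("ROC requires both classes present")
    thresholds = np.concatenate(([-np.inf], np.unique(scores), [np.inf]))
    # cumulative counts of items strictly below each threshold
    sh_sorted = np.sort(scores[sh])
    nsh_sorted = np.sort(scores[~sh])
    tp = np.searchsorted(sh_sorted, thresholds, side="left")
    fp = np.searchsorted(nsh_sorted, thresholds, side="left")
    se = 100.0 * tp / n_sh
    sp = 100.0 * (n_nsh - fp) / n_nsh
    score = se + sp
    best = np.flatnonzero(score == score.max())
    selected = int(best[np.argmax(se[best])])
    return ROCCurve(thresholds=thresholds, se=se, sp=sp, selected=selected)


def evaluate_split(scores: np.ndarray, split: DatasetSplit,
                   threshold: float | None = None) -> pd.Series:
    """Se/Sp/BAC (percent) for one split at a fixed or ROC-selected threshold."""
    if threshold is None:
        threshold = roc_bac_max(scores, split.y).selected_threshold
    se, sp = se_sp(confusion(scores, split.y, threshold))
    return pd.Series({"Se": se, "Sp": sp, "BAC": bac(se, sp), "threshold": threshold})


def evaluate_by_duration(
    models: Mapping[float, object],
    strips: Sequence[ECGStrip],
    durations: Sequence[float] = (2.0, 3.0, 4.0, 5.0, 7.0, 10.0),
) -> pd.DataFrame:
    """Validation report per analysis duration and per source subset.

    ``models`` maps duration (s) to a fitted classifier exposing
    ``predict_proba`` over windows of that duration.  For each duration the
    operating threshold is ROC-selected on the full set, then Se/Sp/BAC are
    reported for the total set and for the Holter-like and OHCA-like
    subsets at that threshold.  Percentages are rounded to 0.1.
    """
    missing = [d for d in durations if d not in models]
    if missing:
        raise ValueError(f"missing models for durations: {missing}")
    rows = {}
    for d in durations:
        split = build_split(strips, l1_seconds=d, role="VALIDATION")
        clf = models[d]
        scores = clf.predict_proba(split.X)[:, 1]  # P(nonshockable)
        roc = roc_bac_max(scores, split.y)
        thr = roc.selected_threshold
        for subset, mask in (
            ("total", np.ones(len(split.y), dtype=bool)),
            ("holter", split.sources == Source.HOLTER_LIKE.value),
            ("ohca", split.sources == Source.OHCA_LIKE.value),
        ):
            if not mask.any():
                continue
            se, sp = se_sp(confusion(scores[mask], split.y[mask], thr))
            rows.setdefault((subset, "Se"), {})[d] = round(se, 1)
            rows.setdefault((subset, "Sp"), {})[d] = round(sp, 1)
            rows.setdefault((subset, "BAC"), {})[d] = round(bac(se, sp), 1)
    out = pd.DataFrame(rows).T
    out.index.names = ["subset", "metric"]
    out.columns.name = "duration_s"
    return out
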