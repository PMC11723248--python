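"""Splitting, confusion-matrix metrics, AUROC and bootstrap profiling.

Sensitivity/specificity/accuracy are reported as percentages with the
*observed* class sizes as denominators:

    Sn = 100 * TP / n1      Sp = 100 * TN / n0
    Ac = 100 * (TP + TN) / (n0 + n1)

AUROC is the rank-based (Mann-Whitney) area under the ROC curve with
midrank tie handling.  When a metric's denominator class is empty the
metric is reported as NaN (an explicit "undefined" marker), never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import train_test_split

__all__ = [
    "EvalReport",
    "split_dataset",
    "confusion_metrics",
    "auroc",
    "bootstrap_eval",
    "format_report_table",
]


@dataclass
class EvalReport:
    """Confusion counts and headline metrics for one data split."""

    split: str
    tp: int
    fn: int
    tn: int
    fp: int
    auroc_value: float = float("nan")

    @property
    def n1(self) -> int:
        return self.tp + self.fn

    @property
    def n0(self) -> int:
        return self.tn + self.fp

    @property
    def sn(self) -> float:
        return 100.0 * self.tp / self.n1 if self.n1 else float("nan")

    @property
    def sp(self) -> float:
        return 100.0 * self.tn / self.n0 if self.n0 else float("nan")

    @property
    def ac(self) -> float:
        total = self.n0 + self.n1
        return 100.0 * (self.tp + self.tn) / total if total else float("nan")

    def as_dict(self) -> dict:
        return {
            "split": self.split,
            "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
            "n0": self.n0, "n1": self.n1,
            "sn": round(self.sn, 1), "sp": round(self.sp, 1),
            "ac": round(self.ac, 1), "auroc": self.auroc_value,
        }


def split_dataset(
    items: Sequence, outcomes: Sequence[int], ratio: float = 0.70,
    seed: int = 0,
) -> tuple[list[int], list[int]]:
    """Stratified train/validation index split (disjoint, exhaustive)."""
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie in (0, 1)")
    y = np.asarray(outcomes, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise ValueError("each class needs at least two members to stratify")
    n_val = len(y) - int(round(ratio * len(y)))
    if n_val < classes.size:
        raise ValueError(
            f"ratio {ratio} leaves too few validation rows to stratify"
        )
    train_idx, val_idx = train_test_split(
        np.arange(len(y)), test_size=n_val, stratify=y, random_state=seed
    )
    return sorted(int(i) for i in train_idx), sorted(int(i) for i in val_idx)


def confusion_metrics(
    observed: Sequence[int], predicted: Sequence[int], split: str = "",
    scores: Sequence[float] | None = None,
) -> EvalReport:
    """Tally the confusion matrix and the Sn/Sp/Ac percentages."""
    obs = np.asarray(observed, dtype=int)
    pred = np.asarray(predicted, dtype=int)
    if obs.shape != pred.shape:
        raise ValueError(
            f"observed ({obs.shape}) and predicted ({pred.shape}) lengths "
            "differ"
        )
    if obs.size == 0:
        raise ValueError("cannot evaluate zero predictions")
    report = EvalReport(
        split=split,
        tp=int(np.sum((obs == 1) & (pred == 1))),
        fn=int(np.sum((obs == 1) & (pred == 0))),
        tn=int(np.sum((obs == 0) & (pred == 0))),
        fp=int(np.sum((obs == 0) & (pred == 1))),
    )
    if scores is not None and np.unique(obs).size == 2:
        report.auroc_value = auroc(obs, scores)
    return report


def auroc(observed: Sequence[int], scores: Sequence[float]) -> float:
    """Rank-based area under the ROC curve (Mann-Whitney, midrank ties).

    AUROC = (R1 - n1(n1+1)/2) / (n0 * n1), with R1 the midrank sum of the
    positive class.  Returns NaN when only one class is present.
    """
    y = np.asarray(observed, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("observed and scores lengths differ")
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = rankdata(s, method="average")
    r1 = float(np.sum(ranks[y == 1]))
    return (r1 - n1 * (n1 + 1) / 2.0) / (n0 * n1)


def bootstrap_eval(
    trainer: Callable[[pd.DataFrame, np.ndarray], object],
    X_train: pd.DataFrame,
    y_train: Sequence[int],
    X_val: pd.DataFrame,
    y_val: Sequence[int],
    n_boot: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap profile of a model family.

    Each iteration resamples the training rows with replacement, calls
    ``trainer(X_resampled, y_resampled)`` (a factory returning a fitted
    model with ``predict``) and records Sn/Sp on the resampled training
    rows and on the untouched validation rows.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    y_train = np.asarray(y_train, dtype=int)
    y_val = np.asarray(y_val, dtype=int)
    rng = np.random.default_rng(seed)
    n = len(y_train)
    rows = []
    for it in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if np.unique(y_train[idx]).size < 2:
            continue
        Xb = X_train.iloc[idx]
        try:
            model = trainer(Xb, y_train[idx])
        except Exception as exc:  # annotate with the iteration index
            raise RuntimeError(f"bootstrap iteration {it} failed") from exc
        rep_tr = confusion_metrics(y_train[idx], model.predict(Xb))
        rep_va = confusion_metrics(y_val, model.predict(X_val))
        rows.append(
            {"iteration": it,
             "sn_train": rep_tr.sn, "sp_train": rep_tr.sp,
             "sn_val": rep_va.sn, "sp_val": rep_va.sp}
        )
    return pd.DataFrame(rows)


def format_report_table(reports: Sequence[EvalReport], model: str = "") -> str:
    """Human-readable confusion table (observed rows x predicted cols)."""
    lines = [f"Model: {model}" if model else "Model report",
             f"{'Set':<12}{'Class':<7}{'Stat':<6}{'%':>7}{'n_j':>7}"
             f"{'pred 0':>9}{'pred 1':>9}"]
    for r in reports:
        lines.append(
            f"{r.split:<12}{'0':<7}{'Sp':<6}{r.sp:>7.1f}{r.n0:>7}"
            f"{r.tn:>9}{r.fp:>9}"
        )
        lines.append(
            f"{'':<12}{'1':<7}{'Sn':<6}{r.sn:>7.1f}{r.n1:>7}"
            f"{r.fn:>9}{r.tp:>9}"
        )
        if not np.isnan(r.auroc_value):
            lines.append(f"{'':<12}AUROC {r.auroc_value:.3f}")
    return "\n".join(lines)
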