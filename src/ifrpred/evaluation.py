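"""Classifier evaluation: confusion metrics, ROC/AUC, cutoff screening,
entry-level k-fold cross-validation, and Welch's comparison of classifier
families.  The interface-forming residue (IFR) is the positive class."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(scores, labels, cutoff: float) -> ConfusionCounts:
    """Confusion counts at a posterior cutoff (score ≥ cutoff → IFR)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pred = s >= cutoff
    return ConfusionCounts(
        tp=int(np.sum(pred & (y == 1))),
        tn=int(np.sum(~pred & (y == 0))),
        fp=int(np.sum(pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))),
    )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor
    vanishes (the random-classifier limit)."""
    num = c.tp * c.tn - c.fp * c.fn
    den = ((c.tp + c.fp) * (c.tp + c.fn)
           * (c.tn + c.fp) * (c.tn + c.fn))
    if den == 0:
        return 0.0
    return num / math.sqrt(den)


def accuracy(c: ConfusionCounts) -> float | None:
    return (c.tp + c.tn) / c.total if c.total else None


def precision(c: ConfusionCounts) -> float | None:
    """TP / predicted positives; undefined (None) with no predicted
    positives — never silently 0."""
    den = c.tp + c.fp
    return c.tp / den if den else None


def sensitivity(c: ConfusionCounts) -> float | None:
    den = c.tp + c.fn
    return c.tp / den if den else None


@dataclass
class EvalReport:
    auc: float
    roc_points: list[tuple[float, float, float]]  # (FPR, TPR, cutoff)
    max_mcc: float
    max_mcc_cutoff: float
    n_positive: int
    n_negative: int
    seed: int | None = None


class UndefinedMetricError(ValueError):
    """Raised when a metric needs both classes and one is absent."""


def roc_auc(scores, labels, seed: int | None = None) -> EvalReport:
    """ROC curve, trapezoidal AUC, and the maximum-MCC operating point.

    Thresholds sweep the distinct score values (ties grouped, so tied
    scores move along the curve together); the trapezoidal area then equals
    the Mann-Whitney concordant-pair statistic including the ½-credit for
    ties.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC needs both classes present")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    points: list[tuple[float, float, float]] = [(0.0, 0.0, math.inf)]
    best_mcc = -2.0
    best_cut = math.inf
    tp = fp = 0
    i = 0
    n = len(s_sorted)
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            j += 1
        tp += int(np.sum(y_sorted[i:j] == 1))
        fp += int(np.sum(y_sorted[i:j] == 0))
        cut = float(s_sorted[i])
        points.append((fp / n_neg, tp / n_pos, cut))
        m = mcc(ConfusionCounts(tp=tp, tn=n_neg - fp, fp=fp, fn=n_pos - tp))
        if m > best_mcc:
            best_mcc = m
            best_cut = cut
        i = j

    auc = 0.0
    for (x0, y0, _), (x1, y1, _) in zip(points, points[1:]):
        auc += (x1 - x0) * (y0 + y1) / 2.0
    return EvalReport(auc=auc, roc_points=points, max_mcc=best_mcc,
                      max_mcc_cutoff=best_cut, n_positive=n_pos,
                      n_negative=n_neg, seed=seed)


@dataclass
class FoldAssignment:
    folds: dict[str, int]  # pdb_id -> fold index
    k: int
    seed: int

    def fold_of(self, pdb_id: str) -> int:
        return self.folds[pdb_id]

    def test_ids(self, fold: int) -> list[str]:
        return sorted(i for i, f in self.folds.items() if f == fold)

    def train_ids(self, fold: int) -> list[str]:
        return sorted(i for i, f in self.folds.items() if f != fold)


def kfold_split(pdb_ids: list[str], k: int = 10, seed: int = 0
                ) -> FoldAssignment:
    """Entry-level fold assignment: shuffle with a seeded RNG, deal
    round-robin.  Splitting is by structure, never by residue, so no
    residue of one entry can appear in two folds."""
    ids = list(pdb_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate pdb_ids in fold assignment")
    if len(ids) < k:
        raise ValueError(f"need at least k={k} entries, got {len(ids)}")
    rng = np.random.default_rng(seed)
    shuffled = [ids[i] for i in rng.permutation(len(ids))]
    return FoldAssignment(
        folds={pdb_id: i % k for i, pdb_id in enumerate(shuffled)},
        k=k, seed=seed)


def cutoff_screen(scores, labels,
                  cutoffs=tuple(round(0.1 * i, 1) for i in range(1, 10))
                  ) -> list[dict]:
    """Confusion metrics at each posterior cutoff (default 0.1..0.9)."""
    rows = []
    for cut in cutoffs:
        c = confusion(scores, labels, cut)
        rows.append({
            "cutoff": cut,
            "tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn,
            "accuracy": accuracy(c),
            "precision": precision(c),
            "sensitivity": sensitivity(c),
            "mcc": mcc(c),
        })
    return rows


def welch_compare(samples_a, samples_b) -> tuple[float, float]:
    """Welch's unequal-variance two-sided t-test with Welch-Satterthwaite
    degrees of freedom.  Returns (t, p).  Two zero-variance groups with
    equal means give p = 1."""
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 samples per group")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.inf * np.sign(a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def precision_at_coverage(report: EvalReport, scores, labels,
                          coverage_levels) -> list[dict]:
    """Precision at requested sensitivity (coverage) levels.

    For each level, the cutoff achieving the smallest sensitivity ≥ level
    is selected from the ROC sweep and its precision reported; unattainable
    levels are flagged."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    out = []
    for level in coverage_levels:
        best: tuple[float, float] | None = None  # (sens, cutoff)
        for _, tpr, cut in report.roc_points[1:]:
            if tpr >= level and (best is None or tpr < best[0]):
                best = (tpr, cut)
        if best is None:
            out.append({"coverage": level, "attained": False,
                        "precision": None, "cutoff": None})
            continue
        c = confusion(s, y, best[1])
        out.append({"coverage": level, "attained": True,
                    "precision": precision(c), "cutoff": best[1],
                    "sensitivity": sensitivity(c)})
    return out


def report_to_dict(report: EvalReport) -> dict:
    return {
        "auc": report.auc,
        "max_mcc": report.max_mcc,
        "max_mcc_cutoff": report.max_mcc_cutoff,
        "n_positive": report.n_positive,
        "n_negative": report.n_negative,
        "seed": report.seed,
    }


def roc_to_tsv(report: EvalReport) -> str:
    lines = ["cutoff\tFPR\tTPR"]
    for fpr, tpr, cut in report.roc_points:
        lines.append(f"{cut:.6g}\t{fpr:.6g}\t{tpr:.6g}")
    return "\n".join(lines) + "\n"
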