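"""Descendant-aware scoring and per-class CE-vs-HCE comparison.

Annotation granularity differs between studies: one study labels a cell
"T cell", another "CD4-positive, alpha-beta T cell".  The correctness rule
used here accounts for that: a prediction is correct iff it equals the
ground-truth label **or is a descendant of it** in the ontology (a more
specific subtype).  Predicting a coarser label — a parent — or an
unrelated class is incorrect.

Per-class bookkeeping: every cell whose prediction is hierarchically
correct is remapped to its ground-truth class before the one-vs-rest
TP/FP/FN tally; this is the only rule that keeps the counts consistent
with the per-cell correctness rule.  Macro F1 is the unweighted mean of
per-class F1 (0/0 defined as 0), by default over the classes present in
the evaluation set's ground truth.

`compare_runs` performs the per-class statistical comparison between two
matched arms of training runs: paired t-test on per-class F1 differences,
Holm-Bonferroni step-down adjustment over the family of testable classes
(a class whose difference vector has zero variance is flagged untestable
and excluded from the family).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "hierarchical_match",
    "confusion",
    "macro_f1",
    "evaluation_report",
    "compare_runs",
    "ConfusionSummary",
    "EvaluationReport",
    "PerClassComparison",
]


def hierarchical_match(pred, truth, reachability: np.ndarray):
    """True iff the prediction equals the truth or is a descendant of it.

    Vectorised over equal-length arrays; ``reachability[truth, pred] == 1``
    encodes "pred is reachable from truth", which covers the diagonal.
    """
    pred = np.asarray(pred, dtype=np.int64)
    truth = np.asarray(truth, dtype=np.int64)
    out = np.asarray(reachability)[truth, pred] == 1
    return bool(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ConfusionSummary:
    """One-vs-rest true/false positive and false negative counts per class."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.tp)

    @property
    def support(self) -> np.ndarray:
        """Ground-truth cell count per class (TP + FN)."""
        return self.tp + self.fn

    def precision_recall_f1(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-class precision, recall and F1, with every 0/0 defined as 0."""
        with np.errstate(invalid="ignore", divide="ignore"):
            precision = np.where(self.tp + self.fp > 0, self.tp / (self.tp + self.fp), 0.0)
            recall = np.where(self.tp + self.fn > 0, self.tp / (self.tp + self.fn), 0.0)
            denom = precision + recall
            f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
        return precision, recall, f1


def confusion(
    preds, truths, reachability: np.ndarray, n_classes: int | None = None
) -> ConfusionSummary:
    """Tally per-class TP/FP/FN under the descendant-correct rule.

    Each hierarchically correct prediction is first remapped to its
    ground-truth class; the tally is then a standard multiclass one-vs-rest
    count.  With an edge-free reachability (identity matrix) this reduces
    to the ordinary confusion tally.
    """
    preds = np.asarray(preds, dtype=np.int64)
    truths = np.asarray(truths, dtype=np.int64)
    if preds.shape != truths.shape:
        raise ValueError("preds and truths must have equal length")
    r = np.asarray(reachability)
    if n_classes is None:
        n_classes = r.shape[0]
    if preds.size and (
        min(preds.min(), truths.min()) < 0
        or max(preds.max(), truths.max()) >= n_classes
    ):
        raise IndexError("class index out of range")
    remapped = np.where(hierarchical_match(preds, truths, r), truths, preds)
    tp = np.bincount(truths[remapped == truths], minlength=n_classes)
    fp = np.bincount(remapped[remapped != truths], minlength=n_classes)
    fn = np.bincount(truths[remapped != truths], minlength=n_classes)
    return ConfusionSummary(tp=tp, fp=fp, fn=fn)


def macro_f1(cs: ConfusionSummary, include: Sequence[int] | None = None) -> float:
    """Unweighted mean of per-class F1 over the included classes.

    ``include`` defaults to the classes with ground-truth support, so
    classes never observed in the evaluation set contribute nothing.
    """
    if include is None:
        include = np.flatnonzero(cs.support > 0)
    include = np.asarray(include, dtype=np.int64)
    if include.size == 0:
        raise ValueError("macro F1 over an empty class set is undefined")
    _, _, f1 = cs.precision_recall_f1()
    return float(f1[include].mean())


@dataclass(frozen=True)
class EvaluationReport:
    """Per-class scores, the macro F1 and the classes it averages over."""

    per_class: pd.DataFrame
    macro_f1: float
    included_classes: tuple

    def to_json(self, path: str | Path) -> None:
        payload = {
            "macro_f1": self.macro_f1,
            "included_classes": list(self.included_classes),
            "per_class": self.per_class.to_dict(orient="index"),
        }
        import json

        Path(path).write_text(json.dumps(payload, default=float))

    @classmethod
    def from_json(cls, path: str | Path) -> "EvaluationReport":
        import json

        payload = json.loads(Path(path).read_text())
        per_class = pd.DataFrame.from_dict(payload["per_class"], orient="index")
        return cls(
            per_class=per_class,
            macro_f1=payload["macro_f1"],
            included_classes=tuple(payload["included_classes"]),
        )


def evaluation_report(
    preds,
    truths,
    reachability: np.ndarray,
    include: str = "present",
    class_names: Sequence[str] | None = None,
) -> EvaluationReport:
    """Full descendant-aware report: per-class P/R/F1 and macro F1.

    ``include="present"`` averages macro F1 over classes present in the
    ground truth; ``include="all"`` averages over every class.
    """
    cs = confusion(preds, truths, reachability)
    precision, recall, f1 = cs.precision_recall_f1()
    if include == "present":
        included = np.flatnonzero(cs.support > 0)
    elif include == "all":
        included = np.arange(cs.n_classes)
    else:
        raise ValueError(f"include must be 'present' or 'all', got {include!r}")
    names = (
        list(class_names)
        if class_names is not None
        else list(range(cs.n_classes))
    )
    per_class = pd.DataFrame(
        {
            "tp": cs.tp,
            "fp": cs.fp,
            "fn": cs.fn,
            "support": cs.support,
            "precision": precision,
            "recall": recall,
            "f1": f1,
        },
        index=names,
    )
    return EvaluationReport(
        per_class=per_class,
        macro_f1=macro_f1(cs, included),
        included_classes=tuple(names[i] for i in included),
    )


@dataclass(frozen=True)
class PerClassComparison:
    """Per-class paired comparison between two arms of training runs."""

    table: pd.DataFrame  # delta_f1, t, p_raw, p_adjusted, significant, testable
    alpha: float

    @property
    def significant_classes(self) -> list:
        return list(self.table.index[self.table["significant"]])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="class")


def compare_runs(
    f1_by_class_a,
    f1_by_class_b,
    alpha: float = 0.05,
    class_names: Sequence[str] | None = None,
) -> PerClassComparison:
    """Paired per-class comparison of two matched arms (b minus a).

    Inputs are runs x classes matrices of per-class F1 from paired
    training runs (matched seeds).  For each class a two-sided paired
    t-test is applied to the difference vector; p-values are adjusted by
    Holm-Bonferroni step-down (with monotonicity enforcement) over the
    family of testable classes only.  A class whose differences have zero
    variance is untestable: its p-values are NaN and it is excluded from
    the adjustment family.
    """
    a = np.atleast_2d(np.asarray(f1_by_class_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(f1_by_class_b, dtype=np.float64))
    if a.shape != b.shape:
        raise ValueError(
            f"mismatched run matrices: {a.shape} vs {b.shape} "
            "(runs and class sets must match)"
        )
    n_runs, n_classes = a.shape
    if n_runs < 2:
        raise ValueError("at least two paired runs are required")
    diffs = b - a
    delta = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    testable = sd > 0

    t_stat = np.full(n_classes, np.nan)
    p_raw = np.full(n_classes, np.nan)
    if testable.any():
        res = stats.ttest_1samp(diffs[:, testable], 0.0, axis=0)
        t_stat[testable] = res.statistic
        p_raw[testable] = res.pvalue

    p_adj = np.full(n_classes, np.nan)
    if testable.any():
        _, adj, _, _ = multipletests(p_raw[testable], alpha=alpha, method="holm")
        p_adj[testable] = adj
    significant = np.zeros(n_classes, dtype=bool)
    significant[testable] = p_adj[testable] <= alpha

    names = list(class_names) if class_names is not None else list(range(n_classes))
    table = pd.DataFrame(
        {
            "delta_f1": delta,
            "t": t_stat,
            "p_raw": p_raw,
            "p_adjusted": p_adj,
            "significant": significant,
            "testable": testable,
        },
        index=names,
    )
    return PerClassComparison(table=table, alpha=alpha)
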