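"""Evaluation: per-class and weighted precision/recall/F-measure from
confusion matrices, chance-corrected agreement (Cohen's kappa, weighted
kappa), and cross-question summary statistics.

Conventions: a 0/0 precision or recall is reported as 0 and flagged
degenerate; F is the harmonic mean with F = 0 when P + R = 0; weighted
averages weight per-class values by actual-class support (row sums);
summary standard deviations are sample (n-1); percentages round half-up
to one decimal for report formatting.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence

import numpy as np


def round_half_up(x: float, digits: int = 1) -> float:
    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """Square counts matrix indexed [actual][predicted] over an ordered
    class list."""

    labels: list
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        k = len(self.labels)
        if k == 0:
            raise ValueError("confusion matrix needs at least one class")
        if self.counts is None:
            self.counts = np.zeros((k, k), dtype=int)
        else:
            self.counts = np.asarray(self.counts, dtype=int)
            if self.counts.shape != (k, k):
                raise ValueError("counts must be square over the class list")
            if (self.counts < 0).any():
                raise ValueError("counts must be non-negative")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def add(self, actual, predicted, n: int = 1) -> None:
        self.counts[self._index[actual], self._index[predicted]] += n

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def supports(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass(frozen=True)
class ClassMetrics:
    label: object
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_measure: float
    degenerate_precision: bool = False
    degenerate_recall: bool = False


def f_measure(p: float, r: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if p + r == 0:
        return 0.0
    return 2 * p * r / (p + r)


def class_metrics(cm: ConfusionMatrix) -> list[ClassMetrics]:
    """P = TP/(TP+FP), R = TP/(TP+FN) per class; 0/0 -> 0 with a flag."""
    if cm.total == 0:
        raise ValueError("cannot compute metrics on an empty confusion matrix")
    out: list[ClassMetrics] = []
    c = cm.counts
    for i, lab in enumerate(cm.labels):
        tp = int(c[i, i])
        fp = int(c[:, i].sum() - tp)
        fn = int(c[i, :].sum() - tp)
        deg_p = tp + fp == 0
        deg_r = tp + fn == 0
        p = 0.0 if deg_p else tp / (tp + fp)
        r = 0.0 if deg_r else tp / (tp + fn)
        out.append(
            ClassMetrics(
                label=lab, tp=tp, fp=fp, fn=fn,
                precision=p, recall=r, f_measure=f_measure(p, r),
                degenerate_precision=deg_p, degenerate_recall=deg_r,
            )
        )
    return out


def weighted_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """Support-weighted means of per-class P, R and F (supports =
    actual-class row sums)."""
    ms = class_metrics(cm)
    supports = cm.supports.astype(float)
    total = supports.sum()
    w = supports / total
    p = float(sum(wi * m.precision for wi, m in zip(w, ms)))
    r = float(sum(wi * m.recall for wi, m in zip(w, ms)))
    f = float(sum(wi * m.f_measure for wi, m in zip(w, ms)))
    return p, r, f


# ---------------------------------------------------------------------------
# Agreement
# ---------------------------------------------------------------------------


@dataclass
class AgreementTable:
    """Counts a[rater1][rater2] over an ordered class list."""

    labels: list
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("agreement table must be square over the class list")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def linear_weights(k: int) -> np.ndarray:
    """Agreement weights 1 - |i-j|/(k-1); w[i][i] = 1."""
    idx = np.arange(k)
    return 1.0 - np.abs(idx[:, None] - idx[None, :]) / (k - 1)


def quadratic_weights(k: int) -> np.ndarray:
    idx = np.arange(k)
    return 1.0 - (idx[:, None] - idx[None, :]) ** 2 / (k - 1) ** 2


def identity_weights(k: int) -> np.ndarray:
    return np.eye(k)


def cohen_kappa(at: AgreementTable) -> float:
    """kappa = (p_o - p_e) / (1 - p_e); p_e = 1 raises (undefined)."""
    n = at.total
    if n == 0:
        raise ValueError("empty agreement table")
    p = at.counts / n
    p_o = float(np.trace(p))
    p_e = float(p.sum(axis=1) @ p.sum(axis=0))
    if math.isclose(p_e, 1.0, abs_tol=1e-15):
        raise ValueError("expected agreement is 1; kappa undefined")
    return (p_o - p_e) / (1 - p_e)


def weighted_kappa(at: AgreementTable, weights: Optional[np.ndarray | str] = "linear") -> float:
    """Weighted kappa under the disagreement-weight form
    kappa_w = 1 - sum(w'_ij o_ij) / sum(w'_ij e_ij) with w' = 1 - w,
    where w is an agreement-weight matrix (w[i][i] = 1, symmetric).

    ``weights`` may be "linear", "quadratic", "identity" or an explicit
    agreement-weight matrix.  Identity weights reduce to the unweighted
    kappa.
    """
    n = at.total
    if n == 0:
        raise ValueError("empty agreement table")
    k = len(at.labels)
    if isinstance(weights, str):
        w = {"linear": linear_weights, "quadratic": quadratic_weights, "identity": identity_weights}[weights](k)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (k, k) or (w < 0).any() or (w > 1).any():
            raise ValueError("weight matrix must be k x k with entries in [0, 1]")
        if not np.allclose(w, w.T) or not np.allclose(np.diag(w), 1.0):
            raise ValueError("agreement weights must be symmetric with unit diagonal")
    wprime = 1.0 - w
    o = at.counts / n
    e = np.outer(o.sum(axis=1), o.sum(axis=0))
    denom = float((wprime * e).sum())
    if math.isclose(denom, 0.0, abs_tol=1e-15):
        raise ValueError("expected disagreement is 0; weighted kappa undefined")
    return 1.0 - float((wprime * o).sum()) / denom


# ---------------------------------------------------------------------------
# Cross-question summary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetricSummary:
    mean: float
    sd: Optional[float]  # sample (n-1); None for a single value
    min: float
    max: float


@dataclass(frozen=True)
class SummaryReport:
    per_question: list  # (question id, P, R, F)
    precision: MetricSummary
    recall: MetricSummary
    f_measure: MetricSummary


def _summary(values: Sequence[float]) -> MetricSummary:
    # exact summation keeps the result permutation-invariant
    n = len(values)
    mean = math.fsum(values) / n
    sd = math.sqrt(math.fsum((v - mean) ** 2 for v in values) / (n - 1)) if n > 1 else None
    return MetricSummary(mean=mean, sd=sd, min=min(values), max=max(values))


def summarize(per_question: Sequence[tuple[str, float, float, float]]) -> SummaryReport:
    """Mean, sample standard deviation, min and max of the per-question
    weighted P, R and F values; permutation-invariant in the input."""
    if not per_question:
        raise ValueError("nothing to summarize")
    ps = [p for _, p, _, _ in per_question]
    rs = [r for _, _, r, _ in per_question]
    fs = [f for _, _, _, f in per_question]
    return SummaryReport(
        per_question=list(per_question),
        precision=_summary(ps),
        recall=_summary(rs),
        f_measure=_summary(fs),
    )


def write_results_csv(
    path: str | Path,
    rows: Sequence[dict],
) -> None:
    """Results table in the published layout: Question, Topic, Classes,
    Method, Features, P (%), R (%), F (%), one row per question,
    percentages at one decimal (half-up)."""
    cols = ["Question", "Topic", "Classes", "Method", "Features", "P (%)", "R (%)", "F (%)"]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=cols)
        w.writeheader()
        for row in rows:
            fmt = dict(row)
            for c in ("P (%)", "R (%)", "F (%)"):
                if c in fmt and isinstance(fmt[c], float):
                    fmt[c] = f"{round_half_up(fmt[c], 1):.1f}"
            w.writerow(fmt)
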