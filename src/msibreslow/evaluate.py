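"""Multi-class diagnostic-accuracy evaluation.

Implements the categorical battery used to compare the two imaging methods
against histology: 3x3 confusion matrices over the ordinal Breslow
categories, one-vs-rest collapses with sensitivity / specificity / PPV /
NPV, micro-averaging (pool the one-vs-rest counts, then apply the binary
formulas), Cohen's kappa with an asymptotic 95% CI (Fleiss-Cohen-Everitt
large-sample variance), per-category mean squared error, and the
marginal-reconstruction utility that rebuilds a confusion matrix's diagonal
and marginals from published per-class (n, sensitivity, specificity) rows.

For a single-label multi-class problem the micro-averaged sensitivity
equals the micro-averaged PPV (both equal overall accuracy) and micro
specificity equals micro NPV; these identities are enforced as invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .classify import CATEGORIES, BreslowCategory
from .errors import InputError, ReconciliationError, UndefinedMetricError

N_CATEGORIES = len(CATEGORIES)


@dataclass(frozen=True)
class ConfusionMatrix3:
    """3x3 confusion matrix; rows = true category, columns = predicted,
    both ordered (<1 mm, 1-2 mm, >2 mm)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (N_CATEGORIES, N_CATEGORIES):
            raise InputError(f"expected a 3x3 matrix, got shape {counts.shape}")
        if np.any(counts < 0):
            raise InputError("confusion counts must be non-negative")
        counts = counts.astype(np.int64)
        if counts.sum() <= 0:
            raise InputError("confusion matrix must contain at least one observation")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def build_confusion(
    true_cats: Sequence[BreslowCategory], pred_cats: Sequence[BreslowCategory]
) -> ConfusionMatrix3:
    true_cats = list(true_cats)
    pred_cats = list(pred_cats)
    if len(true_cats) != len(pred_cats):
        raise InputError(
            f"length mismatch: {len(true_cats)} true vs {len(pred_cats)} predicted"
        )
    if not true_cats:
        raise InputError("at least one observation required")
    counts = np.zeros((N_CATEGORIES, N_CATEGORIES), dtype=np.int64)
    for t, p in zip(true_cats, pred_cats):
        counts[int(t), int(p)] += 1
    return ConfusionMatrix3(counts)


def one_vs_rest(cm: ConfusionMatrix3, k: int) -> tuple[int, int, int, int]:
    """Collapse class ``k`` against the rest: (TP, FN, FP, TN)."""
    c = cm.counts
    tp = int(c[k, k])
    fn = int(c[k, :].sum() - tp)
    fp = int(c[:, k].sum() - tp)
    tn = int(c.sum() - tp - fn - fp)
    return tp, fn, fp, tn


@dataclass(frozen=True)
class ClassMetrics:
    n: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    kappa: float
    kappa_ci: tuple[float, float]
    mse: float | None = None


def _binary_matrix(tp: int, fn: int, fp: int, tn: int) -> np.ndarray:
    return np.array([[tp, fn], [fp, tn]], dtype=np.int64)


def class_metrics(
    tp: int, fn: int, fp: int, tn: int, mse: float | None = None, alpha: float = 0.05
) -> ClassMetrics:
    """Binary diagnostic metrics plus the 2x2 Cohen's kappa for one
    one-vs-rest collapse."""
    if tp + fn == 0:
        raise UndefinedMetricError("no positive cases: sensitivity undefined")
    if fp + tn == 0:
        raise UndefinedMetricError("no negative cases: specificity undefined")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ppv = tp / (tp + fp) if tp + fp > 0 else float("nan")
    npv = tn / (tn + fn) if tn + fn > 0 else float("nan")
    two_by_two = _binary_matrix(tp, fn, fp, tn)
    kappa = cohen_kappa_counts(two_by_two)
    ci = kappa_ci_counts(two_by_two, alpha=alpha)
    return ClassMetrics(
        n=tp + fn,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        kappa=kappa,
        kappa_ci=ci,
        mse=mse,
    )


def micro_average(cm: ConfusionMatrix3) -> tuple[float, float, float, float]:
    """Pool (TP, FN, FP, TN) over the three one-vs-rest collapses, then
    apply the binary formulas to the pooled counts."""
    pooled = np.zeros(4, dtype=np.int64)
    for k in range(N_CATEGORIES):
        pooled += np.array(one_vs_rest(cm, k))
    tp, fn, fp, tn = (int(x) for x in pooled)
    return tp / (tp + fn), tn / (tn + fp), tp / (tp + fp), tn / (tn + fn)


def cohen_kappa_counts(counts: np.ndarray) -> float:
    """Cohen's kappa for a KxK count matrix: (p_o - p_e) / (1 - p_e)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        raise InputError("empty matrix")
    p = counts / n
    po = np.trace(p)
    pe = float(p.sum(axis=1) @ p.sum(axis=0))
    if pe >= 1.0:
        raise UndefinedMetricError("degenerate marginals: chance agreement is 1")
    return float((po - pe) / (1.0 - pe))


def cohen_kappa(cm: ConfusionMatrix3) -> float:
    return cohen_kappa_counts(cm.counts)


def cohen_kappa_from_marginals(
    diagonal: Sequence[float], row_sums: Sequence[float], col_sums: Sequence[float]
) -> float:
    """Kappa depends only on the diagonal and the marginals."""
    diagonal = np.asarray(diagonal, float)
    rows = np.asarray(row_sums, float)
    cols = np.asarray(col_sums, float)
    n = rows.sum()
    if not np.isclose(n, cols.sum()):
        raise InputError("row and column sums disagree on the total")
    po = diagonal.sum() / n
    pe = float(rows @ cols) / n**2
    if pe >= 1.0:
        raise UndefinedMetricError("degenerate marginals: chance agreement is 1")
    return float((po - pe) / (1.0 - pe))


def kappa_se_counts(counts: np.ndarray) -> float:
    """Large-sample standard error of Cohen's kappa
    (Fleiss, Cohen & Everitt asymptotic variance)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    p = counts / n
    rows = p.sum(axis=1)
    cols = p.sum(axis=0)
    po = np.trace(p)
    pe = float(rows @ cols)
    if pe >= 1.0:
        raise UndefinedMetricError("degenerate marginals: chance agreement is 1")
    k = counts.shape[0]
    term_a = 0.0
    for i in range(k):
        term_a += p[i, i] * ((1 - pe) - (rows[i] + cols[i]) * (1 - po)) ** 2
    term_b = 0.0
    for i in range(k):
        for j in range(k):
            if i != j:
                term_b += p[i, j] * (cols[i] + rows[j]) ** 2
    term_b *= (1 - po) ** 2
    term_c = (po * pe - 2 * pe + po) ** 2
    var = (term_a + term_b - term_c) / (n * (1 - pe) ** 4)
    return float(np.sqrt(max(var, 0.0)))


def kappa_ci_counts(counts: np.ndarray, alpha: float = 0.05) -> tuple[float, float]:
    kappa = cohen_kappa_counts(counts)
    se = kappa_se_counts(counts)
    z = norm.ppf(1.0 - alpha / 2.0)
    low = max(-1.0, kappa - z * se)
    high = min(1.0, kappa + z * se)
    return low, high


def kappa_ci(cm: ConfusionMatrix3, alpha: float = 0.05) -> tuple[float, float]:
    """95% (by default) asymptotic CI for kappa, clipped to [-1, 1]."""
    if cm.total < 10:
        raise InputError("kappa CI requires at least 10 observations")
    return kappa_ci_counts(cm.counts, alpha=alpha)


def mse_by_category(
    true_mm: Sequence[float],
    est_mm: Sequence[float],
    true_cats: Sequence[BreslowCategory],
) -> dict[BreslowCategory | str, float | None]:
    """Mean squared error of a continuous thickness estimate within each
    true clinical category and overall.  Empty categories report None."""
    true_mm = np.asarray(true_mm, float)
    est_mm = np.asarray(est_mm, float)
    cats = np.asarray([int(c) for c in true_cats])
    if not (len(true_mm) == len(est_mm) == len(cats)):
        raise InputError("true_mm, est_mm and true_cats must have equal lengths")
    sq = (est_mm - true_mm) ** 2
    out: dict[BreslowCategory | str, float | None] = {}
    for cat in CATEGORIES:
        sel = cats == int(cat)
        out[cat] = float(sq[sel].mean()) if sel.any() else None
    out["overall"] = float(sq.mean())
    return out


@dataclass(frozen=True)
class ReconstructedMarginals:
    """Diagonal, row sums and column sums recovered from per-class rows."""

    diagonal: tuple[int, int, int]
    row_sums: tuple[int, int, int]
    col_sums: tuple[int, int, int]

    @property
    def total(self) -> int:
        return int(sum(self.row_sums))


def confusion_from_class_metrics(
    ns: Sequence[int], sens: Sequence[float], spec: Sequence[float]
) -> ReconstructedMarginals:
    """Rebuild a confusion matrix's diagonal and marginals from per-class
    (n, sensitivity, specificity) rows, enforcing sum(FP) == sum(FN).

    ``diagonal_k = round(sens_k * n_k)``;
    ``FP_k = (N - n_k) - round(spec_k * (N - n_k))``.
    """
    ns = np.asarray(ns, dtype=np.int64)
    sens = np.asarray(sens, float)
    spec = np.asarray(spec, float)
    if ns.shape != (N_CATEGORIES,) or sens.shape != (N_CATEGORIES,) or spec.shape != (N_CATEGORIES,):
        raise InputError("ns, sens and spec must each have 3 entries")
    if np.any(ns <= 0):
        raise InputError("class sizes must be positive")
    if np.any((sens < 0) | (sens > 1)) or np.any((spec < 0) | (spec > 1)):
        raise InputError("sensitivity and specificity must be proportions in [0, 1]")
    total = int(ns.sum())
    diagonal = np.rint(sens * ns).astype(np.int64)
    negatives = total - ns
    fp = negatives - np.rint(spec * negatives).astype(np.int64)
    fn = ns - diagonal
    if fp.sum() != fn.sum():
        raise ReconciliationError(
            f"inconsistent rows: sum(FP) = {int(fp.sum())} but sum(FN) = {int(fn.sum())}"
        )
    col_sums = diagonal + fp
    return ReconstructedMarginals(
        diagonal=tuple(int(x) for x in diagonal),
        row_sums=tuple(int(x) for x in ns),
        col_sums=tuple(int(x) for x in col_sums),
    )


def complete_confusion(marginals: ReconstructedMarginals) -> ConfusionMatrix3:
    """Deterministically fill the off-diagonal cells of a 3x3 matrix with
    the given diagonal and marginals.

    The fill is underdetermined by one degree of freedom; among all
    non-negative integer completions we pick the one that minimizes the
    squared ordinal jump ``sum(c_ij * (i - j)^2)`` (confusions between
    adjacent thickness categories are clinically the most plausible),
    breaking remaining ties by the smallest (0,1) cell.
    """
    diag = np.asarray(marginals.diagonal, np.int64)
    rows = np.asarray(marginals.row_sums, np.int64)
    cols = np.asarray(marginals.col_sums, np.int64)
    fn = rows - diag
    fp = cols - diag
    if np.any(fn < 0) or np.any(fp < 0):
        raise ReconciliationError("diagonal exceeds a marginal")
    best = None
    best_score = None
    for c01 in range(int(fn[0]) + 1):
        c02 = int(fn[0]) - c01
        c21 = int(fp[1]) - c01
        c12 = int(fp[2]) - c02
        c10 = int(fn[1]) - c12
        c20 = int(fn[2]) - c21
        cells = (c01, c02, c10, c12, c20, c21)
        if any(v < 0 for v in cells):
            continue
        if c10 + c20 != int(fp[0]):
            continue
        m = np.array(
            [
                [diag[0], c01, c02],
                [c10, diag[1], c12],
                [c20, c21, diag[2]],
            ],
            dtype=np.int64,
        )
        score = int(sum(m[i, j] * (i - j) ** 2 for i in range(3) for j in range(3)))
        if best_score is None or score < best_score:
            best, best_score = m, score
    if best is None:
        raise ReconciliationError("no non-negative completion matches the marginals")
    return ConfusionMatrix3(best)


@dataclass(frozen=True)
class EvaluationReport:
    """Per-class and micro-averaged diagnostic metrics for one method."""

    per_class: dict[BreslowCategory, ClassMetrics]
    totals: ClassMetrics
    overall_kappa: float
    overall_kappa_ci: tuple[float, float]
    confusion: ConfusionMatrix3
    mse_overall: float | None = None

    def to_dict(self) -> dict:
        def _metrics(m: ClassMetrics) -> dict:
            return {
                "n": m.n,
                "sensitivity_pct": round(100 * m.sensitivity, 1),
                "specificity_pct": round(100 * m.specificity, 1),
                "ppv_pct": round(100 * m.ppv, 1),
                "npv_pct": round(100 * m.npv, 1),
                "kappa": round(m.kappa, 3),
                "kappa_ci": [round(x, 3) for x in m.kappa_ci],
                "mse": None if m.mse is None else round(m.mse, 4),
            }

        return {
            "per_class": {cat.label: _metrics(m) for cat, m in self.per_class.items()},
            "totals": _metrics(self.totals),
            "overall_kappa": round(self.overall_kappa, 3),
            "overall_kappa_ci": [round(x, 3) for x in self.overall_kappa_ci],
            "confusion": self.confusion.counts.tolist(),
        }


def evaluate(
    true_cats: Sequence[BreslowCategory],
    pred_cats: Sequence[BreslowCategory],
    true_mm: Sequence[float] | None = None,
    est_mm: Sequence[float] | None = None,
    alpha: float = 0.05,
) -> EvaluationReport:
    """Full evaluation of one method against histological categories.

    When the continuous estimate is supplied, per-category and overall MSE
    are included.
    """
    cm = build_confusion(true_cats, pred_cats)
    mse = None
    if true_mm is not None and est_mm is not None:
        mse = mse_by_category(true_mm, est_mm, true_cats)
    per_class = {}
    for k, cat in enumerate(CATEGORIES):
        tp, fn, fp, tn = one_vs_rest(cm, k)
        per_class[cat] = class_metrics(
            tp, fn, fp, tn, mse=None if mse is None else mse[cat], alpha=alpha
        )
    sens, spec, ppv, npv = micro_average(cm)
    overall_kappa = cohen_kappa(cm)
    ci = kappa_ci_counts(cm.counts, alpha=alpha)
    totals = ClassMetrics(
        n=cm.total,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        kappa=overall_kappa,
        kappa_ci=ci,
        mse=None if mse is None else mse["overall"],
    )
    return EvaluationReport(
        per_class=per_class,
        totals=totals,
        overall_kappa=overall_kappa,
        overall_kappa_ci=ci,
        confusion=cm,
        mse_overall=None if mse is None else mse["overall"],
    )
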