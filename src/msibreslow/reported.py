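"""Published per-class diagnostic-accuracy rows of the clinical validation
cohort, and their reconstruction.

The clinical study reported, for each imaging method, one row per Breslow
category: class size n, MSE, sensitivity, specificity, PPV, NPV, the binary
one-vs-rest Cohen's kappa and its 95% CI, plus a micro-averaged "Total"
row.  The raw confusion matrices were not published, but the per-class
rows determine the matrix diagonal and marginals exactly (and, up to one
degree of freedom, the full matrix), so the Total-row metrics and the
overall kappa can be recomputed from the per-class rows alone.  These rows
are treated as input data.
"""

from __future__ import annotations

from dataclasses import dataclass

from .classify import CATEGORIES, BreslowCategory
from .evaluate import (
    ConfusionMatrix3,
    ReconstructedMarginals,
    class_metrics,
    cohen_kappa_from_marginals,
    complete_confusion,
    confusion_from_class_metrics,
    kappa_ci_counts,
    micro_average,
    one_vs_rest,
)


@dataclass(frozen=True)
class ReportedClassRow:
    """One published per-class row (percentages as printed)."""

    category: BreslowCategory
    n: int
    mse: float
    sensitivity_pct: float
    specificity_pct: float
    ppv_pct: float
    npv_pct: float
    kappa: float
    kappa_ci: tuple[float, float]


#: OG-HFUS per-class diagnostic accuracy (clinical cohort, n = 98 evaluable).
HFUS_ROWS: tuple[ReportedClassRow, ...] = (
    ReportedClassRow(BreslowCategory.LT1, 56, 0.034, 98.2, 95.2, 96.5, 97.6, 0.937, (0.867, 1.000)),
    ReportedClassRow(BreslowCategory.MID, 15, 0.080, 80.0, 94.0, 70.6, 96.3, 0.701, (0.503, 0.900)),
    ReportedClassRow(BreslowCategory.GT2, 27, 1.02, 85.2, 98.6, 95.8, 94.6, 0.868, (0.755, 0.980)),
)

#: Reported OG-HFUS totals: micro sens/spec/PPV/NPV (%), kappa, 95% CI.
HFUS_TOTAL = (91.8, 96.0, 91.8, 96.0, 0.858, (0.763, 0.952))

#: MSI per-class diagnostic accuracy (clinical cohort, n = 99 evaluable).
MSI_ROWS: tuple[ReportedClassRow, ...] = (
    ReportedClassRow(BreslowCategory.LT1, 56, 0.64, 55.4, 93.0, 91.2, 61.5, 0.457, (0.286, 0.627)),
    ReportedClassRow(BreslowCategory.MID, 15, 0.61, 60.0, 67.9, 25.0, 90.5, 0.177, (-0.052, 0.406)),
    ReportedClassRow(BreslowCategory.GT2, 28, 3.36, 78.6, 90.1, 75.9, 91.4, 0.680, (0.517, 0.842)),
)

#: Reported MSI totals.
MSI_TOTAL = (62.6, 81.3, 62.6, 81.3, 0.440, (0.298, 0.583))


@dataclass(frozen=True)
class ReconstructedTable:
    """Aggregates recomputed from the per-class rows of one method."""

    marginals: ReconstructedMarginals
    confusion: ConfusionMatrix3
    micro_sensitivity: float
    micro_specificity: float
    micro_ppv: float
    micro_npv: float
    overall_kappa: float
    overall_kappa_ci: tuple[float, float]
    per_class_kappa: dict[BreslowCategory, float]
    sum_fp: int
    sum_fn: int


def reconstruct_table(rows: tuple[ReportedClassRow, ...]) -> ReconstructedTable:
    """Rebuild confusion diagonal/marginals from per-class rows and recompute
    every aggregate the published Total row prints."""
    ns = [r.n for r in rows]
    sens = [r.sensitivity_pct / 100.0 for r in rows]
    spec = [r.specificity_pct / 100.0 for r in rows]
    marginals = confusion_from_class_metrics(ns, sens, spec)
    cm = complete_confusion(marginals)
    micro = micro_average(cm)
    overall_kappa = cohen_kappa_from_marginals(
        marginals.diagonal, marginals.row_sums, marginals.col_sums
    )
    per_class_kappa = {}
    for k, cat in enumerate(CATEGORIES):
        tp, fn, fp, tn = one_vs_rest(cm, k)
        per_class_kappa[cat] = class_metrics(tp, fn, fp, tn).kappa
    sum_fn = sum(r - d for r, d in zip(marginals.row_sums, marginals.diagonal))
    sum_fp = sum(c - d for c, d in zip(marginals.col_sums, marginals.diagonal))
    return ReconstructedTable(
        marginals=marginals,
        confusion=cm,
        micro_sensitivity=micro[0],
        micro_specificity=micro[1],
        micro_ppv=micro[2],
        micro_npv=micro[3],
        overall_kappa=overall_kappa,
        overall_kappa_ci=kappa_ci_counts(cm.counts),
        per_class_kappa=per_class_kappa,
        sum_fp=sum_fp,
        sum_fn=sum_fn,
    )


def reconstruct_hfus() -> ReconstructedTable:
    return reconstruct_table(HFUS_ROWS)


def reconstruct_msi() -> ReconstructedTable:
    return reconstruct_table(MSI_ROWS)
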