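"""Side-by-side diagnostic accuracy of the two methods on the simulated
cohort: confusion matrices, per-class and micro-averaged sensitivity /
specificity / PPV / NPV, Cohen's kappa with 95% CI, and per-category MSE.

The MSI continuous estimate scored by the MSE is the fitted value of the
multivariate linear model; the ultrasound estimate is the measurement
itself.  Writes results/reports.json.
"""

from pathlib import Path

import numpy as np

from msibreslow.classify import BreslowCategory, categorize_thickness
from msibreslow.evaluate import evaluate
from msibreslow.io import (
    read_cohort_csv,
    read_features_csv,
    read_predictions_csv,
    write_report_json,
)
from msibreslow.regression import fit_multivariate

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort_csv(RESULTS / "cohort.csv")
    by_id = {r.lesion_id: r for r in cohort}
    feats = read_features_csv(RESULTS / "features.csv")
    true_mm = [by_id[lid].true_breslow for lid in feats["lesion_id"]]
    true_cats = [categorize_thickness(t) for t in true_mm]
    fit = fit_multivariate(feats, true_mm)

    reports = {}
    for name, pred_file, est in (
        ("MSI", "predictions_msi.csv", fit.fitted),
        ("HFUS", "predictions_hfus.csv",
         np.array([by_id[lid].hfus_measured for lid in feats["lesion_id"]])),
    ):
        preds = read_predictions_csv(RESULTS / pred_file)
        pred_cats = [BreslowCategory.from_label(l) for l in preds["predicted_category"]]
        rep = evaluate(true_cats, pred_cats, true_mm, est)
        reports[name] = rep.to_dict()
        t = rep.totals
        print(f"{name:4s}: micro sens {100*t.sensitivity:.1f}%  spec {100*t.specificity:.1f}%  "
              f"kappa {rep.overall_kappa:.3f} "
              f"(95% CI {rep.overall_kappa_ci[0]:.3f}-{rep.overall_kappa_ci[1]:.3f})  "
              f"MSE {rep.mse_overall:.2f} mm^2")

    write_report_json(reports, RESULTS / "reports.json")
    print(f"wrote {RESULTS / 'reports.json'}")


if __name__ == "__main__":
    main()
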