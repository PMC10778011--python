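"""Continuous analyses on the simulated cohort.

Per-feature Pearson correlations with Breslow thickness, then the
multivariate linear model (G, R, IR, circularity -> thickness) with its
overall F-test.  Writes results/modelfit.json.
"""

from pathlib import Path

from msibreslow.io import read_cohort_csv, read_features_csv, write_report_json
from msibreslow.regression import PREDICTORS, fit_multivariate, pearson_r

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = {r.lesion_id: r for r in read_cohort_csv(RESULTS / "cohort.csv")}
    feats = read_features_csv(RESULTS / "features.csv")
    y = [cohort[lid].true_breslow for lid in feats["lesion_id"]]

    print("univariate Pearson correlations with Breslow thickness:")
    for col in PREDICTORS:
        r, p = pearson_r(feats[col], y)
        print(f"  {col:12s} r = {r:+.3f}  (p = {p:.2e})")

    fit = fit_multivariate(feats, y)
    print(f"multivariate model: r = {fit.r_multivariate:.3f}, "
          f"F = {fit.f_statistic:.1f}, p = {fit.p_value:.2e}")
    write_report_json(
        {
            "coefficients": fit.coefficients,
            "stderr": fit.stderr,
            "r_multivariate": fit.r_multivariate,
            "f_statistic": fit.f_statistic,
            "p_value": fit.p_value,
            "n": fit.n,
        },
        RESULTS / "modelfit.json",
    )
    print(f"wrote {RESULTS / 'modelfit.json'}")


if __name__ == "__main__":
    main()
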