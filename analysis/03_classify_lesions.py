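"""Classify every lesion with both methods.

MSI: the circularity -> G / IR threshold decision tree on the extracted
features.  HFUS: direct binning of the simulated ultrasound thickness into
the three clinical categories.  Writes one predictions CSV per method.
"""

from pathlib import Path

from msibreslow.classify import ThresholdConfig, categorize_thickness, classify_msi
from msibreslow.features import FeatureVector
from msibreslow.io import (
    read_cohort_csv,
    read_features_csv,
    write_predictions_csv,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort_csv(RESULTS / "cohort.csv")
    feats = read_features_csv(RESULTS / "features.csv")
    cfg = ThresholdConfig()

    msi_preds = []
    for row in feats.itertuples(index=False):
        fv = FeatureVector(row.mean_G, row.mean_R, row.mean_IR, row.circularity,
                           row.solidity, row.roundness, row.area_px,
                           row.perimeter_px, row.major_axis_px)
        msi_preds.append(classify_msi(fv, cfg))
    hfus_preds = [categorize_thickness(max(r.hfus_measured, 1e-9)) for r in cohort]

    ids = list(feats["lesion_id"])
    write_predictions_csv(ids, msi_preds, "MSI", RESULTS / "predictions_msi.csv")
    write_predictions_csv(ids, hfus_preds, "HFUS", RESULTS / "predictions_hfus.csv")

    for name, preds in (("MSI", msi_preds), ("HFUS", hfus_preds)):
        counts = {c.label: sum(p is c for p in preds) for c in set(preds)}
        print(f"{name:4s} predictions: {counts}")
    print(f"wrote {RESULTS / 'predictions_msi.csv'} and predictions_hfus.csv")


if __name__ == "__main__":
    main()
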