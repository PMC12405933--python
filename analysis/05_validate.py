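"""Internal-external validation of the risk model.

10-fold cross-validation, leave-one-country-out cross-validation, and a
70:30 train-test split with calibration at both risk cuts.  Each fold runs
the entire preprocessing and learning pipeline on its training part only.
"""

from pathlib import Path

import pandas as pd

from exacbn.cohort_io import read_cohort_csv
from exacbn.validation import (PipelineSettings, cross_validate, make_folds,
                               train_test_split_report)

SEED = 20250905
OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    cohort = read_cohort_csv(OUT / "cohort.csv")
    settings = PipelineSettings(seed=SEED)

    cv = cross_validate(cohort, settings,
                        make_folds(cohort, "kfold", 10, seed=SEED))
    (OUT / "validation_cv.json").write_text(cv.to_json())
    cv.predictions.to_csv(OUT / "fold_predictions.csv", index=False)
    print(f"10-fold CV:  AUC(>=1) = {cv.pooled['ge1']['auc']:.3f}  "
          f"AUC(>=2) = {cv.pooled['ge2']['auc']:.3f}  "
          f"macro = {cv.pooled['auc_macro']:.3f}")

    loco = cross_validate(cohort, settings, make_folds(cohort, "loco"))
    (OUT / "validation_loco.json").write_text(loco.to_json())
    print(f"leave-one-country-out ({len(loco.per_fold)} folds): "
          f"AUC(>=1) = {loco.pooled['ge1']['auc']:.3f}  "
          f"AUC(>=2) = {loco.pooled['ge2']['auc']:.3f}")

    split = train_test_split_report(cohort, settings, 0.70, seed=SEED)
    (OUT / "validation_split.json").write_text(split.to_json())
    c = split.calibration
    print("70:30 split calibration:")
    print(f"  risk >=1: slope {c['ge1']['slope']:.3f} "
          f"intercept {c['ge1']['intercept']:.3f}")
    print(f"  risk >=2: slope {c['ge2']['slope']:.3f} "
          f"intercept {c['ge2']['intercept']:.3f}")


if __name__ == "__main__":
    main()
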