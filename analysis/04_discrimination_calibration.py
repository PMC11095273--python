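"""Discrimination and calibration of CS and CCS on the simulated cohort.

Fits the univariable logistic risk model per score on the 4-year binary
MACE outcome, compares apparent AUCs with the paired DeLong test, computes
the 10-fold cross-validated AUC, and assesses calibration (CITL, slope,
Hosmer-Lemeshow). Writes results/discrimination_calibration.json.

Note the expected behaviour on this synthetic registry: outcomes are
generated from the CatLet score alone, so multiplying by ACEF adds noise
and CCS discriminates no better than CS here — unlike in the real
registry, whose patient-level data the generator cannot reconstruct.
"""

import dataclasses
import json
from pathlib import Path

from catlet.calibration import calibration
from catlet.discrimination import (
    auc, binary_outcome_at_horizon, compare_auc_paired, cv_auc, fit_risk_model,
)
from catlet.io import read_cohort, read_outcomes
from catlet.pipeline import cohort_frame
from catlet.weights import illustrative_weight_table

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20240513


def main() -> None:
    patients, _ = read_cohort(OUT / "cohort.csv")
    outcomes = read_outcomes(OUT / "outcomes.csv")
    frame = cohort_frame(patients, illustrative_weight_table())
    sub = outcomes[outcomes.endpoint == "mace"]
    df = frame.merge(sub[["patient_id", "event", "time"]], on="patient_id")
    keep, labels, n_excl = binary_outcome_at_horizon(df["time"], df["event"])
    df = df[keep.astype(bool)]
    print(f"MACE 4-year labels: {labels.sum()} events / {len(labels)} patients "
          f"({n_excl} censored early, excluded)")

    report = {"n": int(len(labels)), "n_excluded": n_excl}
    preds = {}
    for score in ("cs", "ccs"):
        p, coef = fit_risk_model(df[score], labels)
        preds[score] = p
        apparent = auc(p, labels)
        cv = cv_auc(df[score], labels, k=10, seed=SEED)
        cal = calibration(p, labels, with_lowess=False)
        report[score] = {
            "auc_apparent": dataclasses.asdict(apparent),
            "auc_cv": dataclasses.asdict(cv),
            "calibration": {
                "citl": cal.intercept, "slope": cal.slope,
                "hl_statistic": cal.hl_statistic, "hl_df": cal.hl_df, "hl_p": cal.hl_p,
            },
        }
        print(f"  {score.upper():3s}: AUC {apparent.auc:.3f} "
              f"({apparent.ci_low:.3f}-{apparent.ci_high:.3f}), "
              f"cv-AUC {cv.cv_auc:.3f}, slope {cal.slope:.3f}, "
              f"CITL {cal.intercept:+.3f}, H-L p {cal.hl_p:.2f}")

    paired = compare_auc_paired(preds["cs"], preds["ccs"], labels)
    report["paired_delong"] = paired
    print(f"  paired DeLong: dAUC {paired['difference']:+.3f}, p {paired['p_value']:.3f}")
    (OUT / "discrimination_calibration.json").write_text(
        json.dumps(report, indent=1, sort_keys=True))
    print(f"wrote discrimination_calibration.json to {OUT}/")


if __name__ == "__main__":
    main()
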