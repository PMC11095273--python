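"""Generate the synthetic AMI registry used by the downstream analyses.

Draws a cohort of 1018 patients at the registry configuration (score
distribution, anatomy frequencies, per-endpoint event rates and per-SD
hazard ratios) and writes cohort.csv, outcomes.csv and truth.json under
results/. Prints the achieved score distribution against its targets.
"""

import json
from pathlib import Path

import numpy as np

from catlet import registry
from catlet.io import write_cohort, write_outcomes
from catlet.pipeline import cohort_frame
from catlet.synthetic import SyntheticCohortConfig, generate_cohort
from catlet.weights import illustrative_weight_table

SEED = 20240513
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    table = illustrative_weight_table()
    config = SyntheticCohortConfig(seed=SEED)
    patients, outcomes, truth = generate_cohort(config, table)

    write_cohort(patients, OUT / "cohort.csv")
    write_outcomes(outcomes, OUT / "outcomes.csv")
    (OUT / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))

    frame = cohort_frame(patients, table)
    cs, ccs = frame["cs"].to_numpy(), frame["ccs"].to_numpy()
    print(f"simulated n={len(patients)} patients (seed {SEED})")
    print(f"  CS  median {np.median(cs):5.2f} (target {registry.CS_MEDIAN}), "
          f"IQR {np.quantile(cs, 0.25):.2f}-{np.quantile(cs, 0.75):.2f} "
          f"(target {registry.CS_IQR[0]:.0f}-{registry.CS_IQR[1]:.0f})")
    print(f"  CCS median {np.median(ccs):5.2f} (target {registry.CCS_MEDIAN})")
    n_lesions = np.array([len(p.lesions) for p in patients])
    print(f"  lesions/patient {n_lesions.mean():.2f} "
          f"(registry {registry.LESIONS_PER_PATIENT_MEAN})")
    for ep, sub in outcomes.groupby("endpoint"):
        print(f"  {ep:24s} events {int(sub.event.sum()):4d} "
              f"(target {registry.EVENT_COUNTS[ep]})")
    print(f"wrote cohort.csv, outcomes.csv, truth.json to {OUT}/")


if __name__ == "__main__":
    main()
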