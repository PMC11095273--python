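"""Score the simulated cohort: CatLet score, ACEF I, Clinical CatLet score.

Reads results/cohort.csv (written by 01_simulate_cohort.py), computes the
three scores per patient under the non-occlusive scoring convention, and
writes results/scores.csv. Prints distribution summaries in the layout of
a cohort-description table.
"""

from pathlib import Path

import numpy as np

from catlet.io import read_cohort
from catlet.pipeline import cohort_frame
from catlet.weights import illustrative_weight_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    patients, report = read_cohort(OUT / "cohort.csv")
    print(f"read {report['n_patients']} patients ({report['n_rows']} lesion rows)")
    frame = cohort_frame(patients, illustrative_weight_table())
    frame.to_csv(OUT / "scores.csv", index=False)
    for col, label in [("cs", "CatLet score"), ("acef", "ACEF I"),
                       ("ccs", "Clinical CatLet score")]:
        v = frame[col].to_numpy()
        print(f"  {label:22s} mean {v.mean():6.2f}  SD {v.std(ddof=1):5.2f}  "
              f"median {np.median(v):6.2f}  IQR {np.quantile(v, .25):.2f}-"
              f"{np.quantile(v, .75):.2f}")
    print(f"wrote scores.csv to {OUT}/")


if __name__ == "__main__":
    main()
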