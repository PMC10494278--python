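"""Fit the MIMIC model of latent foetal growth conditions.

Fits both model variants on the cohorts from step 01 by maximum likelihood
with Satorra-Bentler corrections, prints the structural/measurement report
(the analogue of the study's main estimates table), and writes the full fit
results as JSON under results/.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from latentfetal.cli import MODEL_COLUMNS, report_table  # noqa: E402
from latentfetal.datamodel import complete_case_filter, read_cohort  # noqa: E402
from latentfetal.sem import analyze, mimic_spec  # noqa: E402

RESULTS = ROOT / "results"


def main():
    for variant in ("population", "subsample"):
        df = read_cohort(RESULTS / f"cohort_{variant}.csv")
        df, report = complete_case_filter(df, MODEL_COLUMNS[variant])
        fit = analyze(df, mimic_spec(variant))
        print(f"\n=== {variant} model (complete cases n = {fit.n}) ===")
        print(report_table(fit))
        for note in fit.notes:
            print(f"note: {note}")
        with open(RESULTS / f"fit_{variant}.json", "w") as fh:
            json.dump(fit.to_dict(), fh, indent=1)
        print(f"wrote results/fit_{variant}.json")


if __name__ == "__main__":
    main()
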