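"""Factor scores and perinatal outcome models.

Computes per-participant linear predictions of latent foetal growth
conditions on the population cohort, standardizes them, and runs the
outcome grid: each perinatal outcome on the standardized latent score
(unadjusted) and, as the per-indicator alternative, on bwz and blz with the
eight-determinant adjustment set.  Writes scores and effects under
results/ and prints the odds-ratio table.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from latentfetal.cli import MODEL_COLUMNS  # noqa: E402
from latentfetal.datamodel import complete_case_filter, read_cohort  # noqa: E402
from latentfetal.outcomes import effects_frame, run_outcome_suite  # noqa: E402
from latentfetal.scores import predict_latent, standardize  # noqa: E402
from latentfetal.sem import analyze, mimic_spec  # noqa: E402

RESULTS = ROOT / "results"


def main():
    df = read_cohort(RESULTS / "cohort_population.csv")
    df, _ = complete_case_filter(df, MODEL_COLUMNS["population"])
    fit = analyze(df, mimic_spec("population"))
    pred = standardize(predict_latent(fit, df))
    raw = pred.raw
    print("latent prediction: "
          f"min {raw.min():.2f}, median {raw.median():.2f}, max {raw.max():.2f} "
          f"(IQR {raw.quantile(0.25):.2f}, {raw.quantile(0.75):.2f})")
    pd.concat([df, pred.frame()], axis=1).to_csv(RESULTS / "scores_population.csv",
                                                 index=False)
    effects = run_outcome_suite(df, pred)
    table = effects_frame(effects)
    table.to_csv(RESULTS / "outcome_effects.csv", index=False)
    show = table[table.error.isna()][
        ["outcome", "model_type", "odds_ratio", "ci_low", "ci_high", "p_value"]
    ]
    print(show.round(3).to_string(index=False))
    print("wrote results/scores_population.csv and results/outcome_effects.csv")


if __name__ == "__main__":
    main()
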