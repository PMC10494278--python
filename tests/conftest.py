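import dataclasses
from pathlib import Path

import pytest

from latentfetal.datamodel import complete_case_filter, read_cohort
from latentfetal.sem import analyze, mimic_spec
from latentfetal.simulate import default_config, generate

DATA_DIR = Path(__file__).parent / "data"
FIXTURE_CSV = DATA_DIR / "synthetic_cohort_n500.csv"

#: raw column names needed for the two model variants
MODEL_COLUMNS = {
    "population": ("age", "height_m", "prepreg_weight_kg", "elevated_bp",
                   "primiparity", "smoking", "malaria_pregnancy",
                   "insufficient_gwg", "bwz", "blz"),
    "subsample": ("age", "height_m", "prepreg_weight_kg", "elevated_bp",
                  "primiparity", "smoking", "malaria_pregnancy",
                  "insufficient_gwg", "hc_z", "ac_z", "fl_z", "bwz", "blz"),
}


@pytest.fixture(scope="session")
def pop_config():
    return default_config("population")


@pytest.fixture(scope="session")
def fixture_cohort():
    """The shipped synthetic fixture cohort (n = 500, complete cases)."""
    df = read_cohort(FIXTURE_CSV)
    df, _ = complete_case_filter(df, MODEL_COLUMNS["population"])
    return df


@pytest.fixture(scope="session")
def fixture_fit(fixture_cohort):
    return analyze(fixture_cohort, mimic_spec("population"))


@pytest.fixture(scope="session")
def big_cohort(pop_config):
    """One large cohort reused by several sampling-error-bounded checks."""
    cfg = dataclasses.replace(pop_config, n=10_000, seed=11)
    return generate(cfg)
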