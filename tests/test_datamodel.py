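import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from latentfetal.datamodel import (
    AnalysisConfig,
    EmptyInputError,
    SchemaError,
    complete_case_filter,
    cohort_units,
    read_cohort,
    validate_cohort,
    write_cohort,
)
from latentfetal.simulate import default_config, generate

from .conftest import FIXTURE_CSV, MODEL_COLUMNS


def test_fixture_round_trip(tmp_path):
    """Read -> write -> read is the identity on a valid cohort file."""
    df = read_cohort(FIXTURE_CSV)
    out = tmp_path / "copy.csv"
    write_cohort(df, out)
    again = read_cohort(out)
    pd.testing.assert_frame_equal(df, again)


def test_synthetic_cohort_round_trip(tmp_path, pop_config):
    """A freshly generated cohort survives CSV round-tripping field by field."""
    cfg = dataclasses.replace(pop_config, n=200, seed=3,
                              missingness={"smoking": 0.1})
    df, _ = generate(cfg)
    path = tmp_path / "cohort.csv"
    write_cohort(df, path)
    again = read_cohort(path)
    pd.testing.assert_frame_equal(df, again, check_exact=False, rtol=0, atol=1e-12)


def test_read_parses_na_and_bad_cells(tmp_path, caplog):
    path = tmp_path / "c.csv"
    base = pd.read_csv(FIXTURE_CSV).head(3).astype(object)
    base.loc[1, "smoking"] = "NA"
    base.loc[2, "smoking"] = "definitely-not-a-number"
    base.to_csv(path, index=False)
    with caplog.at_level("WARNING"):
        df = read_cohort(path)
    assert np.isnan(df.loc[1, "smoking"]) and np.isnan(df.loc[2, "smoking"])
    assert any("unparseable" in rec.message for rec in caplog.records)
    assert len(df) == 3  # row count preserved


def test_read_errors(tmp_path):
    df = pd.read_csv(FIXTURE_CSV).drop(columns=["bwz"])
    path = tmp_path / "nobwz.csv"
    df.to_csv(path, index=False)
    with pytest.raises(SchemaError, match="bwz"):
        read_cohort(path)
    empty = tmp_path / "empty.csv"
    empty.write_text("")
    with pytest.raises(EmptyInputError):
        read_cohort(empty)


def test_complete_case_filter_clean_and_allmissing():
    df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
    out, report = complete_case_filter(df, ("a", "b"))
    assert report.n_removed == 0
    pd.testing.assert_frame_equal(out, df)
    df2 = pd.DataFrame({"a": [np.nan, 2.0], "b": [3.0, np.nan]})
    with pytest.warns(UserWarning, match="every row"):
        out2, report2 = complete_case_filter(df2, ("a", "b"))
    assert len(out2) == 0 and report2.n_retained == 0
    with pytest.raises(SchemaError):
        complete_case_filter(df, ("a", "zz"))


def test_complete_case_filter_matches_brute_force(pop_config):
    """Retained count equals a brute-force scan, and the average retention
    over seeds matches the binomial expectation n * (1 - r)^2."""
    retained = []
    for seed in range(8):
        cfg = dataclasses.replace(
            pop_config, n=1000, seed=seed,
            missingness={"smoking": 0.1, "bwz": 0.1},
        )
        df, _ = generate(cfg)
        out, report = complete_case_filter(df, MODEL_COLUMNS["population"])
        brute = sum(
            1 for _, row in df[list(MODEL_COLUMNS["population"])].iterrows()
            if not row.isna().any()
        )
        assert len(out) == brute == report.n_retained
        retained.append(report.n_retained)
    expected = 1000 * 0.9**2
    se = np.sqrt(1000 * 0.81 * 0.19 / 8)
    assert abs(np.mean(retained) - expected) < 3 * se


def test_cohort_units_height_conversion():
    df = pd.DataFrame({"height_m": [1.57, 1.60], "age": [25.0, 30.0]})
    out = cohort_units(df, ("height_cm", "age"))
    assert out["height_cm"].tolist() == [157.0, 160.0]
    assert out["age"].tolist() == [25.0, 30.0]


@settings(deadline=None, max_examples=25)
@given(st.floats(min_value=1.2, max_value=2.1, allow_nan=False))
def test_height_round_trip_is_identity(h):
    df = pd.DataFrame({"height_m": [h]})
    cm = cohort_units(df, ("height_cm",))["height_cm"].iloc[0]
    assert abs(cm / 100.0 - h) < 1e-12


def test_validate_flags_bounds_and_binary():
    df = pd.read_csv(FIXTURE_CSV).head(5)
    df.loc[0, "smoking"] = 2
    df.loc[1, "bwz"] = 9.0
    df.loc[2, "height_m"] = 0.9
    problems = validate_cohort(df)
    joined = " | ".join(problems)
    assert "smoking" in joined and "bwz" in joined and "height_m" in joined
    assert validate_cohort(pd.read_csv(FIXTURE_CSV)) == []


def test_analysis_config_validation(tmp_path):
    with pytest.raises(ValueError):
        AnalysisConfig(alpha=1.5)
    with pytest.raises(SchemaError):
        AnalysisConfig(covariates=("not_a_column",))
    path = tmp_path / "cfg.yaml"
    path.write_text("model_variant: subsample\nalpha: 0.01\ncovariates: [age, bwz]\n")
    cfg = AnalysisConfig.from_yaml(path)
    assert cfg.model_variant == "subsample" and cfg.alpha == 0.01
    assert cfg.covariates == ("age", "bwz")
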