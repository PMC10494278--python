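import dataclasses

import numpy as np
import pandas as pd
import pytest

from latentfetal.datamodel import cohort_units
from latentfetal.scores import LatentPrediction, predict_latent, standardize
from latentfetal.sem import FitResult, ParameterSet, mimic_spec
from latentfetal.simulate import generate


def _stub_fit(params, spec):
    """Minimal converged FitResult carrying a chosen parameter set."""
    return FitResult(
        spec=spec, theta=np.zeros(1), names=["x"], n=10, df=0, n_free=1,
        loglik=0.0, loglik_sat=0.0, fmin=0.0, T_ML=0.0, converged=True,
        n_iter=0, grad_norm=0.0, vcov_naive=np.zeros((1, 1)), params=params,
    )


def test_matches_generic_conditioning_formula(fixture_fit, fixture_cohort):
    """Regression scores equal the conditional mean from the explicitly
    assembled joint normal of (eta, bwz, blz) given the determinants."""
    spec = fixture_fit.spec
    p = fixture_fit.params
    lam = np.array([1.0, p.lambda_blz])
    design = cohort_units(fixture_cohort,
                          tuple(spec.determinants) + tuple(spec.indicators))
    X = design[list(spec.determinants)].to_numpy()
    Y = design[list(spec.indicators)].to_numpy()
    gamma = np.array([p.gamma[c] for c in spec.determinants])
    nu = np.array([p.nu[i] for i in spec.indicators])
    theta = np.array([p.theta[i] for i in spec.indicators])
    # joint covariance of (eta, bwz, blz) | x, assembled from scratch
    joint = np.zeros((3, 3))
    joint[0, 0] = p.psi
    joint[0, 1:] = joint[1:, 0] = lam * p.psi
    joint[1:, 1:] = np.outer(lam, lam) * p.psi + np.diag(theta)
    w = np.linalg.solve(joint[1:, 1:], joint[0, 1:])
    expected = X @ gamma + (Y - nu - np.outer(X @ gamma, lam)) @ w
    pred = predict_latent(fixture_fit, fixture_cohort)
    np.testing.assert_allclose(pred.raw.to_numpy(), expected, atol=1e-10)


def test_marker_dominates_as_theta1_vanishes(fixture_cohort):
    """theta_bwz -> 0 makes the score collapse onto bwz - nu_bwz."""
    spec = mimic_spec("population")
    params = ParameterSet(
        gamma={c: 0.01 for c in spec.determinants}, lambda_blz=0.8,
        nu={"bwz": -2.0, "blz": -1.5}, psi=0.6,
        theta={"bwz": 1e-12, "blz": 0.4}, beta={}, omega={},
    )
    fit = _stub_fit(params, spec)
    pred = predict_latent(fit, fixture_cohort)
    expected = fixture_cohort["bwz"] + 2.0
    np.testing.assert_allclose(pred.raw.to_numpy(), expected.to_numpy(), atol=1e-6)


def test_indicators_at_conditional_mean_give_structural_prediction(fixture_fit):
    spec = fixture_fit.spec
    p = fixture_fit.params
    gamma = np.array([p.gamma[c] for c in spec.determinants])
    row = {c: 1.0 for c in spec.determinants}
    row["height_m"] = 1.60
    x = np.array([row[c] if c != "height_cm" else 160.0 for c in spec.determinants])
    struct = float(x @ gamma)
    table = pd.DataFrame([{
        **{("height_m" if c == "height_cm" else c): row.get(
            "height_m" if c == "height_cm" else c, 1.0) for c in spec.determinants},
        "bwz": p.nu["bwz"] + struct,
        "blz": p.nu["blz"] + p.lambda_blz * struct,
    }])
    pred = predict_latent(fixture_fit, table)
    assert abs(pred.raw.iloc[0] - struct) < 1e-10


def test_missing_rows_flagged(fixture_fit, fixture_cohort):
    df = fixture_cohort.head(10).copy()
    df.loc[3, "bwz"] = np.nan
    pred = predict_latent(fixture_fit, df)
    assert not pred.available[3] and np.isnan(pred.raw[3])
    assert pred.available.drop(3).all()


def test_standardize_basic_and_idempotent():
    pred = LatentPrediction(
        raw=pd.Series([1.0, 2.0, 3.0]), standardized=None,
        available=pd.Series([True] * 3),
    )
    out = standardize(pred)
    np.testing.assert_allclose(out.standardized.to_numpy(), [-1.0, 0.0, 1.0])
    twice = standardize(LatentPrediction(raw=out.standardized, standardized=None,
                                         available=pred.available))
    np.testing.assert_allclose(twice.standardized.to_numpy(),
                               out.standardized.to_numpy(), atol=1e-12)
    with pytest.raises(ValueError):
        standardize(LatentPrediction(raw=pd.Series([2.0, 2.0]), standardized=None,
                                     available=pd.Series([True, True])))


def test_scores_track_truth_and_are_shrunken(big_cohort):
    """Standardized scores correlate strongly with the generating latent
    values, and raw scores are shrunken relative to them."""
    from latentfetal.sem import analyze

    df, truth = big_cohort
    fit = analyze(df)
    pred = standardize(predict_latent(fit, df))
    s = pred.standardized.to_numpy()
    assert abs(s.mean()) < 1e-10 and abs(s.std(ddof=1) - 1.0) < 1e-10
    assert np.corrcoef(s, truth.eta)[0, 1] >= 0.9
    assert pred.raw.var(ddof=1) <= truth.eta.var(ddof=1)


def test_bartlett_scores_are_conditionally_unbiased_weighting(fixture_fit, fixture_cohort):
    """Bartlett scores differ from regression scores by a uniform blend
    towards the indicators (no shrinkage of the measurement part)."""
    reg = predict_latent(fixture_fit, fixture_cohort, method="regression")
    bart = predict_latent(fixture_fit, fixture_cohort, method="bartlett")
    assert bart.raw.var(ddof=1) > reg.raw.var(ddof=1)
    assert np.corrcoef(bart.raw, reg.raw)[0, 1] > 0.99
    with pytest.raises(ValueError):
        predict_latent(fixture_fit, fixture_cohort, method="nope")
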