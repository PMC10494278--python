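import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from latentfetal.sem import (
    DirectSpec,
    ModelSpec,
    ParameterSet,
    _indices_from_stats,
    _vech_indices,
    analyze,
    build_direct_model,
    compare_models,
    fit_indices,
    implied_moments,
    mimic_spec,
    ml_fit,
    r2_components,
    r_squared,
    satorra_bentler,
)
from latentfetal.simulate import generate


def _no_covariate_params(lam=0.82, psi=1.0, th=(0.5, 0.5), nu=(0.0, 0.0)):
    return ParameterSet(
        gamma={}, lambda_blz=lam, nu={"bwz": nu[0], "blz": nu[1]}, psi=psi,
        theta={"bwz": th[0], "blz": th[1]}, beta={}, omega={},
    )


class TestImpliedMoments:
    def test_no_covariate_closed_form(self):
        """lam lam' psi + diag(theta) for the pure measurement model."""
        spec = ModelSpec(determinants=(), endogenous=())
        mu, Sigma = implied_moments(_no_covariate_params(), spec)
        expected = np.array([[1.5, 0.82], [0.82, 1.1724]])
        np.testing.assert_allclose(Sigma, expected, atol=1e-12)
        np.testing.assert_allclose(mu, [0.0, 0.0], atol=1e-12)

    def test_zero_gamma_means_equal_nu(self):
        spec = ModelSpec(determinants=("age",), endogenous=())
        params = _no_covariate_params(nu=(0.3, -0.2))
        params.gamma = {"age": 0.0}
        mu, _ = implied_moments(params, spec, mu_x=[25.0], Phi_x=[[49.0]])
        np.testing.assert_allclose(mu[1:], [0.3, -0.2], atol=1e-12)

    def test_negative_variance_rejected(self):
        spec = ModelSpec(determinants=(), endogenous=())
        with pytest.raises(ValueError):
            implied_moments(_no_covariate_params(psi=-0.1), spec)

    def test_matches_monte_carlo_covariance(self, pop_config):
        """Full population-model implied covariance reproduces the joint
        covariance of one million generated draws entry by entry."""
        cfg = dataclasses.replace(pop_config, n=1_000_000, seed=17)
        df, truth = generate(cfg)
        spec = mimic_spec("population")
        theta_true, _ = truth.theta_vector(spec)
        from latentfetal.sem import _LatentModel

        model = _LatentModel(spec)
        pset = model.parameter_set(theta_true)
        from latentfetal.datamodel import cohort_units

        design = cohort_units(df, tuple(spec.determinants) + tuple(spec.indicators))
        X = design[list(spec.exogenous)].to_numpy()
        mu, Sigma = implied_moments(pset, spec, X.mean(0), np.cov(X, rowvar=False))
        order = list(spec.exogenous) + list(spec.modelled)
        S = np.cov(design[order].to_numpy(), rowvar=False)
        # compare on the correlation scale so every entry shares the same
        # Monte-Carlo error magnitude
        d_i = np.sqrt(np.diag(Sigma))
        d_s = np.sqrt(np.diag(S))
        corr_implied = Sigma / np.outer(d_i, d_i)
        corr_sample = S / np.outer(d_s, d_s)
        q = len(spec.exogenous)
        np.testing.assert_allclose(corr_implied[q:, :], corr_sample[q:, :], atol=0.01)
        np.testing.assert_allclose(np.diag(Sigma)[q:] / np.diag(S)[q:],
                                   np.ones(4), atol=0.01)
        np.testing.assert_allclose(mu[q:], design[order].mean()[q:], atol=0.01)


class TestMlFit:
    def test_free_parameter_and_df_hand_counts(self, fixture_fit):
        assert fixture_fit.n_free == 30
        assert fixture_fit.df == 8

    def test_subsample_df_hand_count(self, pop_config):
        from latentfetal.simulate import default_config

        cfg = dataclasses.replace(default_config("subsample"), n=600, seed=2)
        df, _ = generate(cfg)
        fit = ml_fit(df, mimic_spec("subsample"))
        assert fit.n_free == 39
        assert fit.df == 11

    def test_consistency_at_large_n(self, pop_config):
        """Estimates at n = 20000 sit within 3 robust SEs of the truth."""
        cfg = dataclasses.replace(pop_config, n=20_000, seed=21)
        df, truth = generate(cfg)
        fit = satorra_bentler(None, ml_fit(df, mimic_spec("population")))
        true_vec, names = truth.theta_vector()
        for nm, tv, est, se in zip(names, true_vec, fit.theta, fit.se_robust):
            assert abs(est - tv) < 3.5 * se + 1e-9, nm

    def test_saturated_model_identity(self, fixture_cohort):
        """A saturated spec has df = 0, T_ML = 0 and implied moments equal
        to the sample moments."""
        spec = DirectSpec(
            determinants=("age", "height_cm", "prepreg_weight_kg"),
            endogenous=(),
        )
        fit = ml_fit(fixture_cohort, spec)
        assert fit.df == 0
        assert abs(fit.T_ML) < 1e-6
        A, Sigma = fit._model.reduced_form(fit.theta)
        A_sat, Sig_sat = fit._frame.saturated()
        np.testing.assert_allclose(A, A_sat, atol=1e-7)
        np.testing.assert_allclose(Sigma, Sig_sat, atol=1e-7)
        fit = satorra_bentler(None, fit)
        assert fit.T_SB == 0.0 and fit.sb_c is None

    def test_scale_equivariance(self, fixture_cohort, fixture_fit):
        """Scaling blz by k rescales lambda by k, theta_blz by k^2 and
        leaves the chi-square unchanged."""
        k = 2.0
        scaled = fixture_cohort.copy()
        scaled["blz"] = scaled["blz"] * k
        fit_k = ml_fit(scaled, mimic_spec("population"))
        assert np.isclose(fit_k.params.lambda_blz,
                          k * fixture_fit.params.lambda_blz, atol=1e-6)
        assert np.isclose(fit_k.params.theta["blz"],
                          k**2 * fixture_fit.params.theta["blz"], atol=1e-6)
        assert abs(fit_k.T_ML - fixture_fit.T_ML) < 1e-6

    def test_n_too_small_rejected(self, fixture_cohort):
        with pytest.raises(ValueError, match="free parameters"):
            ml_fit(fixture_cohort.head(25), mimic_spec("population"))


class TestSatorraBentler:
    def test_gamma_matches_bootstrap(self, fixture_cohort, fixture_fit):
        """The empirical fourth-moment matrix agrees with a nonparametric
        bootstrap of the sample-moment covariance on its leading entries."""
        frame = fixture_fit._frame
        Z, M, n = frame.Z, frame.M, frame.n
        rng = np.random.default_rng(0)
        rows, cols = _vech_indices(M.shape[1])
        stats = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            Zb, Mb = Z[idx], M[idx]
            Szz = Zb.T @ Zb / n
            A = linalg.solve(Szz, (Mb.T @ Zb / n).T, assume_a="pos").T
            R = Mb - Zb @ A.T
            Sig = R.T @ R / n
            stats.append(np.concatenate([A.ravel(order="F"), Sig[rows, cols]]))
        stats = np.asarray(stats)
        Gamma_boot = n * np.cov(stats, rowvar=False)
        Gamma = fixture_fit.Gamma
        lead = np.abs(Gamma) >= 0.5 * np.abs(Gamma).max()
        rel = np.abs(Gamma_boot[lead] - Gamma[lead]) / np.abs(Gamma[lead])
        assert rel.max() < 0.05

    def test_mismatched_table_rejected(self, fixture_cohort):
        fit = ml_fit(fixture_cohort, mimic_spec("population"))
        with pytest.raises(ValueError, match="match"):
            satorra_bentler(fixture_cohort.head(400), fit)


class TestFitIndices:
    def test_hand_case(self):
        rmsea, cfi, tli = _indices_from_stats(30.0, 20, 300.0, 28, 1001)
        assert abs(rmsea - np.sqrt(10.0 / 20000.0)) < 1e-9
        assert abs(cfi - (1.0 - 10.0 / 272.0)) < 1e-6
        expected_tli = (300.0 / 28 - 30.0 / 20) / (300.0 / 28 - 1.0)
        assert abs(tli - expected_tli) < 1e-6

    def test_exact_fit_conventions(self):
        rmsea, cfi, _ = _indices_from_stats(20.0, 20, 300.0, 28, 500)
        assert rmsea == 0.0
        rmsea2, cfi2, _ = _indices_from_stats(10.0, 20, 300.0, 28, 500)
        assert rmsea2 == 0.0 and cfi2 == 1.0

    def test_attached_indices_in_range(self, fixture_fit):
        idx = fixture_fit.indices
        assert idx["rmsea"] >= 0.0
        assert 0.0 <= idx["cfi"] <= 1.0
        assert np.isfinite(idx["bic"])
        assert 0.0 <= idx["srmr"] < 0.2
        assert "rmsea_sb" in idx and "cfi_sb" in idx


class TestRSquared:
    def test_forced_arithmetic(self):
        """The reported explained-variance identities."""
        assert abs(r2_components(0.883, [1.0], [0.117])[0] - 0.883) < 1e-12
        share = r2_components(1.0, [0.82], [0.58])[0]
        assert abs(share - 0.6724 / 1.2524) < 1e-9
        with pytest.raises(ValueError):
            r2_components(0.0, [0.0], [0.0])

    def test_zero_gamma_zero_latent_r2(self, pop_config):
        cfg = dataclasses.replace(pop_config, n=4000, seed=31,
                                  gamma={k: 0.0 for k in pop_config.gamma})
        df, _ = generate(cfg)
        fit = r_squared(ml_fit(df, mimic_spec("population")))
        assert abs(fit.r2["r2_latent"]) < 0.02  # estimation noise only

    def test_fitted_r2_matches_calibration(self, fixture_fit):
        assert abs(fixture_fit.r2["r2_bwz"] - 0.883) < 0.05
        assert abs(fixture_fit.r2["r2_blz"] - 0.537) < 0.07


class TestDirectModel:
    def test_equals_equationwise_ols(self, fixture_cohort):
        """ML of the direct model coincides with per-equation least squares
        (seemingly-unrelated regressions with identical regressors)."""
        from latentfetal.datamodel import cohort_units

        fit = build_direct_model(fixture_cohort, variant="population")
        spec = fit.spec
        design = cohort_units(
            fixture_cohort, tuple(spec.determinants) + tuple(spec.indicators)
        )
        X = np.column_stack([
            np.ones(len(design)), design[list(spec.determinants)].to_numpy()
        ])
        est = fit.estimates()
        for ind in ("bwz", "blz"):
            coef, *_ = np.linalg.lstsq(X, design[ind].to_numpy(), rcond=None)
            got = [est[f"{ind}_const"]] + [
                est[f"{ind}_on_{c}"] for c in spec.determinants
            ]
            np.testing.assert_allclose(got, coef, atol=1e-6)

    def test_parameter_counting_and_bic(self, fixture_cohort, fixture_fit):
        direct = fit_indices(build_direct_model(fixture_cohort))
        assert direct.n_free >= fixture_fit.n_free
        assert direct.df < fixture_fit.df
        assert np.isfinite(direct.indices["bic"])
        assert np.isfinite(fixture_fit.indices["bic"])

    def test_compare_to_self_is_tie(self, fixture_fit):
        comp = compare_models(fixture_fit, fixture_fit)
        assert comp.preferred == "tie"
        assert (comp.table.loc["latent"] == comp.table.loc["direct"]).all()

    def test_latent_data_prefers_latent_model(self, fixture_cohort, fixture_fit):
        direct = fit_indices(build_direct_model(fixture_cohort))
        comp = compare_models(fixture_fit, direct)
        assert comp.preferred == "latent"

    def test_mismatched_rows_rejected(self, fixture_cohort, fixture_fit):
        other = build_direct_model(fixture_cohort.head(450))
        with pytest.raises(ValueError):
            compare_models(fixture_fit, other)
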