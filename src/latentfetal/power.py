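"""Monte-Carlo power analysis and sampling-distribution cross-validation.

Power for each coefficient of the specified MIMIC model is the proportion
of simulated cohorts whose robust-Wald test is significant at the chosen
level: each replicate draws a cohort from the generating configuration,
applies the complete-case filter, fits the model by ML, applies the
Satorra-Bentler correction and records the robust p-values.  Replicate
seeds derive from the master seed through a counter-based spawn scheme, so
any replicate can be reproduced independently and results do not depend on
execution order.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .datamodel import complete_case_filter
from .sem import ConvergenceError, FitSettings, mimic_spec, ml_fit, satorra_bentler
from .simulate import GeneratorConfig, generate

__all__ = ["PowerResult", "run_power", "sampling_distribution",
           "linear_regression_power_mc", "wald_power_slope"]


class NonConvergenceRateError(RuntimeError):
    """More than the tolerated share of replicates failed to converge."""


@dataclass
class PowerResult:
    power: dict[str, float]
    mc_se: dict[str, float]
    n_requested: int
    n_converged: int
    n: int
    alpha: float
    seed: int
    estimates: pd.DataFrame | None = None  # replicate x parameter
    percentiles: pd.DataFrame | None = None
    sign_consistent: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        for name, p in self.power.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"power for {name} outside [0, 1]")


def _replicate_seed(master: int, rep: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(master), spawn_key=(rep,))


def _run_replicates(spec, truth: GeneratorConfig, n, nsim, seed, keep_pvalues,
                    max_nonconv=0.2, force=False):
    names = None
    estimates, pvalues = [], []
    n_fail = 0
    model_cols = [
        c if c != "height_cm" else "height_m"
        for c in list(spec.determinants) + list(spec.indicators)
    ]
    for rep in range(nsim):
        rep_seed = int(_replicate_seed(seed, rep).generate_state(1)[0] % (2**31))
        cfg = dataclasses.replace(truth, n=n, seed=rep_seed)
        df, _ = generate(cfg)
        df, _ = complete_case_filter(df, tuple(model_cols))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = ml_fit(df, spec, settings=FitSettings())
                fit = satorra_bentler(None, fit)
        except (ConvergenceError, ValueError):
            n_fail += 1
            continue
        if names is None:
            names = list(fit.names)
        estimates.append(fit.theta.copy())
        if keep_pvalues:
            p = fit.pvalues(robust=True)
            pvalues.append([p[nm] for nm in names])
    n_conv = nsim - n_fail
    if n_conv == 0:
        raise NonConvergenceRateError("no replicate converged")
    if n_fail / nsim > max_nonconv:
        msg = f"{n_fail}/{nsim} replicates failed to converge"
        if force:
            warnings.warn(msg, stacklevel=3)
        else:
            raise NonConvergenceRateError(msg)
    est = pd.DataFrame(np.asarray(estimates), columns=names)
    pvals = pd.DataFrame(np.asarray(pvalues), columns=names) if keep_pvalues else None
    return est, pvals, n_conv


def run_power(
    spec=None,
    truth: GeneratorConfig | None = None,
    n: int = 1253,
    nsim: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    force: bool = False,
) -> PowerResult:
    """Per-parameter power of the robust Wald tests at level ``alpha``.

    Non-converged replicates are excluded from the denominator and counted;
    more than 20% of them raises unless ``force`` is set.
    """
    from .simulate import default_config

    spec = spec or mimic_spec("population")
    truth = truth or default_config(spec.variant)
    est, pvals, n_conv = _run_replicates(
        spec, truth, n, nsim, seed, keep_pvalues=True, force=force
    )
    power = {nm: float((pvals[nm] <= alpha).mean()) for nm in pvals.columns}
    mc_se = {
        nm: float(np.sqrt(p * (1 - p) / n_conv)) for nm, p in power.items()
    }
    return PowerResult(
        power=power, mc_se=mc_se, n_requested=nsim, n_converged=n_conv,
        n=n, alpha=alpha, seed=seed, estimates=est,
    )


def sampling_distribution(
    spec=None,
    truth: GeneratorConfig | None = None,
    n: int = 1253,
    nsim: int = 1000,
    seed: int = 0,
    force: bool = False,
) -> PowerResult:
    """Replicate estimates with empirical 2.5/50/97.5 percentiles and a
    sign-consistency summary: for parameters with nonzero generating value,
    whether the percentile interval excludes zero on the truth's side."""
    from .simulate import default_config

    spec = spec or mimic_spec("population")
    truth = truth or default_config(spec.variant)
    est, _, n_conv = _run_replicates(
        spec, truth, n, nsim, seed, keep_pvalues=False, force=force
    )
    pct = est.quantile([0.025, 0.5, 0.975])
    df_gen, record = generate(dataclasses.replace(truth, n=2, seed=1))
    true_vec, names = record.theta_vector(spec)
    sign = {}
    for nm, tv in zip(names, true_vec):
        if nm in pct.columns and tv != 0.0:
            lo, hi = pct.loc[0.025, nm], pct.loc[0.975, nm]
            sign[nm] = bool(lo > 0) if tv > 0 else bool(hi < 0)
    return PowerResult(
        power={}, mc_se={}, n_requested=nsim, n_converged=n_conv, n=n,
        alpha=np.nan, seed=seed, estimates=est, percentiles=pct,
        sign_consistent=sign,
    )


# --------------------------------------------------------------------------
# degenerate single-regression check against the closed-form Wald power
# --------------------------------------------------------------------------


def wald_power_slope(beta: float, n: int, sigma: float, sd_x: float,
                     alpha: float = 0.05) -> float:
    """Closed-form asymptotic power of the two-sided Wald test for a simple
    linear regression slope: se(slope) = sigma / (sd_x * sqrt(n))."""
    se = sigma / (sd_x * np.sqrt(n))
    z = sstats.norm.ppf(1 - alpha / 2)
    shift = beta / se
    return float(sstats.norm.sf(z - shift) + sstats.norm.cdf(-z - shift))


def linear_regression_power_mc(beta: float, n: int, nsim: int, sigma: float = 1.0,
                               sd_x: float = 1.0, alpha: float = 0.05,
                               seed: int = 0) -> float:
    """Monte-Carlo power of the same test (no latent variable: the model
    degenerates to one linear regression), for validating the machinery
    against :func:`wald_power_slope`."""
    hits = 0
    z = sstats.norm.ppf(1 - alpha / 2)
    for rep in range(nsim):
        rng = np.random.default_rng(_replicate_seed(seed, rep))
        x = sd_x * rng.standard_normal(n)
        y = beta * x + sigma * rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x])
        coef, res_ss, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        s2 = resid @ resid / (n - 2)
        XtX_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(s2 * XtX_inv[1, 1])
        if abs(coef[1] / se) > z:
            hits += 1
    return hits / nsim
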