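"""Logistic models of perinatal outcomes.

The primary models regress each binary perinatal outcome (preterm birth,
reanimation procedures, infant formula prescription, hospital stay >3 days)
on the standardized latent prediction, unadjusted: the latent score already
aggregates the measured determinants, and the interest is in the odds ratio
per standardized unit of foetal growth conditions.  The alternative
per-indicator models regress the same outcomes on the birth weight or
length z-score directly, adjusted for the eight maternal determinants.

Estimation is plain ML logistic regression; odds ratios carry Wald 95%
confidence intervals on the log scale.  Uncertainty from the first-stage
model is not propagated into the second stage (two-step procedure).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sstats

from .datamodel import OUTCOME_COLUMNS, cohort_units
from .scores import LatentPrediction

__all__ = ["OutcomeEffect", "fit_outcome_logistic", "run_outcome_suite",
           "ADJUSTMENT_COVARIATES"]

#: adjustment set of the per-indicator alternative models
ADJUSTMENT_COVARIATES = (
    "age",
    "height_cm",
    "prepreg_weight_kg",
    "elevated_bp",
    "primiparity",
    "smoking",
    "malaria_pregnancy",
    "insufficient_gwg",
)


class SeparationError(RuntimeError):
    """Perfect separation: the ML estimate does not exist."""


@dataclass
class OutcomeEffect:
    outcome: str
    predictor: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    model_type: str  # latent | bwz-adjusted | blz-adjusted
    error: str | None = None

    def __post_init__(self):
        if self.error is None:
            if not (self.ci_low <= self.odds_ratio <= self.ci_high):
                raise ValueError("confidence interval must bracket the odds ratio")
            if self.odds_ratio <= 0:
                raise ValueError("odds ratio must be positive")


def fit_outcome_logistic(
    table: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: tuple[str, ...] = (),
    alpha: float = 0.05,
) -> OutcomeEffect:
    """One ML logistic regression; the reported effect is for ``predictor``.

    Deterministic given the data.  Raises on a single-class outcome, a
    constant predictor, or perfect separation.
    """
    cols = (outcome, predictor) + tuple(covariates)
    design = cohort_units(table, cols)
    design = design.dropna()
    n = len(design)
    y = design[outcome].to_numpy(float)
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])):
        raise ValueError(f"outcome {outcome!r} is not binary 0/1")
    if classes.size < 2:
        raise ValueError(f"outcome {outcome!r} has a single class")
    X = design[[predictor] + list(covariates)]
    if X[predictor].nunique() < 2:
        raise ValueError(f"predictor {predictor!r} is constant")
    X = sm.add_constant(X, prepend=True)
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning) as exc:
            raise SeparationError(
                f"perfect separation fitting {outcome!r} on {predictor!r}"
            ) from exc
    if not res.mle_retvals.get("converged", True):
        raise SeparationError(
            f"logistic fit for {outcome!r} on {predictor!r} did not converge"
        )
    beta = res.params[predictor]
    se = res.bse[predictor]
    zq = sstats.norm.ppf(1 - alpha / 2)
    return OutcomeEffect(
        outcome=outcome,
        predictor=predictor,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - zq * se)),
        ci_high=float(np.exp(beta + zq * se)),
        p_value=float(res.pvalues[predictor]),
        n=n,
        model_type="custom",
    )


def run_outcome_suite(
    table: pd.DataFrame,
    scores: LatentPrediction,
    outcomes: tuple[str, ...] = OUTCOME_COLUMNS,
    alpha: float = 0.05,
) -> list[OutcomeEffect]:
    """The full outcome grid: every outcome against (a) the standardized
    latent score, unadjusted, and (b, c) bwz and blz each adjusted for the
    eight determinants.  Failed cells are flagged and the suite continues.
    """
    if scores.standardized is None:
        raise ValueError("scores must be standardized first")
    if len(scores.standardized) != len(table):
        raise ValueError("scores are not aligned to the table rows")
    augmented = table.copy()
    augmented["score_std"] = scores.standardized.to_numpy()
    grid = [("score_std", (), "latent"),
            ("bwz", ADJUSTMENT_COVARIATES, "bwz-adjusted"),
            ("blz", ADJUSTMENT_COVARIATES, "blz-adjusted")]
    effects = []
    for outcome in outcomes:
        for predictor, covs, model_type in grid:
            try:
                eff = fit_outcome_logistic(augmented, outcome, predictor, covs, alpha)
                eff.model_type = model_type
            except Exception as exc:  # noqa: BLE001 - suite keeps going
                eff = OutcomeEffect(
                    outcome=outcome, predictor=predictor, odds_ratio=np.nan,
                    ci_low=np.nan, ci_high=np.nan, p_value=np.nan, n=0,
                    model_type=model_type, error=str(exc),
                )
            effects.append(eff)
    return effects


def effects_frame(effects: list[OutcomeEffect]) -> pd.DataFrame:
    """One row per effect, ready for CSV export."""
    return pd.DataFrame([e.__dict__ for e in effects])
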