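"""Per-participant linear predictions (factor scores) of the latent variable.

The default is the regression (empirical-Bayes) score: the conditional
expectation of eta given a participant's indicators and determinants,
evaluated at the fitted parameters,

    E[eta | y, x] = gamma'x + cov(eta, y | x) Var(y | x)^{-1} (y - nu - lambda gamma'x)

which is linear in the data and shrunken towards the structural prediction.
Bartlett scores (conditionally unbiased, not shrunken) are available behind
a flag for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .datamodel import cohort_units
from .sem import FitResult

__all__ = ["LatentPrediction", "predict_latent", "standardize"]


@dataclass
class LatentPrediction:
    """Raw scores on the latent (birth-weight z-score) scale, optionally a
    standardized version, and a per-row availability flag."""

    raw: pd.Series
    standardized: pd.Series | None
    available: pd.Series

    def frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"score_raw": self.raw, "score_available": self.available})
        if self.standardized is not None:
            out["score_std"] = self.standardized
        return out


def predict_latent(fit: FitResult, table: pd.DataFrame, method: str = "regression") -> LatentPrediction:
    """Factor scores for every row complete on the model variables.

    Rows with any missing model variable get a missing score and an
    ``available`` flag of False.
    """
    if not fit.converged:
        raise ValueError("predict_latent requires a converged fit")
    if fit.params is None:
        raise ValueError("factor scores are defined for the latent-variable model")
    spec = fit.spec
    p = fit.params
    lam = np.array([1.0, p.lambda_blz])
    nu = np.array([p.nu[ind] for ind in spec.indicators])
    theta = np.array([p.theta[ind] for ind in spec.indicators])
    Vy = np.outer(lam, lam) * p.psi + np.diag(theta)
    if np.linalg.matrix_rank(Vy) < 2:
        raise ValueError("singular Var(y | x): both theta at zero")

    design = cohort_units(table, tuple(spec.determinants) + tuple(spec.indicators))
    complete = ~design.isna().any(axis=1)
    X = design.loc[complete, list(spec.determinants)].to_numpy(float)
    Y = design.loc[complete, list(spec.indicators)].to_numpy(float)
    gamma = np.array([p.gamma[c] for c in spec.determinants])
    struct = X @ gamma
    resid = Y - nu - np.outer(struct, lam)
    if method == "regression":
        try:
            weights = linalg.solve(Vy, lam * p.psi, assume_a="pos")
        except linalg.LinAlgError as exc:
            raise ValueError("singular Var(y | x): both theta at zero") from exc
        scores = struct + resid @ weights
    elif method == "bartlett":
        w = lam / theta
        scores = struct + resid @ w / (lam @ w)
    else:
        raise ValueError(f"unknown factor-score method {method!r}")
    raw = pd.Series(np.nan, index=table.index, name="score_raw")
    raw.loc[complete] = scores
    return LatentPrediction(
        raw=raw,
        standardized=None,
        available=pd.Series(complete, index=table.index, name="score_available"),
    )


def standardize(pred: LatentPrediction) -> LatentPrediction:
    """Sample z-transform of the raw scores (mean 0, SD 1 over complete
    cases, denominator n-1).  Idempotent up to floating error."""
    vals = pred.raw.dropna()
    if vals.nunique() < 2:
        raise ValueError("standardization needs at least two distinct scores")
    sd = vals.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance in factor scores")
    std = (pred.raw - vals.mean()) / sd
    return LatentPrediction(raw=pred.raw, standardized=std.rename("score_std"),
                            available=pred.available)
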