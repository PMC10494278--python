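"""MIMIC structural equation model: ML fit, robust corrections, fit indices.

The model describes latent foetal growth conditions eta with two reflective
indicators (birth weight and length z-scores) and observed maternal
determinants as causes::

    eta  = gamma' x_all + zeta,          zeta ~ N(0, psi)
    bwz  = nu_1 +        eta + eps_1,    eps_1 ~ N(0, theta_1)
    blz  = nu_2 + lambda*eta + eps_2,    eps_2 ~ N(0, theta_2)

The loading of bwz is fixed at 1, scaling the latent variable in birth-weight
z-score units.  Two determinants (pre-pregnancy elevated blood pressure and
insufficient gestational weight gain) are themselves endogenous, receiving
linear paths from the remaining determinants; all other determinants are
exogenous and treated as fixed regressors (conditional likelihood).  Binary
endogenous variables are modelled linearly, the linear-probability convention
of covariance-structure software; see the methods note for the implied
limitations.

Estimation minimizes the normal-theory ML discrepancy between the implied
and sample conditional moments.  Because the likelihood of the exogenous
block factorizes out, the conditional fit yields the same point estimates as
a joint fit with saturated exogenous moments.  Robustness to non-normality
comes from the Satorra-Bentler correction: the empirical fourth-order moment
matrix Gamma of the sample moments rescales the chi-square statistic and
sandwiches the parameter covariance.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats as sstats

from .datamodel import cohort_units

__all__ = [
    "ModelSpec",
    "DirectSpec",
    "ParameterSet",
    "FitResult",
    "FitSettings",
    "mimic_spec",
    "implied_moments",
    "ml_fit",
    "satorra_bentler",
    "fit_indices",
    "r_squared",
    "build_direct_model",
    "compare_models",
    "analyze",
    "ComparisonTable",
]

POPULATION_DETERMINANTS = (
    "age",
    "height_cm",
    "prepreg_weight_kg",
    "elevated_bp",
    "primiparity",
    "smoking",
    "malaria_pregnancy",
    "insufficient_gwg",
)
SUBSAMPLE_DETERMINANTS = POPULATION_DETERMINANTS + ("hc_z", "ac_z", "fl_z")
ENDOGENOUS_DEFAULT = ("elevated_bp", "insufficient_gwg")
INDICATORS = ("bwz", "blz")


class ConvergenceError(RuntimeError):
    """Optimizer failed to converge; carries the last iterate."""

    def __init__(self, message, theta=None, grad_norm=None):
        super().__init__(message)
        self.theta = theta
        self.grad_norm = grad_norm


class IdentificationError(RuntimeError):
    """Singular information matrix: the model is not identified on the data."""


# --------------------------------------------------------------------------
# model specifications
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of the MIMIC graph.

    ``determinants`` lists all observed causes of the latent variable, in
    model-ready units (height per centimetre).  Members of ``endogenous``
    additionally receive linear paths from every exogenous determinant.
    """

    determinants: tuple[str, ...]
    endogenous: tuple[str, ...] = ENDOGENOUS_DEFAULT
    indicators: tuple[str, ...] = INDICATORS
    fixed_loading: str = "bwz"
    variant: str = "population"

    def __post_init__(self):
        if self.fixed_loading != self.indicators[0]:
            raise ValueError("the first indicator carries the fixed unit loading")
        missing = [c for c in self.endogenous if c not in self.determinants]
        if missing:
            raise ValueError(f"endogenous variables must be determinants: {missing}")

    @property
    def exogenous(self) -> tuple[str, ...]:
        return tuple(c for c in self.determinants if c not in self.endogenous)

    @property
    def modelled(self) -> tuple[str, ...]:
        """Endogenous variables: receive-a-path order used throughout."""
        return tuple(self.endogenous) + self.indicators


@dataclass(frozen=True)
class DirectSpec:
    """No-latent alternative: each indicator regressed on all determinants,
    with correlated indicator residuals; endogenous-covariate equations kept
    identical to the latent model so both condition on the same variables."""

    determinants: tuple[str, ...]
    endogenous: tuple[str, ...] = ENDOGENOUS_DEFAULT
    indicators: tuple[str, ...] = INDICATORS
    variant: str = "direct"

    exogenous = ModelSpec.exogenous
    modelled = ModelSpec.modelled


def mimic_spec(variant: str = "population") -> ModelSpec:
    """Model layout for the two study populations."""
    if variant == "population":
        return ModelSpec(determinants=POPULATION_DETERMINANTS, variant=variant)
    if variant == "subsample":
        return ModelSpec(determinants=SUBSAMPLE_DETERMINANTS, variant=variant)
    raise ValueError(f"unknown variant {variant!r}")


@dataclass
class ParameterSet:
    """Structured view of the free parameters of a latent-variable spec."""

    gamma: dict[str, float]
    lambda_blz: float
    nu: dict[str, float]
    psi: float
    theta: dict[str, float]
    beta: dict[str, dict[str, float]]  # endogenous -> {const, exogenous...}
    omega: dict[str, float]  # endogenous residual variances

    def validate(self):
        if self.psi < 0 or any(v < 0 for v in self.theta.values()):
            raise ValueError("variance parameters must be non-negative")


# --------------------------------------------------------------------------
# internal parameterizations
# --------------------------------------------------------------------------


class _LatentModel:
    """Maps the free-parameter vector of a ModelSpec to its reduced form.

    Layout: per endogenous variable (intercept, q exogenous slopes); the two
    indicator intercepts; gamma over determinants; lambda; endogenous
    residual variances; psi; the two indicator residual variances.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.exo = spec.exogenous
        self.endo = spec.endogenous
        q, e = len(self.exo), len(self.endo)
        self.q, self.e = q, e
        self.k = 1 + q
        self.nm = e + 2
        names: list[str] = []
        for dep in self.endo:
            names.append(f"{dep}_const")
            names += [f"{dep}_on_{c}" for c in self.exo]
        names += [f"nu_{ind}" for ind in spec.indicators]
        names += [f"gamma_{c}" for c in spec.determinants]
        names.append("lambda_blz")
        names += [f"omega_{dep}" for dep in self.endo]
        names.append("psi")
        names += [f"theta_{ind}" for ind in spec.indicators]
        self.names = names
        self.n_params = len(names)
        # index helpers
        self._i_beta = [(1 + q) * j for j in range(e)]
        self._i_nu = (1 + q) * e
        self._i_gamma = self._i_nu + 2
        d = len(spec.determinants)
        self._i_lambda = self._i_gamma + d
        self._i_omega = self._i_lambda + 1
        self._i_psi = self._i_omega + e
        self._i_theta = self._i_psi + 1
        self._gamma_exo_pos = [spec.determinants.index(c) for c in self.exo]
        self._gamma_endo_pos = [spec.determinants.index(c) for c in self.endo]

    def reduced_form(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        q, e, k = self.q, self.e, self.k
        A = np.zeros((self.nm, k))
        for j in range(e):
            A[j] = theta[self._i_beta[j] : self._i_beta[j] + k]
        nu1, nu2 = theta[self._i_nu], theta[self._i_nu + 1]
        gamma = theta[self._i_gamma : self._i_gamma + len(self.spec.determinants)]
        lam = theta[self._i_lambda]
        omega = theta[self._i_omega : self._i_omega + e]
        psi = theta[self._i_psi]
        th1, th2 = theta[self._i_theta], theta[self._i_theta + 1]
        # reduced-form row of eta over [1, x_exo]
        eta_row = np.zeros(k)
        for pos, det_i in zip(range(q), self._gamma_exo_pos):
            eta_row[1 + pos] = gamma[det_i]
        g_endo = np.array([gamma[i] for i in self._gamma_endo_pos])
        for j in range(e):
            eta_row += g_endo[j] * A[j]
        A[e] = eta_row
        A[e, 0] += nu1
        A[e + 1] = lam * eta_row
        A[e + 1, 0] += nu2
        # conditional covariance via loading matrix on (delta..., zeta, eps1, eps2)
        L = np.zeros((self.nm, e + 3))
        for j in range(e):
            L[j, j] = 1.0
        L[e, :e] = g_endo
        L[e, e] = 1.0
        L[e, e + 1] = 1.0
        L[e + 1, :e] = lam * g_endo
        L[e + 1, e] = lam
        L[e + 1, e + 2] = 1.0
        v = np.concatenate([omega, [psi, th1, th2]])
        Sigma = (L * v) @ L.T
        return A, Sigma

    def bounds(self):
        b = [(None, None)] * self.n_params
        for j in range(self.e):
            b[self._i_omega + j] = (1e-8, None)
        b[self._i_psi] = (1e-8, None)
        b[self._i_theta] = (1e-8, None)
        b[self._i_theta + 1] = (1e-8, None)
        return b

    def variance_indices(self):
        return list(range(self._i_omega, self._i_theta + 2))

    def start(self, frame: "_Frame") -> np.ndarray:
        """Deterministic starting values from least-squares decompositions."""
        spec = self.spec
        theta = np.zeros(self.n_params)
        A_sat, Sig_sat = frame.saturated()
        for j in range(self.e):
            theta[self._i_beta[j] : self._i_beta[j] + self.k] = A_sat[j]
            theta[self._i_omega + j] = max(Sig_sat[j, j], 1e-4)
        X = frame.X_det
        Z1 = np.column_stack([np.ones(len(X)), X])
        bwz = frame.M[:, self.e]
        blz = frame.M[:, self.e + 1]
        coef, *_ = np.linalg.lstsq(Z1, bwz, rcond=None)
        gamma0 = coef[1:]
        eta_hat = X @ gamma0
        v_eta_hat = eta_hat.var()
        if v_eta_hat > 1e-10:
            lam0 = float(np.cov(blz, eta_hat, ddof=0)[0, 1] / v_eta_hat)
        else:
            lam0 = 0.8
        if not np.isfinite(lam0) or abs(lam0) < 1e-3:
            lam0 = 0.8
        i, j = self.e, self.e + 1
        v0 = Sig_sat[i, j] / lam0 if abs(lam0) > 1e-8 else 0.5 * Sig_sat[i, i]
        v0 = float(np.clip(v0, 0.05 * Sig_sat[i, i], 2.0 * Sig_sat[i, i]))
        th1 = max(Sig_sat[i, i] - v0, 0.05 * Sig_sat[i, i])
        th2 = max(Sig_sat[j, j] - lam0**2 * v0, 0.05 * Sig_sat[j, j])
        g_endo_sq = sum(
            gamma0[p] ** 2 * theta[self._i_omega + jj]
            for jj, p in enumerate(self._gamma_endo_pos)
        )
        psi0 = max(v0 - g_endo_sq, 0.1 * v0)
        theta[self._i_nu] = coef[0]
        theta[self._i_nu + 1] = float(blz.mean() - lam0 * eta_hat.mean())
        theta[self._i_gamma : self._i_gamma + len(spec.determinants)] = gamma0
        theta[self._i_lambda] = lam0
        theta[self._i_psi] = psi0
        theta[self._i_theta] = th1
        theta[self._i_theta + 1] = th2
        return theta

    def parameter_set(self, theta: np.ndarray) -> ParameterSet:
        spec = self.spec
        gamma = theta[self._i_gamma : self._i_gamma + len(spec.determinants)]
        beta = {}
        for j, dep in enumerate(self.endo):
            row = theta[self._i_beta[j] : self._i_beta[j] + self.k]
            beta[dep] = {"const": float(row[0])}
            beta[dep].update({c: float(v) for c, v in zip(self.exo, row[1:])})
        return ParameterSet(
            gamma={c: float(g) for c, g in zip(spec.determinants, gamma)},
            lambda_blz=float(theta[self._i_lambda]),
            nu={ind: float(theta[self._i_nu + i]) for i, ind in enumerate(spec.indicators)},
            psi=float(theta[self._i_psi]),
            theta={
                ind: float(theta[self._i_theta + i])
                for i, ind in enumerate(spec.indicators)
            },
            beta=beta,
            omega={dep: float(theta[self._i_omega + j]) for j, dep in enumerate(self.endo)},
        )

    def pack(self, pset: ParameterSet) -> np.ndarray:
        theta = np.zeros(self.n_params)
        for j, dep in enumerate(self.endo):
            theta[self._i_beta[j]] = pset.beta[dep]["const"]
            for p, c in enumerate(self.exo):
                theta[self._i_beta[j] + 1 + p] = pset.beta[dep][c]
            theta[self._i_omega + j] = pset.omega[dep]
        for i, ind in enumerate(self.spec.indicators):
            theta[self._i_nu + i] = pset.nu[ind]
            theta[self._i_theta + i] = pset.theta[ind]
        for p, c in enumerate(self.spec.determinants):
            theta[self._i_gamma + p] = pset.gamma[c]
        theta[self._i_lambda] = pset.lambda_blz
        theta[self._i_psi] = pset.psi
        return theta

    # internal standardized parameterization: coefficients re-expressed for
    # centered/unit-scale exogenous covariates, so the optimizer works on a
    # well-conditioned surface while estimates stay on the original scale
    def phi_from_theta(self, theta, mx, sx):
        phi = np.asarray(theta, float).copy()
        q = self.q
        for j in range(self.e):
            b = self._i_beta[j]
            beta = theta[b + 1 : b + 1 + q]
            phi[b + 1 : b + 1 + q] = beta * sx
            phi[b] = theta[b] + beta @ mx
        shift = 0.0
        for t, p in enumerate(self._gamma_exo_pos):
            shift += theta[self._i_gamma + p] * mx[t]
            phi[self._i_gamma + p] = theta[self._i_gamma + p] * sx[t]
        lam = theta[self._i_lambda]
        phi[self._i_nu] = theta[self._i_nu] + shift
        phi[self._i_nu + 1] = theta[self._i_nu + 1] + lam * shift
        return phi

    def theta_from_phi(self, phi, mx, sx):
        theta = np.asarray(phi, float).copy()
        q = self.q
        for j in range(self.e):
            b = self._i_beta[j]
            beta = phi[b + 1 : b + 1 + q] / sx
            theta[b + 1 : b + 1 + q] = beta
            theta[b] = phi[b] - beta @ mx
        shift = 0.0
        for t, p in enumerate(self._gamma_exo_pos):
            theta[self._i_gamma + p] = phi[self._i_gamma + p] / sx[t]
            shift += theta[self._i_gamma + p] * mx[t]
        lam = phi[self._i_lambda]
        theta[self._i_nu] = phi[self._i_nu] - shift
        theta[self._i_nu + 1] = phi[self._i_nu + 1] - lam * shift
        return theta


class _DirectModel:
    """Per-indicator direct-effects alternative (no latent variable)."""

    def __init__(self, spec: DirectSpec):
        self.spec = spec
        self.exo = spec.exogenous
        self.endo = spec.endogenous
        q, e = len(self.exo), len(self.endo)
        self.q, self.e = q, e
        self.k = 1 + q
        self.nm = e + 2
        names: list[str] = []
        for dep in self.endo:
            names.append(f"{dep}_const")
            names += [f"{dep}_on_{c}" for c in self.exo]
        for ind in spec.indicators:
            names.append(f"{ind}_const")
            names += [f"{ind}_on_{c}" for c in self.exo]
            names += [f"{ind}_on_{c}" for c in self.endo]
        names += [f"omega_{dep}" for dep in self.endo]
        names += [f"theta_{ind}" for ind in spec.indicators]
        names.append("theta_cov")
        self.names = names
        self.n_params = len(names)
        self._i_ind = [(1 + q) * e + (1 + q + e) * i for i in range(2)]
        self._i_omega = (1 + q) * e + (1 + q + e) * 2
        self._i_theta = self._i_omega + e

    def reduced_form(self, theta):
        q, e, k = self.q, self.e, self.k
        A = np.zeros((self.nm, k))
        for j in range(e):
            A[j] = theta[(1 + q) * j : (1 + q) * j + k]
        d_endo = np.zeros((2, e))
        for i in range(2):
            base = self._i_ind[i]
            row = theta[base : base + k].copy()
            d_endo[i] = theta[base + k : base + k + e]
            for j in range(e):
                row += d_endo[i, j] * A[j]
            A[e + i] = row
        omega = theta[self._i_omega : self._i_omega + e]
        th1 = theta[self._i_theta]
        th2 = theta[self._i_theta + 1]
        thc = theta[self._i_theta + 2]
        L = np.zeros((self.nm, e + 2))
        for j in range(e):
            L[j, j] = 1.0
        L[e, :e] = d_endo[0]
        L[e, e] = 1.0
        L[e + 1, :e] = d_endo[1]
        L[e + 1, e + 1] = 1.0
        Cov_u = np.diag(np.concatenate([omega, [th1, th2]]))
        Cov_u[e, e + 1] = Cov_u[e + 1, e] = thc
        Sigma = L @ Cov_u @ L.T
        return A, Sigma

    def bounds(self):
        b = [(None, None)] * self.n_params
        for j in range(self.e):
            b[self._i_omega + j] = (1e-8, None)
        b[self._i_theta] = (1e-8, None)
        b[self._i_theta + 1] = (1e-8, None)
        return b

    def variance_indices(self):
        return list(range(self._i_omega, self._i_theta + 2))

    def start(self, frame):
        """Equation-wise least squares; exact ML here up to the single
        cross-equation independence restriction."""
        theta = np.zeros(self.n_params)
        A_sat, Sig_sat = frame.saturated()
        for j in range(self.e):
            theta[(1 + self.q) * j : (1 + self.q) * j + self.k] = A_sat[j]
            theta[self._i_omega + j] = max(Sig_sat[j, j], 1e-4)
        n = frame.M.shape[0]
        # regressors in parameter-layout order: constant, exogenous, endogenous
        Z1 = np.column_stack([frame.Z, frame.M[:, : self.e]])
        resids = []
        for i in range(2):
            y = frame.M[:, self.e + i]
            coef, *_ = np.linalg.lstsq(Z1, y, rcond=None)
            base = self._i_ind[i]
            theta[base : base + self.k + self.e] = coef
            resid = y - Z1 @ coef
            resids.append(resid)
            theta[self._i_theta + i] = max(resid @ resid / n, 1e-4)
        theta[self._i_theta + 2] = resids[0] @ resids[1] / n
        return theta

    def phi_from_theta(self, theta, mx, sx):
        phi = np.asarray(theta, float).copy()
        q, k = self.q, self.k
        rows = [(1 + q) * j for j in range(self.e)] + list(self._i_ind)
        for b in rows:
            beta = theta[b + 1 : b + 1 + q]
            phi[b + 1 : b + 1 + q] = beta * sx
            phi[b] = theta[b] + beta @ mx
        return phi

    def theta_from_phi(self, phi, mx, sx):
        theta = np.asarray(phi, float).copy()
        q = self.q
        rows = [(1 + q) * j for j in range(self.e)] + list(self._i_ind)
        for b in rows:
            beta = phi[b + 1 : b + 1 + q] / sx
            theta[b + 1 : b + 1 + q] = beta
            theta[b] = phi[b] - beta @ mx
        return theta


class _BaselineModel:
    """Independence baseline: modelled variables uncorrelated, free means
    and variances, no dependence on the exogenous covariates."""

    def __init__(self, nm: int, k: int):
        self.nm, self.k = nm, k
        self.n_params = 2 * nm
        self.names = [f"mean_{i}" for i in range(nm)] + [f"var_{i}" for i in range(nm)]

    def reduced_form(self, theta):
        A = np.zeros((self.nm, self.k))
        A[:, 0] = theta[: self.nm]
        Sigma = np.diag(theta[self.nm :])
        return A, Sigma

    def bounds(self):
        return [(None, None)] * self.nm + [(1e-10, None)] * self.nm

    def variance_indices(self):
        return list(range(self.nm, 2 * self.nm))

    def start(self, frame):
        M = frame.M
        return np.concatenate([M.mean(axis=0), M.var(axis=0)])


# --------------------------------------------------------------------------
# data frame for the conditional model
# --------------------------------------------------------------------------


class _Frame:
    """Design (Z = [1, exogenous]) and endogenous (M) matrices plus the
    sufficient statistics of the conditional Gaussian likelihood."""

    def __init__(self, df: pd.DataFrame, spec):
        self.spec = spec
        cols_needed = list(spec.determinants) + list(spec.indicators)
        design = cohort_units(df, tuple(cols_needed))
        if design.isna().any().any():
            raise ValueError(
                "ml_fit requires complete cases for all model variables; "
                "apply complete_case_filter first"
            )
        self.X_det = design[list(spec.determinants)].to_numpy(float)
        X_exo = design[list(spec.exogenous)].to_numpy(float)
        n = len(design)
        self.Z = np.column_stack([np.ones(n), X_exo])
        self.M = design[list(spec.modelled)].to_numpy(float)
        self.n = n
        self.Szz = self.Z.T @ self.Z / n
        self.Smz = self.M.T @ self.Z / n
        self.Smm = self.M.T @ self.M / n
        self._sat = None
        payload = np.ascontiguousarray(np.column_stack([self.Z, self.M]))
        self.data_hash = hashlib.sha256(payload.tobytes()).hexdigest()[:16]

    def saturated(self):
        if self._sat is None:
            A_sat = linalg.solve(self.Szz, self.Smz.T, assume_a="pos").T
            Sig_sat = self.Smm - A_sat @ self.Szz @ A_sat.T
            Sig_sat = 0.5 * (Sig_sat + Sig_sat.T)
            self._sat = (A_sat, Sig_sat)
        return self._sat

    def residuals(self, A):
        return self.M - self.Z @ A.T


def _discrepancy_terms(model, theta, frame):
    """log|Sigma| + tr(Sigma^{-1} R(theta)); large finite value off the cone."""
    A, Sigma = model.reduced_form(np.asarray(theta, float))
    R = (
        frame.Smm
        - frame.Smz @ A.T
        - A @ frame.Smz.T
        + A @ frame.Szz @ A.T
    )
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        return 1e10
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    tr = np.trace(np.linalg.solve(Sigma, R))
    if not np.isfinite(tr):
        return 1e10
    return logdet + tr


# --------------------------------------------------------------------------
# fit result container
# --------------------------------------------------------------------------


@dataclass
class FitSettings:
    """Optimizer settings: relative function tolerance, gradient max-norm at
    the solution, and the iteration cap."""

    ftol: float = 1e-12
    gtol: float = 1e-5
    max_iter: int = 500


@dataclass
class FitResult:
    spec: object
    theta: np.ndarray
    names: list[str]
    n: int
    df: int
    n_free: int
    loglik: float
    loglik_sat: float
    fmin: float
    T_ML: float
    converged: bool
    n_iter: int
    grad_norm: float
    vcov_naive: np.ndarray
    params: ParameterSet | None = None
    vcov_robust: np.ndarray | None = None
    sb_c: float | None = None
    T_SB: float | None = None
    Gamma: np.ndarray | None = None
    indices: dict = field(default_factory=dict)
    r2: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)
    data_hash: str = ""
    Phi_det: np.ndarray | None = None
    mean_det: np.ndarray | None = None
    _model: object = None
    _frame: object = None

    @property
    def se_naive(self):
        return np.sqrt(np.clip(np.diag(self.vcov_naive), 0, None))

    @property
    def se_robust(self):
        if self.vcov_robust is None:
            return None
        return np.sqrt(np.clip(np.diag(self.vcov_robust), 0, None))

    def pvalues(self, robust: bool = True) -> dict[str, float]:
        se = self.se_robust if (robust and self.vcov_robust is not None) else self.se_naive
        z = self.theta / np.where(se > 0, se, np.nan)
        p = 2.0 * sstats.norm.sf(np.abs(z))
        return dict(zip(self.names, p))

    def estimates(self) -> dict[str, float]:
        return dict(zip(self.names, self.theta))

    def conf_int(self, alpha: float = 0.05, robust: bool = True):
        se = self.se_robust if (robust and self.vcov_robust is not None) else self.se_naive
        zq = sstats.norm.ppf(1 - alpha / 2)
        return {
            name: (est - zq * s, est + zq * s)
            for name, est, s in zip(self.names, self.theta, se)
        }

    def to_dict(self) -> dict:
        """JSON-serializable summary (round-trippable estimates)."""
        out = {
            "variant": getattr(self.spec, "variant", "custom"),
            "n": self.n,
            "df": self.df,
            "n_free": self.n_free,
            "loglik": self.loglik,
            "T_ML": self.T_ML,
            "T_SB": self.T_SB,
            "sb_c": self.sb_c,
            "converged": bool(self.converged),
            "estimates": self.estimates(),
            "se_naive": dict(zip(self.names, self.se_naive)),
            "indices": self.indices,
            "r2": self.r2,
            "notes": self.notes,
        }
        if self.vcov_robust is not None:
            out["se_robust"] = dict(zip(self.names, self.se_robust))
        return out


# --------------------------------------------------------------------------
# moment-vector machinery (shared by naive and robust covariances)
# --------------------------------------------------------------------------


def _vech_indices(p):
    rows, cols = [], []
    for j in range(p):
        for i in range(j, p):
            rows.append(i)
            cols.append(j)
    return np.array(rows), np.array(cols)


def _duplication(p):
    """Duplication matrix D with vec(S) = D vech(S) for symmetric S."""
    nv = p * (p + 1) // 2
    D = np.zeros((p * p, nv))
    rows, cols = _vech_indices(p)
    for idx, (i, j) in enumerate(zip(rows, cols)):
        D[j * p + i, idx] = 1.0
        D[i * p + j, idx] = 1.0
    return D


def _moment_vector(model, theta, k):
    A, Sigma = model.reduced_form(theta)
    rows, cols = _vech_indices(A.shape[0])
    return np.concatenate([A.ravel(order="F"), Sigma[rows, cols]])


def _moment_jacobian(model, theta, k):
    base = _moment_vector(model, theta, k)
    J = np.zeros((base.size, theta.size))
    for j in range(theta.size):
        h = 1e-6 * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        J[:, j] = (_moment_vector(model, tp, k) - _moment_vector(model, tm, k)) / (2 * h)
    return J


def _weight_matrix(Szz, Sigma):
    """Normal-theory weight: block-diagonal over (coefficients, covariances)."""
    p = Sigma.shape[0]
    Sinv = linalg.inv(Sigma)
    V_coef = np.kron(Szz, Sinv)
    D = _duplication(p)
    V_cov = 0.5 * D.T @ np.kron(Sinv, Sinv) @ D
    k = Szz.shape[0]
    V = np.zeros((k * p + D.shape[1], k * p + D.shape[1]))
    V[: k * p, : k * p] = V_coef
    V[k * p :, k * p :] = V_cov
    return V


def _naive_vcov(model, theta, frame):
    _, Sigma = model.reduced_form(theta)
    V = _weight_matrix(frame.Szz, Sigma)
    Delta = _moment_jacobian(model, theta, frame.Z.shape[1])
    H = Delta.T @ V @ Delta
    try:
        B = linalg.inv(H)
    except linalg.LinAlgError as exc:
        raise IdentificationError("singular information matrix") from exc
    return B / frame.n, Delta, V, B


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------


def implied_moments(params: ParameterSet, spec: ModelSpec, mu_x=None, Phi_x=None):
    """Model-implied joint mean vector and covariance of the modelled
    variables, ordered (exogenous..., endogenous..., bwz, blz).

    ``mu_x`` and ``Phi_x`` are the exogenous moments; for a spec with no
    exogenous determinants they may be omitted.  For the indicator block
    conditional on the covariates the implied covariance is
    ``lambda lambda' * v_eta + diag(theta)`` with ``v_eta`` the total latent
    variance given the path structure.
    """
    params.validate()
    model = _LatentModel(spec)
    theta = model.pack(params)
    A, Sigma_c = model.reduced_form(theta)
    q = model.q
    if q == 0:
        mu_x = np.zeros(0)
        Phi_x = np.zeros((0, 0))
    else:
        mu_x = np.asarray(mu_x, float).reshape(q)
        Phi_x = np.asarray(Phi_x, float).reshape(q, q)
    A0, A1 = A[:, 0], A[:, 1:]
    mu_m = A0 + A1 @ mu_x
    top = np.hstack([Phi_x, Phi_x @ A1.T])
    bottom = np.hstack([A1 @ Phi_x, A1 @ Phi_x @ A1.T + Sigma_c])
    Sigma = np.vstack([top, bottom])
    Sigma = 0.5 * (Sigma + Sigma.T)
    mu = np.concatenate([mu_x, mu_m])
    return mu, Sigma


def _central_gradient(fun, x, at_bound):
    grad = np.zeros_like(x)
    for j in range(x.size):
        h = 1e-6 * max(1.0, abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        grad[j] = (fun(xp) - fun(xm)) / (2 * h)
    free = grad[~at_bound]
    return grad, (float(np.max(np.abs(free))) if free.size else 0.0)


def _fit_internal(frame, model, settings: FitSettings):
    """Quasi-Newton minimization in the standardized parameterization."""
    theta0 = model.start(frame)
    X = frame.Z[:, 1:]
    if X.shape[1]:
        mx = X.mean(axis=0)
        sx = X.std(axis=0)
        sx = np.where(sx > 1e-12, sx, 1.0)
    else:
        mx = sx = np.zeros(0)
    to_theta = lambda phi: model.theta_from_phi(phi, mx, sx)
    fun = lambda phi: _discrepancy_terms(model, to_theta(phi), frame)

    def fun_and_grad(phi):
        f0 = fun(phi)
        grad = np.empty_like(phi)
        for j in range(phi.size):
            h = 1e-7 * max(1.0, abs(phi[j]))
            pj = phi.copy()
            pj[j] += h
            grad[j] = (fun(pj) - f0) / h
        return f0, grad

    phi0 = model.phi_from_theta(theta0, mx, sx)
    bounds = model.bounds()  # variance positions are scale-invariant
    opts = {"maxiter": settings.max_iter, "ftol": settings.ftol,
            "gtol": 1e-9, "maxfun": 200000}
    res = optimize.minimize(fun_and_grad, phi0, jac=True, method="L-BFGS-B",
                            bounds=bounds, options=opts)
    phi, n_iter = res.x, res.nit
    for _ in range(2):
        at_bound = np.array(
            [lo is not None and phi[j] <= lo + 1e-7 for j, (lo, hi) in enumerate(bounds)]
        )
        _, grad_norm = _central_gradient(fun, phi, at_bound)
        if grad_norm < settings.gtol:
            break
        res = optimize.minimize(
            fun_and_grad, phi, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": settings.max_iter, "ftol": 1e-15, "gtol": 1e-10},
        )
        phi = res.x
        n_iter += res.nit
    at_bound = np.array(
        [lo is not None and phi[j] <= lo + 1e-7 for j, (lo, hi) in enumerate(bounds)]
    )
    _, grad_norm = _central_gradient(fun, phi, at_bound)
    converged = grad_norm < settings.gtol
    theta = to_theta(phi)
    return theta, res, n_iter, grad_norm, converged, at_bound


def ml_fit(df: pd.DataFrame, spec, settings: FitSettings | None = None) -> FitResult:
    """Fit the model by maximum likelihood on complete cases.

    Minimizes the conditional ML discrepancy by quasi-Newton iteration from
    deterministic least-squares starting values.  ``T_ML = (n - 1) * Fhat``
    with ``Fhat`` the discrepancy of the fitted versus the saturated
    multivariate regression; ``df`` is the number of non-redundant sample
    moments minus the number of free parameters.

    Raises :class:`ConvergenceError` on non-convergence and flags Heywood
    cases (variance estimates at the zero boundary) with a warning.
    """
    settings = settings or FitSettings()
    if isinstance(spec, DirectSpec):
        model = _DirectModel(spec)
    else:
        model = _LatentModel(spec)
    frame = _Frame(df, spec)
    n, nm, k = frame.n, model.nm, frame.Z.shape[1]
    if n <= model.n_params:
        raise ValueError(f"n = {n} must exceed the {model.n_params} free parameters")
    A_sat, Sig_sat = frame.saturated()
    try:
        linalg.cho_factor(Sig_sat)
        linalg.cho_factor(frame.Szz)
    except linalg.LinAlgError as exc:
        raise ValueError("sample moment matrix not positive definite") from exc

    theta, res, n_iter, grad_norm, converged, at_bound = _fit_internal(frame, model, settings)
    notes = []
    heywood = [model.names[j] for j in model.variance_indices() if at_bound[j]]
    if heywood:
        msg = f"Heywood case: variance floored at 0 for {heywood}"
        warnings.warn(msg, stacklevel=2)
        notes.append(msg)
    if not converged:
        raise ConvergenceError(
            f"no convergence after {n_iter} iterations (grad max-norm {grad_norm:.2e})",
            theta=theta,
            grad_norm=grad_norm,
        )

    f_sat = 2.0 * np.sum(np.log(np.diag(linalg.cholesky(Sig_sat, lower=True)))) + nm
    fval = _discrepancy_terms(model, theta, frame)
    fhat = max(fval - f_sat, 0.0)
    T_ML = (n - 1) * fhat
    n_moments = nm * k + nm * (nm + 1) // 2
    df_model = n_moments - model.n_params
    loglik = -0.5 * n * (nm * np.log(2 * np.pi) + fval)
    loglik_sat = -0.5 * n * (nm * np.log(2 * np.pi) + f_sat)
    vcov_naive, *_ = _naive_vcov(model, theta, frame)

    X = frame.X_det
    fit = FitResult(
        spec=spec,
        theta=theta,
        names=list(model.names),
        n=n,
        df=df_model,
        n_free=model.n_params,
        loglik=float(loglik),
        loglik_sat=float(loglik_sat),
        fmin=float(fhat),
        T_ML=float(T_ML),
        converged=converged,
        n_iter=int(n_iter),
        grad_norm=grad_norm,
        vcov_naive=vcov_naive,
        params=model.parameter_set(theta) if isinstance(model, _LatentModel) else None,
        notes=notes,
        data_hash=frame.data_hash,
        Phi_det=np.cov(X, rowvar=False, ddof=1) if X.shape[1] else None,
        mean_det=X.mean(axis=0) if X.shape[1] else None,
        _model=model,
        _frame=frame,
    )
    return fit


def satorra_bentler(table: pd.DataFrame | None, fit: FitResult) -> FitResult:
    """Attach Satorra-Bentler scaled statistics and robust standard errors.

    Gamma is the empirical asymptotic covariance of the non-redundant sample
    moments (a function of fourth-order moments).  The robust parameter
    covariance is the sandwich (D'VD)^{-1} D'V Gamma V D (D'VD)^{-1} / n and
    the scaling factor is c = tr(U Gamma) / df with U the residual weight
    projector; T_SB = T_ML / c.
    """
    model, frame = fit._model, fit._frame
    if table is not None:
        frame_new = _Frame(table, fit.spec)
        if frame_new.data_hash != frame.data_hash:
            raise ValueError("table does not match the data the model was fitted on")
    if not fit.converged:
        raise ValueError("satorra_bentler requires a converged fit")
    n = frame.n
    A_sat, Sig_sat = frame.saturated()
    R = frame.residuals(A_sat)
    W = frame.Z @ linalg.inv(frame.Szz)
    IF_coef = np.einsum("ia,ib->iab", W, R).reshape(n, -1)
    rows, cols = _vech_indices(model.nm)
    IF_cov = R[:, rows] * R[:, cols] - Sig_sat[rows, cols]
    IF = np.hstack([IF_coef, IF_cov])
    Gamma = IF.T @ IF / n

    _, Sigma_hat = model.reduced_form(fit.theta)
    V = _weight_matrix(frame.Szz, Sigma_hat)
    Delta = _moment_jacobian(model, fit.theta, frame.Z.shape[1])
    H = Delta.T @ V @ Delta
    try:
        B = linalg.inv(H)
    except linalg.LinAlgError as exc:
        raise IdentificationError("singular information matrix") from exc
    VD = V @ Delta
    fit.vcov_robust = B @ (VD.T @ Gamma @ VD) @ B / n
    fit.Gamma = Gamma
    if fit.df > 0:
        U = V - VD @ B @ VD.T
        c = float(np.trace(U @ Gamma) / fit.df)
        fit.sb_c = c
        fit.T_SB = float(fit.T_ML / c)
    else:
        fit.sb_c = None
        fit.T_SB = 0.0
        fit.notes.append("df = 0: SB scaling undefined, T_SB reported as 0")
    return fit


def _fit_baseline(frame) -> dict:
    """Closed-form independence baseline on the same data."""
    model = _BaselineModel(frame.M.shape[1], frame.Z.shape[1])
    theta = model.start(frame)
    nm = model.nm
    fval = _discrepancy_terms(model, theta, frame)
    _, Sig_sat = frame.saturated()
    f_sat = 2.0 * np.sum(np.log(np.diag(linalg.cholesky(Sig_sat, lower=True)))) + nm
    T = (frame.n - 1) * max(fval - f_sat, 0.0)
    n_moments = nm * frame.Z.shape[1] + nm * (nm + 1) // 2
    return {"model": model, "theta": theta, "T_ML": T, "df": n_moments - model.n_params}


def _baseline_sb(frame, base, Gamma):
    model, theta = base["model"], base["theta"]
    _, Sigma = model.reduced_form(theta)
    V = _weight_matrix(frame.Szz, Sigma)
    Delta = _moment_jacobian(model, theta, frame.Z.shape[1])
    B = linalg.inv(Delta.T @ V @ Delta)
    VD = V @ Delta
    U = V - VD @ B @ VD.T
    c = float(np.trace(U @ Gamma) / base["df"])
    return base["T_ML"] / c


def _srmr(fit: FitResult) -> float:
    """Root mean square standardized residual over the joint covariance
    block of all modelled variables (exogenous moments at their sample
    values; no mean residuals)."""
    model, frame = fit._model, fit._frame
    A, Sigma_c = model.reduced_form(fit.theta)
    A1 = A[:, 1:]
    X = frame.Z[:, 1:]
    n = frame.n
    if X.shape[1]:
        Phi = np.cov(X, rowvar=False, ddof=0).reshape(X.shape[1], X.shape[1])
    else:
        Phi = np.zeros((0, 0))
    implied = np.vstack(
        [
            np.hstack([Phi, Phi @ A1.T]),
            np.hstack([A1 @ Phi, A1 @ Phi @ A1.T + Sigma_c]),
        ]
    )
    joint = np.column_stack([X, frame.M])
    S = np.cov(joint, rowvar=False, ddof=0)
    sd = np.sqrt(np.diag(S))
    rows, cols = _vech_indices(S.shape[0])
    resid = (S[rows, cols] - implied[rows, cols]) / (sd[rows] * sd[cols])
    return float(np.sqrt(np.mean(resid**2)))


def _indices_from_stats(T_t, df_t, T_b, df_b, n):
    rmsea = float(np.sqrt(max(T_t - df_t, 0.0) / (df_t * (n - 1)))) if df_t > 0 else 0.0
    denom = max(T_b - df_b, T_t - df_t, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(T_t - df_t, 0.0) / denom
    cfi = float(np.clip(cfi, 0.0, 1.0))
    if df_t > 0 and df_b > 0 and (T_b / df_b) != 1.0:
        tli = float(((T_b / df_b) - (T_t / df_t)) / ((T_b / df_b) - 1.0))
    else:
        tli = np.nan
    return rmsea, cfi, tli


def fit_indices(fit: FitResult, baseline: dict | None = None, n: int | None = None) -> FitResult:
    """Attach RMSEA, CFI, TLI, BIC and SRMR, each computed with the
    normal-theory statistic and (when available) the Satorra-Bentler scaled
    statistic in the same formulas."""
    frame = fit._frame
    n = n or fit.n
    base = baseline or _fit_baseline(frame)
    T_t, df_t = fit.T_ML, fit.df
    T_b, df_b = base["T_ML"], base["df"]
    rmsea, cfi, tli = _indices_from_stats(T_t, df_t, T_b, df_b, n)
    out = {
        "rmsea": rmsea,
        "cfi": cfi,
        "tli": tli,
        "bic": float(-2.0 * fit.loglik + fit.n_free * np.log(n)),
        "srmr": _srmr(fit),
        "baseline_T": float(T_b),
        "baseline_df": int(df_b),
    }
    if fit.T_SB is not None and fit.Gamma is not None and df_t > 0:
        T_b_sb = _baseline_sb(frame, base, fit.Gamma)
        r_sb, c_sb, t_sb = _indices_from_stats(fit.T_SB, df_t, T_b_sb, df_b, n)
        out.update({"rmsea_sb": r_sb, "cfi_sb": c_sb, "tli_sb": t_sb,
                    "baseline_T_sb": float(T_b_sb)})
    fit.indices.update(out)
    return fit


def r2_components(v_eta: float, lambdas, thetas) -> list[float]:
    """Indicator explained-variance shares lam_j^2 v_eta / (lam_j^2 v_eta +
    theta_j); pure arithmetic shared with :func:`r_squared`."""
    out = []
    for lam, th in zip(lambdas, thetas):
        tot = lam**2 * v_eta + th
        if tot <= 0:
            raise ValueError("zero total indicator variance")
        out.append(lam**2 * v_eta / tot)
    return out


def r_squared(fit: FitResult) -> FitResult:
    """Explained-variance shares.

    For indicator j: R2_j = lambda_j^2 Var(eta) / (lambda_j^2 Var(eta) +
    theta_j) with Var(eta) = gamma' Phi gamma + psi, Phi the sample
    covariance of the determinants.  R2 for the latent variable itself is
    gamma' Phi gamma / (gamma' Phi gamma + psi).
    """
    if fit.params is None:
        raise ValueError("r_squared applies to latent-variable fits")
    spec = fit.spec
    gamma = np.array([fit.params.gamma[c] for c in spec.determinants])
    Phi = fit.Phi_det
    struct = float(gamma @ Phi @ gamma) if Phi is not None else 0.0
    v_eta = struct + fit.params.psi
    lambdas = [1.0, fit.params.lambda_blz]
    thetas = [fit.params.theta[ind] for ind in spec.indicators]
    shares = r2_components(v_eta, lambdas, thetas)
    r2 = {f"r2_{ind}": s for ind, s in zip(spec.indicators, shares)}
    r2["r2_latent"] = struct / v_eta if v_eta > 0 else np.nan
    r2["var_eta"] = v_eta
    fit.r2.update(r2)
    return fit


def build_direct_model(df: pd.DataFrame, covariates=None, variant="population",
                       settings: FitSettings | None = None) -> FitResult:
    """Fit the no-latent alternative: bwz and blz each regressed on all
    determinants with correlated residuals, in the same ML framework."""
    determinants = tuple(covariates) if covariates else (
        POPULATION_DETERMINANTS if variant == "population" else SUBSAMPLE_DETERMINANTS
    )
    spec = DirectSpec(determinants=determinants, variant=f"direct-{variant}")
    return ml_fit(df, spec, settings=settings)


@dataclass
class ComparisonTable:
    table: pd.DataFrame
    preferred: str  # "latent" | "direct" | "tie"

    def __str__(self):  # pragma: no cover - cosmetic
        return f"{self.table}\npreferred by BIC: {self.preferred}"


def compare_models(latent: FitResult, direct: FitResult) -> ComparisonTable:
    """Side-by-side fit statistics with a lower-BIC preference flag.

    Both fits must come from identical rows of the same table.
    """
    if latent.n != direct.n or latent.data_hash[:8] == "":
        raise ValueError("fits must use the same sample")
    if latent._frame.M.shape == direct._frame.M.shape and not np.allclose(
        latent._frame.M, direct._frame.M
    ):
        raise ValueError("fits were not computed on identical rows")
    rows = {}
    for label, fit in (("latent", latent), ("direct", direct)):
        rows[label] = {
            "T_SB": fit.T_SB if fit.T_SB is not None else np.nan,
            "T_ML": fit.T_ML,
            "df": fit.df,
            "n_free": fit.n_free,
            "rmsea": fit.indices.get("rmsea", np.nan),
            "bic": fit.indices.get("bic", np.nan),
            "cfi": fit.indices.get("cfi", np.nan),
            "tli": fit.indices.get("tli", np.nan),
        }
    table = pd.DataFrame(rows).T
    b_l, b_d = rows["latent"]["bic"], rows["direct"]["bic"]
    if np.isclose(b_l, b_d, rtol=0, atol=1e-9):
        preferred = "tie"
    else:
        preferred = "latent" if b_l < b_d else "direct"
    return ComparisonTable(table=table, preferred=preferred)


def fit_from_dict(payload: dict) -> FitResult:
    """Rebuild a latent-model FitResult from its JSON form (estimates and
    summary statistics only; matrices needed for refitting are not kept)."""
    spec = mimic_spec(payload["variant"])
    model = _LatentModel(spec)
    theta = np.array([payload["estimates"][nm] for nm in model.names])
    k = len(model.names)
    fit = FitResult(
        spec=spec,
        theta=theta,
        names=list(model.names),
        n=int(payload["n"]),
        df=int(payload["df"]),
        n_free=int(payload["n_free"]),
        loglik=float(payload["loglik"]),
        loglik_sat=np.nan,
        fmin=np.nan,
        T_ML=float(payload["T_ML"]),
        converged=bool(payload["converged"]),
        n_iter=0,
        grad_norm=np.nan,
        vcov_naive=np.full((k, k), np.nan),
        params=model.parameter_set(theta),
        T_SB=payload.get("T_SB"),
        sb_c=payload.get("sb_c"),
        indices=dict(payload.get("indices", {})),
        r2=dict(payload.get("r2", {})),
        notes=list(payload.get("notes", [])),
    )
    return fit


def analyze(df: pd.DataFrame, spec=None, settings: FitSettings | None = None) -> FitResult:
    """Convenience pipeline: ML fit, SB corrections, fit indices, R2."""
    spec = spec or mimic_spec("population")
    fit = ml_fit(df, spec, settings=settings)
    fit = satorra_bentler(None, fit)
    fit = fit_indices(fit)
    if isinstance(spec, ModelSpec):
        fit = r_squared(fit)
    return fit
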